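import numpy as np
import pytest

import bpimap as bp
from bpimap.evaluate import (
    DEFAULT_N_GRID,
    PipelineConfig,
    decision_rates,
    gamma_sweep,
    run_pipeline,
    sample_size_sweep,
)


class TestDecisionRates:
    def test_perfect_classification(self):
        truth = np.array([bp.ACTIVATED] * 3 + [bp.DEACTIVATED] * 2 + [bp.NOT_ACTIVATED] * 5, dtype=np.int8)
        r = decision_rates(truth.copy(), truth)
        assert all(v == 1.0 for v in r.correct.values())
        assert all(v == 0.0 for v in r.incorrect.values())
        assert r.low_confidence == 0.0

    def test_all_low_confidence(self):
        truth = np.array([bp.ACTIVATED, bp.DEACTIVATED, bp.NOT_ACTIVATED], dtype=np.int8)
        r = decision_rates(np.zeros(3, dtype=np.int8), truth)
        assert r.low_confidence == 1.0
        assert all(v == 0.0 for v in r.correct.values())

    def test_confusion_matrix_arithmetic(self):
        # 10 true activated: 7 labelled activated, 2 low confidence, 1 not act;
        # 90 true not-activated: 3 labelled activated, rest correct
        truth = np.array([bp.ACTIVATED] * 10 + [bp.NOT_ACTIVATED] * 90, dtype=np.int8)
        labels = np.array(
            [bp.ACTIVATED] * 7 + [bp.LOW_CONFIDENCE] * 2 + [bp.NOT_ACTIVATED]
            + [bp.ACTIVATED] * 3 + [bp.NOT_ACTIVATED] * 87,
            dtype=np.int8,
        )
        r = decision_rates(labels, truth)
        assert r.correct["activated"] == pytest.approx(0.7)
        assert r.incorrect["activated"] == pytest.approx(3 / 90)

    def test_empty_truth_category_is_undefined_not_zero(self):
        truth = np.array([bp.ACTIVATED, bp.NOT_ACTIVATED], dtype=np.int8)
        r = decision_rates(truth.copy(), truth)
        assert r.correct["deactivated"] is None
        assert r.as_flat_dict()["correct_deactivated"] is None

    def test_invariant_under_joint_permutation(self, rng):
        truth = rng.choice([bp.ACTIVATED, bp.DEACTIVATED, bp.NOT_ACTIVATED], 200).astype(np.int8)
        labels = rng.choice([bp.ACTIVATED, bp.DEACTIVATED, bp.NOT_ACTIVATED, bp.LOW_CONFIDENCE], 200).astype(np.int8)
        perm = rng.permutation(200)
        assert decision_rates(labels, truth).as_flat_dict() == decision_rates(labels[perm], truth[perm]).as_flat_dict()

    def test_every_voxel_counted_exactly_once(self, rng):
        truth = rng.choice([bp.ACTIVATED, bp.DEACTIVATED, bp.NOT_ACTIVATED], 500).astype(np.int8)
        labels = rng.choice([bp.ACTIVATED, bp.DEACTIVATED, bp.NOT_ACTIVATED, bp.LOW_CONFIDENCE], 500).astype(np.int8)
        r = decision_rates(labels, truth)
        n_correct = sum(
            (labels == code)[truth == code].sum()
            for code in (bp.ACTIVATED, bp.DEACTIVATED, bp.NOT_ACTIVATED)
        )
        n_incorrect = sum(
            (labels == code)[truth != code].sum()
            for code in (bp.ACTIVATED, bp.DEACTIVATED, bp.NOT_ACTIVATED)
        )
        n_lc = (labels == bp.LOW_CONFIDENCE).sum()
        assert n_correct + n_incorrect + n_lc == 500
        assert r.low_confidence == n_lc / 500


class TestSampleSizeSweep:
    def test_default_grid_matches_simulation_protocol(self):
        assert DEFAULT_N_GRID[:10] == tuple(range(10, 101, 10))
        assert DEFAULT_N_GRID[10:] == tuple(range(150, 501, 50))

    def test_full_sample_single_rep_equals_direct_run(self, small_phantom):
        n = small_phantom.stack.n_subjects
        res = sample_size_sweep(
            small_phantom.stack, small_phantom.truth, grid=[n], n_reps=1
        )
        direct = decision_rates(
            run_pipeline(small_phantom.stack.data), small_phantom.truth
        )
        assert res.mean[0] == {k: v for k, v in direct.as_flat_dict().items()}

    def test_low_confidence_rate_nonincreasing_in_n(self, small_phantom):
        """More subjects never leave substantially more voxels undecided."""
        res = sample_size_sweep(
            small_phantom.stack,
            small_phantom.truth,
            grid=[20, 40, 80, 160, 300],
            n_reps=10,
            base_seed=1,
        )
        lc = [m["low_confidence"] for m in res.mean]
        assert np.all(np.diff(lc) <= 0.02)

    def test_grid_exceeding_pool_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            sample_size_sweep(small_phantom.stack, small_phantom.truth, grid=[10_000])

    def test_reproducible_for_same_base_seed(self, small_phantom):
        kw = dict(grid=[30, 60], n_reps=3, base_seed=5)
        a = sample_size_sweep(small_phantom.stack, small_phantom.truth, **kw)
        b = sample_size_sweep(small_phantom.stack, small_phantom.truth, **kw)
        assert a.mean == b.mean

    def test_nhst_count_overtakes_bpi_count_at_large_n(self, small_phantom):
        """With gamma = 1 prior SD the Bayesian activated count plateaus near
        the true count while the Bonferroni NHST count keeps growing."""
        from bpimap.design import fit_ols, make_design
        from bpimap.nhst import NhstConfig, nhst_map

        data = small_phantom.stack.data
        n = data.shape[0]
        labels = run_pipeline(data)
        bpi_count = int((labels.label == bp.ACTIVATED).sum())
        s = fit_ols(data, make_design("one_sample", n))
        nhst_count = int(nhst_map(s, NhstConfig()).positive.sum())
        assert nhst_count > bpi_count


class TestGammaSweep:
    def test_zero_gamma_kills_not_activated_sensitivity(self, small_phantom):
        res = gamma_sweep(
            small_phantom.stack.data[:100], small_phantom.truth, [0.0, 0.5]
        )
        assert res.mean[0]["correct_not_activated"] == 0.0

    def test_huge_gamma_saturates_to_not_activated(self, small_phantom):
        res = gamma_sweep(small_phantom.stack.data[:100], small_phantom.truth, [5.0])
        assert res.mean[0]["correct_not_activated"] == 1.0
        assert res.mean[0]["incorrect_not_activated"] == 1.0

    def test_default_threshold_inside_optimal_band(self, small_phantom):
        """gamma = 1 prior SD falls inside the band where correct rates
        exceed 80% and incorrect rates stay below 5% (moderate effect,
        medium noise, large N)."""
        data = small_phantom.stack.data[:200]
        labels = run_pipeline(data)
        prior_sd = labels.posterior.prior.prior_sd
        grid = np.arange(0.0, 0.31, 0.01)
        res = gamma_sweep(data, small_phantom.truth, grid)
        band = res.extra["optimal_band"]
        assert band is not None
        assert band[0] <= prior_sd <= band[1]
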