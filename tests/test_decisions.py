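import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import bpimap as bp
from bpimap.design import VoxelSummary
from bpimap.peb import PosteriorMaps, PriorModel


def _posterior(means, sds, prior_var=0.04):
    means = np.atleast_1d(np.asarray(means, dtype=float))
    sds = np.broadcast_to(np.asarray(sds, dtype=float), means.shape)
    summary = VoxelSummary(means, np.full(means.shape, 0.01), np.full(means.shape, 10.0))
    return PosteriorMaps(means, sds, PriorModel(prior_var), summary)


class TestPosteriorProbabilities:
    def test_symmetric_zero_width_rope(self):
        p = bp.posterior_probabilities(_posterior(0.0, 1.0), 0.0)
        assert p.p_act[0] == pytest.approx(0.5)
        assert p.p_deact[0] == pytest.approx(0.5)
        assert p.p_null[0] == 0.0

    def test_gaussian_cdf_oracle(self):
        # m=0.2, s=0.1, gamma=0.1: P(theta > gamma) = Phi((m-gamma)/s) = Phi(1)
        p = bp.posterior_probabilities(_posterior(0.2, 0.1), 0.1)
        assert p.p_act[0] == pytest.approx(norm.cdf(1.0), abs=1e-12)

    def test_point_mass_limits(self):
        p = bp.posterior_probabilities(_posterior([0.3, 0.05, -0.3], 0.0), 0.1)
        assert p.p_act.tolist() == [1.0, 0.0, 0.0]
        assert p.p_null.tolist() == [0.0, 1.0, 0.0]
        assert p.p_deact.tolist() == [0.0, 0.0, 1.0]

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            bp.posterior_probabilities(_posterior(0.0, 1.0), -0.1)

    @settings(derandomize=True, max_examples=200)
    @given(
        m=st.floats(-5, 5),
        s=st.floats(1e-6, 10),
        gamma=st.floats(0, 5),
    )
    def test_normalization_property(self, m, s, gamma):
        p = bp.posterior_probabilities(_posterior(m, s), gamma)
        assert abs(p.p_act[0] + p.p_deact[0] + p.p_null[0] - 1.0) <= 1e-12

    def test_monotone_in_gamma(self):
        post = _posterior([0.1, -0.2, 0.0], [0.05, 0.1, 0.2])
        gammas = np.linspace(0, 1, 50)
        prev = None
        for g in gammas:
            p = bp.posterior_probabilities(post, g)
            if prev is not None:
                assert np.all(p.p_null >= prev.p_null - 1e-15)
                assert np.all(p.p_act <= prev.p_act + 1e-15)
                assert np.all(p.p_deact <= prev.p_deact + 1e-15)
            prev = p


class TestLpo:
    def test_even_odds(self):
        assert bp.lpo_from_probability(0.5) == 0.0

    def test_logit_closed_form(self):
        assert bp.lpo_from_probability(0.95) == pytest.approx(np.log(19), abs=1e-10)
        assert float(bp.lpo_from_probability(0.95)) == pytest.approx(2.9444, abs=1e-4)

    def test_lpo3_inverts_above_95pct(self):
        p = bp.probability_from_lpo(3.0)
        assert p == pytest.approx(0.9526, abs=1e-4)
        assert p > 0.95

    def test_endpoints_capped(self):
        assert bp.lpo_from_probability(1.0) == 38.0
        assert bp.lpo_from_probability(0.0) == -38.0


class TestRopeOnly:
    def test_labels_from_probabilities(self):
        post = _posterior([0.4, -0.4, 0.0, 0.11], [0.05, 0.05, 0.01, 0.08])
        dec = bp.classify_rope_only(bp.posterior_probabilities(post, 0.1), 0.95, post)
        assert dec.label.tolist() == [
            bp.ACTIVATED, bp.DEACTIVATED, bp.NOT_ACTIVATED, bp.LOW_CONFIDENCE,
        ]

    def test_threshold_must_exceed_half(self):
        post = _posterior(0.0, 1.0)
        with pytest.raises(ValueError):
            bp.classify_rope_only(bp.posterior_probabilities(post, 0.1), 0.4)


class TestHdi:
    def test_standard_normal_interval(self):
        lo, hi = bp.hdi(0.0, 1.0, 0.95)
        assert lo == pytest.approx(-1.95996, abs=1e-4)
        assert hi == pytest.approx(1.95996, abs=1e-4)

    def test_degenerate_interval(self):
        lo, hi = bp.hdi(0.3, 0.0, 0.95)
        assert lo == hi == 0.3

    def test_posterior_update_example_interval(self):
        lo, hi = bp.hdi(0.16, 0.0894, 0.95)
        assert lo == pytest.approx(-0.0153, abs=1e-3)
        assert hi == pytest.approx(0.3353, abs=1e-3)


class TestHdiRope:
    @pytest.mark.parametrize(
        "m,s,gamma,expected",
        [
            (0.3, 0.0510, 0.1, bp.ACTIVATED),      # HDI ~ [0.2, 0.4]
            (0.0, 0.0255, 0.1, bp.NOT_ACTIVATED),  # HDI ~ [-0.05, 0.05]
            (0.125, 0.0383, 0.1, bp.LOW_CONFIDENCE),  # HDI ~ [0.05, 0.2]
        ],
    )
    def test_interval_position_labels(self, m, s, gamma, expected):
        dec = bp.classify_hdi_rope(_posterior(m, s), gamma, 0.95)
        assert dec.label[0] == expected

    def test_touching_rope_edge_is_low_confidence(self):
        z = norm.ppf(0.975)
        gamma = 0.1
        dec = bp.classify_hdi_rope(_posterior(gamma + z * 0.05, 0.05), gamma, 0.95)
        assert dec.label[0] == bp.LOW_CONFIDENCE

    def test_conservative_subset_of_rope_only(self, rng):
        """HDI+ROPE decisions are nested inside ROPE-only decisions at
        matched thresholds (p_thr = mass = 0.95) for Gaussian posteriors."""
        post = _posterior(rng.normal(0, 0.2, 2000), rng.uniform(0.01, 0.15, 2000))
        gamma = 0.1
        rope = bp.classify_rope_only(bp.posterior_probabilities(post, gamma), 0.95, post)
        hdi_dec = bp.classify_hdi_rope(post, gamma, 0.95)
        for code in (bp.ACTIVATED, bp.DEACTIVATED, bp.NOT_ACTIVATED):
            assert np.all((hdi_dec.label != code) | (rope.label == code))


class TestResolveGamma:
    def test_absolute_value_passthrough(self):
        assert bp.resolve_gamma("absolute", value=0.1) == 0.1

    def test_prior_sd_multiple(self):
        post = _posterior(0.0, 0.1, prior_var=0.135**2)
        assert bp.resolve_gamma("prior_sd_multiple", post) == pytest.approx(0.135)
        assert bp.resolve_gamma("prior_sd_multiple", post, 2.0) == pytest.approx(0.27)

    def test_degenerate_prior_instructs_absolute(self):
        post = _posterior(0.0, 0.1, prior_var=0.0)
        with pytest.raises(ValueError, match="absolute"):
            bp.resolve_gamma("prior_sd_multiple", post)


class TestRopeMap:
    def test_rope_only_closed_forms(self):
        post = _posterior([0.3, 0.0, -0.3], [0.1, 0.05, 0.1])
        rmap = bp.rope_map(post, "rope_only", p_thr=0.95)
        z = norm.ppf(0.95)
        assert rmap.gamma_star_act[0] == pytest.approx(0.3 - z * 0.1, abs=1e-4)
        assert rmap.gamma_star_act[0] == pytest.approx(0.1355, abs=1e-4)
        assert np.isnan(rmap.gamma_star_act[1])
        assert rmap.gamma_star_deact[2] == pytest.approx(0.1355, abs=1e-4)
        # symmetric not-activated radius: gamma* = z_{0.975} * s
        assert rmap.gamma_star_null[1] == pytest.approx(0.05 * norm.ppf(0.975), abs=1e-4)

    def test_hdi_rope_closed_forms(self):
        post = _posterior([0.1], [0.05])
        rmap = bp.rope_map(post, "hdi_rope", mass=0.95)
        z = norm.ppf(0.975)
        assert rmap.gamma_star_null[0] == pytest.approx(0.1 + z * 0.05, abs=1e-6)
        assert rmap.gamma_star_null[0] == pytest.approx(0.1980, abs=1e-4)

    def test_null_radius_matches_bisection_oracle(self, rng):
        from scipy.optimize import brentq

        m = rng.normal(0, 0.2, 50)
        s = rng.uniform(0.02, 0.2, 50)
        rmap = bp.rope_map(_posterior(m, s), "rope_only", p_thr=0.95)

        def p_null(g, mm, ss):
            return norm.cdf((g - mm) / ss) - norm.cdf((-g - mm) / ss)

        for i in range(50):
            root = brentq(
                lambda g: p_null(g, m[i], s[i]) - 0.95, 0, abs(m[i]) + 10 * s[i],
                xtol=1e-10,
            )
            assert rmap.gamma_star_null[i] == pytest.approx(root, abs=1e-6)

    @pytest.mark.parametrize("rule", ["rope_only", "hdi_rope"])
    def test_reclassification_consistency_at_critical_gamma(self, rng, rule):
        """Decisions survive at gamma*(1-eps) and flip to low confidence at
        gamma*(1+eps) for activations; symmetric behaviour for the
        not-activated radius."""
        post = _posterior(rng.uniform(0.2, 0.5, 30), rng.uniform(0.02, 0.06, 30))
        rmap = bp.rope_map(post, rule, p_thr=0.95, mass=0.95)
        g_act = rmap.gamma_star_act
        assert np.all(np.isfinite(g_act))

        def labels_at(g_vec, sign):
            out = []
            for i, g in enumerate(g_vec):
                single = _posterior([post.post_mean[i]], [post.post_sd[i]])
                gg = max(g * (1 + sign * 1e-6), 0.0)
                if rule == "rope_only":
                    d = bp.classify_rope_only(
                        bp.posterior_probabilities(single, gg), 0.95, single
                    )
                else:
                    d = bp.classify_hdi_rope(single, gg, 0.95)
                out.append(d.label[0])
            return np.array(out)

        assert np.all(labels_at(g_act, -1) == bp.ACTIVATED)
        assert np.all(labels_at(g_act, +1) == bp.LOW_CONFIDENCE)

        g_null = rmap.gamma_star_null
        null_above = labels_at(g_null * (1 + 2e-6) / (1 + 1e-6), 0)
        assert np.all(null_above == bp.NOT_ACTIVATED)

    def test_zero_gamma_never_yields_not_activated(self, rng):
        post = _posterior(rng.normal(0, 0.1, 200), rng.uniform(0.01, 0.1, 200))
        p = bp.posterior_probabilities(post, 0.0)
        assert np.all(p.p_null == 0.0)
        dec = bp.classify_rope_only(p, 0.95, post)
        assert not np.any(dec.label == bp.NOT_ACTIVATED)
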