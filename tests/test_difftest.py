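"""Moderated threshold test, variance prior, BH adjustment, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import sgascore as sg
from sgascore.difftest import ModeratedVariancePrior
from sgascore.gridprep import ReplicateObservation


def step_up_oracle(pvals):
    """Hand BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestReplicateDifferentials:
    def make_obs(self, induced, uninduced, strain="x", query="q1"):
        return [
            ReplicateObservation(strain, query, "induced",
                                 np.asarray(induced, dtype=float)),
            ReplicateObservation(strain, query, "uninduced",
                                 np.asarray(uninduced, dtype=float)),
        ]

    def test_uniform_halving_gives_minus_one(self):
        obs = self.make_obs([100] * 4, [200] * 4)
        d = sg.replicate_differentials(obs, "q1")["x"]
        np.testing.assert_allclose(d, -1.0)

    def test_missing_slot_drops_pair(self):
        obs = self.make_obs([100, np.nan, 100, 100], [200] * 4)
        assert len(sg.replicate_differentials(obs, "q1")["x"]) == 3

    def test_zero_area_drops_pair(self):
        obs = self.make_obs([100, 0.0, 100, 100], [200] * 4)
        assert len(sg.replicate_differentials(obs, "q1")["x"]) == 3

    def test_single_pair_marks_untestable(self):
        obs = self.make_obs([100, np.nan, np.nan, np.nan], [200] * 4)
        assert len(sg.replicate_differentials(obs, "q1")["x"]) == 0

    def test_matches_per_slot_log_ratio_oracle(self, rng):
        a = rng.lognormal(6, 0.3, size=4)
        b = rng.lognormal(6, 0.3, size=4)
        d = sg.replicate_differentials(self.make_obs(a, b), "q1")["x"]
        np.testing.assert_allclose(d, np.log2(a) - np.log2(b), rtol=1e-12)


class TestVariancePrior:
    def test_all_equal_variances_give_infinite_d0(self):
        prior = sg.fit_variance_prior([0.04] * 100, 3)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.04)
        np.testing.assert_allclose(
            prior.posterior_variance([0.1, 0.02], 3), 0.04)

    def test_d0_zero_means_no_moderation(self):
        prior = ModeratedVariancePrior(d0=0.0, s0_sq=1.0)
        v = np.array([0.01, 0.5, 2.0])
        np.testing.assert_allclose(prior.posterior_variance(v, 3), v)

    def test_recovers_known_prior(self, rng):
        d0_true, s0_true, df = 4.0, 0.04, 3
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(df, size=5000) / df
        prior = sg.fit_variance_prior(s2, df)
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.15)

    def test_posterior_pools_toward_prior(self):
        prior = ModeratedVariancePrior(d0=4.0, s0_sq=0.04)
        post = float(prior.posterior_variance(0.12, 3))
        assert 0.04 < post < 0.12
        assert post == pytest.approx((4 * 0.04 + 3 * 0.12) / 7)


class TestThresholdTest:
    prior = ModeratedVariancePrior(d0=4.0, s0_sq=0.04)

    def test_zero_threshold_reduces_to_two_sided_t(self):
        for delta in (0.0, 0.1, 0.5, 1.5):
            _, p = sg.threshold_test(delta, 0.04, 4, self.prior,
                                     fold_threshold=1.0)
            df = 4 - 1 + 4.0
            t = delta / math.sqrt(0.04 / 4)
            expected = 2 * stats.t.sf(abs(t), df)
            assert p == pytest.approx(expected, abs=1e-10)

    def test_null_centered_effect_has_high_p(self):
        _, p = sg.threshold_test(0.0, 0.04, 4, self.prior, fold_threshold=1.3)
        assert p == pytest.approx(1.0)
        _, p2 = sg.threshold_test(0.0, 1e-6, 4, self.prior, fold_threshold=1.3)
        assert p2 == pytest.approx(1.0)

    def test_monotone_in_threshold_and_effect(self):
        ps = [sg.threshold_test(0.8, 0.04, 4, self.prior, fold_threshold=f)[1]
              for f in (1.0, 1.2, 1.5, 2.0)]
        assert ps == sorted(ps)
        ps = [sg.threshold_test(d, 0.04, 4, self.prior, fold_threshold=1.3)[1]
              for d in (0.1, 0.5, 1.0, 2.0)]
        assert ps == sorted(ps, reverse=True)

    def test_zero_se_degenerate_cases(self):
        _, p = sg.threshold_test(1.0, 0.0, 4, self.prior, fold_threshold=1.3)
        assert p == 0.0
        _, p = sg.threshold_test(0.1, 0.0, 4, self.prior, fold_threshold=1.3)
        assert p == 1.0

    def test_infinite_d0_uses_normal_tail(self):
        prior = ModeratedVariancePrior(d0=math.inf, s0_sq=0.04)
        _, p = sg.threshold_test(0.9, 0.04, 4, prior, fold_threshold=1.0)
        z = 0.9 / math.sqrt(0.04 / 4)
        assert p == pytest.approx(2 * stats.norm.sf(z), abs=1e-12)

    def test_null_center_shifts_effect(self):
        _, p_raw = sg.threshold_test(0.5, 0.04, 4, self.prior, 1.3, 0.0)
        _, p_centered = sg.threshold_test(0.5, 0.04, 4, self.prior, 1.3, 0.5)
        assert p_centered > p_raw
        assert p_centered == pytest.approx(1.0)


class TestBHAdjust:
    def test_single_p(self):
        np.testing.assert_allclose(sg.bh_adjust([0.03]), [0.03])

    def test_all_equal(self):
        np.testing.assert_allclose(sg.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            sg.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sg.bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            sg.bh_adjust([-0.1])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, pvals):
        np.testing.assert_allclose(sg.bh_adjust(pvals), step_up_oracle(pvals),
                                   atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_permutation_invariance_and_monotonicity(self, pvals, rnd):
        q = sg.bh_adjust(pvals)
        assert (q >= np.asarray(pvals) - 1e-15).all()
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q_perm = sg.bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


class TestClassify:
    cfg = sg.TestConfig()

    def run_one(self, s, q, control_wij, usable=True):
        return sg.classify([s], [q], [control_wij], [usable], self.cfg)[0]

    @pytest.mark.parametrize(
        "s,q,cw,expected",
        [
            (0.45, 0.01, 1.0, "positive"),
            (0.45, 0.20, 1.0, "none"),
            (-0.50, 0.001, 0.6, "filtered"),   # control gate fails
            (-0.50, 0.001, 1.0, "negative"),
            (0.25, 0.001, 1.0, "none"),        # |S| below threshold
            (0.45, 0.01, 1.3, "positive"),     # window is closed at 1.3
            (0.45, 0.01, 0.7, "positive"),     # ... and at 0.7
        ],
    )
    def test_gate_combinations(self, s, q, cw, expected):
        assert self.run_one(s, q, cw) == expected

    def test_unusable_is_filtered(self):
        assert self.run_one(0.45, 0.01, 1.0, usable=False) == "filtered"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sg.TestConfig(fold_threshold=0.9)
        with pytest.raises(ValueError):
            sg.TestConfig(s_positive_min=-0.1)


class TestTestQuery:
    def test_null_screen_p_values_superuniform(self, rng):
        # all strains share the global differential; p < 0.05 must be rare
        diffs = {
            f"s{i}": -1.0 + rng.normal(0, 0.2, size=4) for i in range(500)
        }
        out = sg.test_query(diffs)
        assert out.attrs["null_center"] == pytest.approx(-1.0, abs=0.05)
        assert (out["p_value"] < 0.05).mean() <= 0.06
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()

    def test_outlying_strain_detected(self, rng):
        diffs = {f"s{i}": rng.normal(0, 0.15, size=4) for i in range(300)}
        diffs["hit"] = rng.normal(-2.0, 0.15, size=4)
        out = sg.test_query(diffs).set_index("strain")
        assert out.at["hit", "q_value"] < 0.01
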