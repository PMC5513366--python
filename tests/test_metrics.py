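"""IPCW metrics: Kaplan-Meier, weights, AUC, Brier, sBS, coverage."""

import itertools

import numpy as np
import pytest

from psajoint import (
    auc_ipcw,
    brier_ipcw,
    censoring_km_curve,
    coverage,
    ipcw_weights,
    km_curve,
    scaled_brier,
)
from psajoint.hazard import SurvivalRecord
from psajoint.metrics import km_conditional_death_prob


def make_records(T, d):
    return [SurvivalRecord(subject_id=str(i), T=float(t), delta_event=int(e))
            for i, (t, e) in enumerate(zip(T, d))]


class TestKaplanMeier:
    def test_no_censoring_gives_empirical_survival(self):
        T = np.array([1.0, 2.0, 3.0, 4.0])
        c = km_curve(T, np.ones(4, int))
        assert np.allclose(c(np.array([1.0, 2.5, 4.0])), [0.75, 0.5, 0.0])

    def test_all_censored_gives_constant_one(self):
        c = km_curve([2.0, 5.0, 9.0], [0, 0, 0])
        assert np.allclose(c(np.array([1.0, 6.0, 20.0])), 1.0)

    def test_hand_product_limit(self):
        c = km_curve([2, 3, 5, 7], [1, 0, 1, 1])
        assert c(5.0) == pytest.approx(0.375)
        assert c.left(5.0) == pytest.approx(0.75)

    def test_censoring_curve_reverses_indicator(self):
        recs = make_records([2, 3, 5, 7], [1, 0, 1, 1])
        G = censoring_km_curve(recs)
        # only censoring "event" at t=3 among 3 at risk
        assert G(2.9) == pytest.approx(1.0)
        assert G(3.0) == pytest.approx(2.0 / 3.0)


class TestIpcwWeights:
    def test_no_censoring_weights_are_one(self):
        recs = make_records([5, 10, 20, 30], [1, 1, 1, 1])
        w, idx, nex = ipcw_weights(2.0, 10.0, recs, censoring_km_curve(recs))
        assert np.allclose(w[np.isin(idx, [0, 1, 2, 3])], 1.0)
        assert nex == 0

    def test_censored_inside_window_gets_zero(self):
        recs = make_records([5, 10, 20, 30], [1, 0, 1, 1])
        w, idx, _ = ipcw_weights(2.0, 15.0, recs, censoring_km_curve(recs))
        assert w[list(idx).index(1)] == 0.0

    def test_hand_computed_toy_weights(self):
        # 6 subjects, one censored at 8 inside the window (s, s+t] = (2, 20]
        T = [5.0, 8.0, 12.0, 25.0, 30.0, 40.0]
        d = [1, 0, 1, 1, 1, 1]
        recs = make_records(T, d)
        G = censoring_km_curve(recs)
        # censoring KM: only drop at 8 (5 at risk) -> G = 4/5 from t=8 on
        w, idx, _ = ipcw_weights(2.0, 18.0, recs, G)
        wm = dict(zip(idx, w))
        assert wm[0] == pytest.approx(1.0)          # event at 5, G(5-)=1
        assert wm[1] == 0.0                          # censored in window
        assert wm[2] == pytest.approx(1.0 / 0.8)     # event at 12, G(12-)=0.8
        for j in (3, 4, 5):
            assert wm[j] == pytest.approx(1.0 / 0.8)  # controls, G(20)=0.8


class TestAucIpcw:
    def test_perfect_separation_gives_one(self):
        recs = make_records([5, 6, 30, 40], [1, 1, 1, 1])
        assert auc_ipcw(0.0, 10.0, np.array([0.9, 0.8, 0.1, 0.2]), recs) == 1.0

    def test_constant_predictor_gives_half(self):
        recs = make_records([5, 6, 30, 40], [1, 1, 1, 1])
        assert auc_ipcw(0.0, 10.0, np.full(4, 0.5), recs) == 0.5

    def test_no_cases_returns_undefined(self):
        recs = make_records([30, 40, 50], [1, 1, 1])
        assert np.isnan(auc_ipcw(0.0, 10.0, np.array([0.1, 0.2, 0.3]), recs))

    def test_five_subject_toy_with_censoring_matches_hand_enumeration(self):
        T = [4.0, 6.0, 9.0, 15.0, 20.0]
        d = [1, 0, 1, 1, 1]
        recs = make_records(T, d)
        pi = np.array([0.9, 0.5, 0.6, 0.3, 0.2])
        # window (0, 10]: cases {0 (w=1), 2 (w=1/G(9-)=1/0.75)}; censored 1 w=0
        # controls {3, 4} with w = 1/G(10) = 1/0.75
        w0, w2, wc = 1.0, 1 / 0.75, 1 / 0.75
        num = w0 * wc * (1.0 + 1.0) + w2 * wc * (1.0 + 1.0)
        den = (w0 + w2) * 2 * wc
        assert auc_ipcw(0.0, 10.0, pi, recs) == pytest.approx(num / den)

    def test_invariant_to_monotone_transform(self, rng):
        T = rng.uniform(1, 50, 12)
        d = (rng.uniform(size=12) < 0.8).astype(int)
        recs = make_records(T, d)
        pi = rng.uniform(size=12)
        a1 = auc_ipcw(1.0, 20.0, pi, recs)
        a2 = auc_ipcw(1.0, 20.0, np.sqrt(pi) + 3.0, recs)
        assert a1 == pytest.approx(a2)

    def test_matches_exhaustive_enumeration_without_censoring(self, rng):
        """All cohorts of <= 8 subjects, random predictions, zero censoring."""
        for n in range(3, 9):
            for _ in range(20):
                T = rng.uniform(1, 100, n)
                pi = np.round(rng.uniform(size=n), 1)  # force some ties
                recs = make_records(T, np.ones(n, int))
                s, t = 0.0, float(rng.uniform(10, 80))
                case = (T > s) & (T <= s + t)
                ctrl = T > s + t
                if case.sum() == 0 or ctrl.sum() == 0:
                    assert np.isnan(auc_ipcw(s, t, pi, recs))
                    continue
                num = den = 0.0
                for i, j in itertools.product(np.flatnonzero(case),
                                              np.flatnonzero(ctrl)):
                    num += (pi[i] > pi[j]) + 0.5 * (pi[i] == pi[j])
                    den += 1.0
                assert auc_ipcw(s, t, pi, recs) == pytest.approx(num / den)


class TestBrierIpcw:
    def test_constant_half_gives_quarter(self):
        recs = make_records([5, 6, 30, 40], [1, 1, 1, 1])
        assert brier_ipcw(0.0, 10.0, np.full(4, 0.5), recs) == 0.25

    def test_oracle_predictor_gives_zero(self):
        T = np.array([5.0, 6.0, 30.0, 40.0])
        recs = make_records(T, [1, 1, 1, 1])
        pi = ((T > 0) & (T <= 10)).astype(float)
        assert brier_ipcw(0.0, 10.0, pi, recs) == 0.0

    def test_six_subject_toy_with_censoring_matches_hand_value(self):
        T = [5.0, 8.0, 12.0, 25.0, 30.0, 40.0]
        d = [1, 0, 1, 1, 1, 1]
        recs = make_records(T, d)
        pi = np.array([0.8, 0.5, 0.7, 0.2, 0.1, 0.1])
        # weights from TestIpcwWeights hand computation; denominator = 6 at risk
        hand = (1.0 * (1 - 0.8) ** 2 + 0.0 +
                1.25 * (1 - 0.7) ** 2 +
                1.25 * ((0 - 0.2) ** 2 + (0 - 0.1) ** 2 + (0 - 0.1) ** 2)) / 6.0
        assert brier_ipcw(2.0, 18.0, pi, recs) == pytest.approx(hand)

    def test_equals_mse_without_censoring(self, rng):
        for n in (4, 6, 8):
            T = rng.uniform(1, 100, n)
            recs = make_records(T, np.ones(n, int))
            pi = rng.uniform(size=n)
            s, t = 0.0, 50.0
            D = ((T > s) & (T <= s + t)).astype(float)
            assert brier_ipcw(s, t, pi, recs) == pytest.approx(np.mean((D - pi) ** 2))

    def test_minimized_at_event_proportion_over_constants(self, rng):
        T = rng.uniform(1, 100, 8)
        recs = make_records(T, np.ones(8, int))
        s, t = 0.0, 40.0
        p_event = np.mean((T > s) & (T <= s + t))
        grid = np.linspace(0, 1, 101)
        scores = [brier_ipcw(s, t, np.full(8, c), recs) for c in grid]
        assert grid[int(np.argmin(scores))] == pytest.approx(p_event, abs=0.01)


class TestAgainstSksurv:
    """Independent library implementation (scikit-survival), landmark 0."""

    def test_auc_and_brier_match_with_and_without_censoring(self, rng):
        from sksurv.metrics import brier_score, cumulative_dynamic_auc
        n = 30
        T = rng.uniform(1, 100, n)
        risk = np.round(rng.uniform(size=n), 1)
        times = np.array([20.0, 40.0, 60.0])
        for frac_events in (1.0, 0.7):
            d = rng.uniform(size=n) < frac_events
            y = np.array(list(zip(d, T)), dtype=[("e", bool), ("t", float)])
            recs = make_records(T, d.astype(int))
            auc_sk, _ = cumulative_dynamic_auc(y, y, risk, times)
            auc_us = [auc_ipcw(0.0, t, risk, recs) for t in times]
            assert np.allclose(auc_sk, auc_us, rtol=1e-10)
            _, bs_sk = brier_score(y, y, np.tile(1 - risk[:, None], (1, 3)), times)
            bs_us = [brier_ipcw(0.0, t, risk, recs) for t in times]
            assert np.allclose(bs_sk, bs_us, rtol=1e-10)


class TestScaledBrier:
    def setup_method(self):
        self.T = [5.0, 8.0, 12.0, 25.0, 30.0, 40.0]
        self.recs = make_records(self.T, [1, 1, 1, 1, 1, 1])
        self.ref = km_curve(self.T, np.ones(6, int))

    def test_zero_when_model_equals_km(self):
        pi_km = np.full(6, km_conditional_death_prob(self.ref, 2.0, 2.0 + 18.0 - 2.0))
        # direct identity: BS == BS_KM -> 0
        bs = brier_ipcw(2.0, 18.0, np.full(6, km_conditional_death_prob(self.ref, 2.0, 18.0)), self.recs)
        assert scaled_brier(2.0, 18.0, bs, self.recs, self.ref) == pytest.approx(0.0)

    def test_one_when_model_is_perfect(self):
        assert scaled_brier(2.0, 18.0, 0.0, self.recs, self.ref) == pytest.approx(1.0)

    def test_negative_when_model_worse_than_km(self):
        bs_km = brier_ipcw(2.0, 18.0,
                           np.full(6, km_conditional_death_prob(self.ref, 2.0, 18.0)),
                           self.recs)
        assert scaled_brier(2.0, 18.0, bs_km + 0.1, self.recs, self.ref) < 0.0


class TestCoverage:
    def test_infinite_bands_cover_everything(self):
        inb = np.ones((40, 5), dtype=bool)
        prop, lo, hi = coverage(inb)
        assert np.all(prop == 1.0) and lo < 0.95 < hi

    def test_zero_width_wrong_bands_cover_nothing(self):
        prop, _, _ = coverage(np.zeros((40, 5), dtype=bool))
        assert np.all(prop == 0.0)

    def test_envelope_tightens_with_sample_size(self):
        _, lo_small, hi_small = coverage(np.ones((20, 1), bool))
        _, lo_big, hi_big = coverage(np.ones((500, 1), bool))
        assert (hi_big - lo_big) < (hi_small - lo_small)
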