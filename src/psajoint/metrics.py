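"""Time-dependent predictive-accuracy metrics and coverage evaluation.

Discrimination and calibration of dynamic predictions pi(s+t|s) are
measured with the cumulative/dynamic time-dependent AUC and the Brier
score, both corrected for right censoring by inverse-probability-of-
censoring weights (IPCW) built from the Kaplan-Meier estimate G of the
censoring-time survival function:

    W_i(s,t) = 1{T_i > s+t} / G(s+t | s)  +  D_i delta_i / G(T_i- | s)

with D_i = 1{s < T_i <= s+t} and G(u|s) = G(u)/G(s).  G is evaluated
left-continuously at observed times so a subject's own censoring never
deflates its weight.  Cases are subjects with an event inside (s, s+t],
controls those still at risk beyond s+t; tied predictions count 1/2 so
a constant predictor scores AUC = 0.5 (and BS = 0.25 without censoring).

The scaled Brier score sBS = (BS_KM - BS)/BS_KM compares the model with
the marginal Kaplan-Meier prediction from a reference cohort.

Coverage evaluation (simulated cohorts only) checks how often the
generating truth falls inside the 95% Monte Carlo prediction bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import binom

__all__ = [
    "StepSurvivalCurve",
    "MetricResult",
    "km_curve",
    "censoring_km_curve",
    "ipcw_weights",
    "auc_ipcw",
    "brier_ipcw",
    "scaled_brier",
    "km_conditional_death_prob",
    "coverage",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepSurvivalCurve:
    """Right-continuous step survival curve starting at 1."""

    times: np.ndarray      # jump times, increasing
    values: np.ndarray     # curve value from times[i] (inclusive) onward

    def __call__(self, u):
        """Right-continuous evaluation S(u)."""
        idx = np.searchsorted(self.times, np.asarray(u, dtype=float), side="right")
        vals = np.concatenate([[1.0], self.values])
        return vals[idx]

    def left(self, u):
        """Left limit S(u-)."""
        idx = np.searchsorted(self.times, np.asarray(u, dtype=float), side="left")
        vals = np.concatenate([[1.0], self.values])
        return vals[idx]


@dataclass(frozen=True)
class MetricResult:
    s: float
    t: float
    auc: float
    bs: float
    sbs: float
    n_at_risk: int
    n_events_in_window: int


def _as_arrays(records):
    if isinstance(records, pd.DataFrame):
        return records["time_days"].to_numpy(float), records["event"].to_numpy(int)
    T = np.array([r.T for r in records], dtype=float)
    d = np.array([r.delta_event for r in records], dtype=int)
    return T, d


def km_curve(times, event_indicators) -> StepSurvivalCurve:
    """Product-limit survival estimate as a step curve."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_indicators, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(float)
    v = sf.iloc[:, 0].to_numpy(float)
    keep = t > 0
    return StepSurvivalCurve(times=t[keep], values=v[keep])


def censoring_km_curve(records) -> StepSurvivalCurve:
    """Kaplan-Meier curve of the censoring time (reversed indicator)."""
    T, d = _as_arrays(records)
    return km_curve(T, 1 - d)


def ipcw_weights(s: float, t: float, records, G_hat: StepSurvivalCurve):
    """IPCW weights for the subjects at risk at s.

    Returns ``(weights, at_risk_index, n_excluded)``; weights align with
    ``at_risk_index`` into the input records.  Subjects censored inside
    (s, s+t] get weight 0.  Subjects whose required G value is 0 are
    excluded (NaN-free output) with a logged count.
    """
    T, d = _as_arrays(records)
    at_risk = np.flatnonzero(T > s)
    Ti, di = T[at_risk], d[at_risk]
    G_s = float(G_hat(s))
    if G_s <= 0.0:
        raise ValueError("censoring survival is 0 at the landmark; weights undefined")

    D = ((Ti > s) & (Ti <= s + t)).astype(float)
    w = np.zeros(Ti.size)
    bad = np.zeros(Ti.size, dtype=bool)

    ctrl = Ti > s + t
    G_st = float(G_hat(s + t)) / G_s
    if np.any(ctrl):
        if G_st <= 0.0:
            bad |= ctrl
        else:
            w[ctrl] = 1.0 / G_st

    case = (D == 1.0) & (di == 1)
    G_Ti = G_hat.left(Ti[case]) / G_s
    zero = G_Ti <= 0.0
    if np.any(zero):
        idx = np.flatnonzero(case)
        bad[idx[zero]] = True
        G_Ti = np.where(zero, 1.0, G_Ti)
    w[case] = np.where(zero, 0.0, 1.0 / G_Ti)

    n_excluded = int(bad.sum())
    if n_excluded:
        logger.warning("excluding %d subjects with zero censoring-survival "
                       "weight at (s=%.0f, t=%.0f)", n_excluded, s, t)
    keep = ~bad
    return w[keep], at_risk[keep], n_excluded


def auc_ipcw(s: float, t: float, pi_hat, records, G_hat=None):
    """IPCW cumulative/dynamic AUC of predictions pi_hat at (s, t).

    ``pi_hat`` aligns with ``records``.  Ties in the predictor count
    1/2.  Returns NaN when there is no weighted case or no weighted
    control.
    """
    T, d = _as_arrays(records)
    pi_hat = np.asarray(pi_hat, dtype=float)
    if G_hat is None:
        G_hat = censoring_km_curve(records)
    w, idx, _ = ipcw_weights(s, t, records, G_hat)
    Ti, di, pi = T[idx], d[idx], pi_hat[idx]

    D = ((Ti > s) & (Ti <= s + t) & (di == 1))
    ctrl = Ti > s + t
    wc, pc = w[D], pi[D]
    wk, pk = w[ctrl], pi[ctrl]
    denom = np.sum(wc) * np.sum(wk)
    if wc.size == 0 or wk.size == 0 or denom <= 0.0:
        return np.nan
    gt = (pc[:, None] > pk[None, :]).astype(float)
    eq = (pc[:, None] == pk[None, :])
    num = np.sum((gt + 0.5 * eq) * wc[:, None] * wk[None, :])
    return float(num / denom)


def brier_ipcw(s: float, t: float, pi_hat, records, G_hat=None):
    """IPCW Brier score at (s, t); denominator is the count at risk at s."""
    T, d = _as_arrays(records)
    pi_hat = np.asarray(pi_hat, dtype=float)
    if G_hat is None:
        G_hat = censoring_km_curve(records)
    n_at_risk = int(np.sum(T > s))
    if n_at_risk == 0:
        return np.nan
    w, idx, _ = ipcw_weights(s, t, records, G_hat)
    Ti = T[idx]
    D = ((Ti > s) & (Ti <= s + t)).astype(float)
    pi = pi_hat[idx]
    return float(np.sum(w * (D - pi) ** 2) / n_at_risk)


def km_conditional_death_prob(reference_curve: StepSurvivalCurve, s: float, t):
    """Marginal prediction pi_KM(s+t|s) = 1 - S_KM(s+t)/S_KM(s)."""
    S_s = float(reference_curve(s))
    if S_s <= 0.0:
        raise ValueError("reference survival is 0 at the landmark")
    return 1.0 - reference_curve(s + np.asarray(t, dtype=float)) / S_s


def scaled_brier(s: float, t: float, bs: float, pi_hat_records,
                 reference_curve: StepSurvivalCurve, G_hat=None):
    """sBS = (BS_KM - BS)/BS_KM with the KM plug-in prediction as reference.

    ``pi_hat_records`` are the survival records of the evaluation cohort
    (the KM prediction is constant across subjects).  Returns NaN when
    BS_KM is 0 or BS is undefined.
    """
    if not np.isfinite(bs):
        return np.nan
    T, _ = _as_arrays(pi_hat_records)
    pi_km = np.full(T.size, km_conditional_death_prob(reference_curve, s, t))
    bs_km = brier_ipcw(s, t, pi_km, pi_hat_records, G_hat=G_hat)
    if not np.isfinite(bs_km) or bs_km <= 0.0:
        return np.nan
    return float((bs_km - bs) / bs_km)


def coverage(in_band: np.ndarray, nominal: float = 0.95):
    """Empirical coverage of prediction bands, with exact binomial envelope.

    ``in_band`` is a boolean (n_subjects, n_horizons) matrix: truth
    inside the band.  Returns ``(proportion, lo, hi)`` arrays per
    horizon, where [lo, hi] is the exact (Clopper-style) central 95%
    binomial envelope around the nominal level for n subjects.
    """
    in_band = np.asarray(in_band, dtype=bool)
    n = in_band.shape[0]
    prop = in_band.mean(axis=0)
    lo, hi = binom.interval(0.95, n, nominal)
    return prop, float(lo) / n, float(hi) / n
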