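"""Cohort and prediction file I/O.

All on-disk times are in days; PSA is stored in ng/mL and converted to
the modelling scale y = log(PSA+1) on read.  Files are plain CSV with a
header row, UTF-8, '.' decimal:

- ``longitudinal.csv``: subject_id, time_days, psa_ng_ml
- ``survival.csv``:     subject_id, time_days, event
- ``truth.csv``:        subject_id, r, psa0, eps, tesc, x_true_days
  (simulated cohorts only; kept separate so prediction code cannot
  silently read it)
- ``predictions.csv``:  subject_id, s_days, t_days, pi_median, pi_lo, pi_hi
- ``trajectories.csv``: subject_id, s_days, u_days, y_median, y_lo, y_hi
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .hazard import SurvivalRecord
from .model import LongitudinalRecord
from .simulate import Cohort

__all__ = ["read_cohort", "write_cohort", "read_truth", "write_predictions"]

LONGITUDINAL_FILE = "longitudinal.csv"
SURVIVAL_FILE = "survival.csv"
TRUTH_FILE = "truth.csv"


def write_cohort(cohort: Cohort, directory) -> None:
    """Write observable tables; truth (if present) goes to its own file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "subject_id": [r.subject_id for r in cohort.records],
        "time_days": [r.t for r in cohort.records],
        "psa_ng_ml": [float(np.expm1(r.y)) for r in cohort.records],
    }).to_csv(directory / LONGITUDINAL_FILE, index=False)
    pd.DataFrame({
        "subject_id": [s.subject_id for s in cohort.survival],
        "time_days": [s.T for s in cohort.survival],
        "event": [s.delta_event for s in cohort.survival],
    }).to_csv(directory / SURVIVAL_FILE, index=False)
    if cohort.subjects:
        pd.DataFrame({
            "subject_id": [s.subject_id for s in cohort.subjects],
            "r": [s.psi_true.r for s in cohort.subjects],
            "psa0": [s.psi_true.psa0 for s in cohort.subjects],
            "eps": [s.psi_true.eps for s in cohort.subjects],
            "tesc": [s.psi_true.tesc for s in cohort.subjects],
            "x_true_days": [s.x_true for s in cohort.subjects],
        }).to_csv(directory / TRUTH_FILE, index=False)


def _numeric(df: pd.DataFrame, col: str, fname: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"{fname}: non-numeric value in column {col!r} at row {row}")
    if vals.isna().any():
        row = int(vals.isna().idxmax())
        raise ValueError(f"{fname}: missing value in column {col!r} at row {row}")
    return vals.to_numpy(float)


def read_cohort(directory) -> Cohort:
    """Read observable tables back into a Cohort (truth never loaded here).

    PSA is converted to y = log(PSA+1); PSA = 0 is admitted (y = 0).
    Subjects present in the survival table but without PSA rows are kept
    with zero longitudinal records; the reverse is an error.
    """
    directory = Path(directory)
    long_df = pd.read_csv(directory / LONGITUDINAL_FILE)
    surv_df = pd.read_csv(directory / SURVIVAL_FILE)

    t = _numeric(long_df, "time_days", LONGITUDINAL_FILE)
    psa = _numeric(long_df, "psa_ng_ml", LONGITUDINAL_FILE)
    neg = np.flatnonzero(t < 0)
    if neg.size:
        raise ValueError(f"{LONGITUDINAL_FILE}: negative time at row {neg[0]}")
    # additive noise on the log(PSA+1) scale can legitimately put stored
    # measurements slightly below 0; only PSA <= -1 breaks the transform
    if np.any(psa <= -1.0):
        row = int(np.flatnonzero(psa <= -1.0)[0])
        raise ValueError(f"{LONGITUDINAL_FILE}: PSA <= -1 ng/mL at row {row}")

    surv_ids = set(surv_df["subject_id"].astype(str))
    long_ids = long_df["subject_id"].astype(str)
    orphans = sorted(set(long_ids) - surv_ids)
    if orphans:
        raise ValueError(
            f"subjects present in {LONGITUDINAL_FILE} but not in "
            f"{SURVIVAL_FILE}: {orphans[:5]}")

    records = [LongitudinalRecord(subject_id=sid, t=float(tt), y=float(np.log1p(p)))
               for sid, tt, p in zip(long_ids, t, psa)]
    T = _numeric(surv_df, "time_days", SURVIVAL_FILE)
    ev = _numeric(surv_df, "event", SURVIVAL_FILE)
    survival = [SurvivalRecord(subject_id=str(sid), T=float(tt), delta_event=int(e))
                for sid, tt, e in zip(surv_df["subject_id"], T, ev)]
    return Cohort(records=records, survival=survival)


def read_truth(directory) -> pd.DataFrame:
    """Load the hidden-truth table (evaluation code only)."""
    return pd.read_csv(Path(directory) / TRUTH_FILE)


def write_predictions(pred_rows, traj_rows, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(pred_rows, columns=[
        "subject_id", "s_days", "t_days", "pi_median", "pi_lo", "pi_hi",
    ]).to_csv(directory / "predictions.csv", index=False)
    pd.DataFrame(traj_rows, columns=[
        "subject_id", "s_days", "u_days", "y_median", "y_lo", "y_hi",
    ]).to_csv(directory / "trajectories.csv", index=False)
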