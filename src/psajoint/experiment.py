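"""Orchestration: simulate -> predict -> evaluate, reproducibly.

A single experiment seed determines everything: the cohort, and one
sampler substream per (landmark, subject) pair, derived through
``numpy.random.SeedSequence`` spawn keys so per-subject sampling is
order-independent.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig, dump_config
from .io import write_cohort, write_predictions
from .metrics import (
    auc_ipcw,
    brier_ipcw,
    censoring_km_curve,
    coverage,
    km_curve,
    scaled_brier,
)
from .model import DAYS_PER_MONTH, IndividualParameters, PopulationParameters
from .posterior import DynamicPrediction, LandmarkDataset, SamplerSettings, dynamic_prediction
from .simulate import Cohort, simulate_cohort, true_conditional_death_prob
from .model import log_psa_obs_mean

__all__ = ["ExperimentResult", "predict_landmark", "evaluate_predictions",
           "evaluate_coverage", "run_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentResult:
    cohort: Cohort
    predictions: dict[float, dict[str, DynamicPrediction]]  # s_days -> subject -> pred
    metrics: pd.DataFrame
    coverage: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _subject_seed(seed: int, s_days: float, index: int) -> int:
    key = (int(round(s_days * 1000)), index)
    ss = np.random.SeedSequence(seed, spawn_key=key)
    return int(ss.generate_state(1)[0]) % (2**31)


def predict_landmark(cohort: Cohort, pop: PopulationParameters, s_days: float,
                     horizon_days: np.ndarray, L: int, seed: int,
                     settings: SamplerSettings = SamplerSettings(),
                     ) -> dict[str, DynamicPrediction]:
    """Dynamic predictions for every subject at risk at the landmark."""
    by_subject: dict[str, list] = {}
    for r in cohort.records:
        by_subject.setdefault(r.subject_id, []).append(r)
    preds: dict[str, DynamicPrediction] = {}
    for i, srec in enumerate(cohort.survival):
        if srec.T <= s_days:
            continue
        recs = [r for r in by_subject.get(srec.subject_id, []) if r.t <= s_days]
        data = LandmarkDataset(
            subject_id=srec.subject_id, s=s_days,
            times=np.array([r.t for r in recs]),
            y=np.array([r.y for r in recs]))
        pred, _ = dynamic_prediction(
            data, pop, horizon_days, L=L,
            seed=_subject_seed(seed, s_days, i), settings=settings)
        preds[srec.subject_id] = pred
    return preds


def evaluate_predictions(preds: dict[str, DynamicPrediction], cohort: Cohort,
                         s_days: float, horizon_days: np.ndarray,
                         reference_curve=None) -> list[dict]:
    """IPCW AUC / BS / sBS rows for one landmark over the horizon grid.

    The reference Kaplan-Meier curve for the scaled Brier score defaults
    to the evaluation cohort's own curve.
    """
    records = [s for s in cohort.survival]
    T = np.array([s.T for s in records])
    d = np.array([s.delta_event for s in records])
    if reference_curve is None:
        reference_curve = km_curve(T, d)
    G_hat = censoring_km_curve(records)
    at_risk_ids = [s.subject_id for s in records if s.T > s_days]
    pi_matrix = np.full((len(records), horizon_days.size), np.nan)
    id_index = {s.subject_id: i for i, s in enumerate(records)}
    for sid in at_risk_ids:
        if sid in preds:
            pi_matrix[id_index[sid]] = preds[sid].pi_median
    rows = []
    for j, t_days in enumerate(horizon_days):
        pi_hat = pi_matrix[:, j]
        try:
            auc = auc_ipcw(s_days, t_days, pi_hat, records, G_hat=G_hat)
            bs = brier_ipcw(s_days, t_days, pi_hat, records, G_hat=G_hat)
            sbs = scaled_brier(s_days, t_days, bs, records, reference_curve,
                               G_hat=G_hat)
        except ValueError:
            # degenerate risk set or exhausted censoring curve: marker rows
            auc = bs = sbs = np.nan
        rows.append({
            "s_months": s_days / DAYS_PER_MONTH,
            "t_months": t_days / DAYS_PER_MONTH,
            "s_days": s_days, "t_days": t_days,
            "auc": auc, "bs": bs, "sbs": sbs,
            "n_at_risk": int(np.sum(T > s_days)),
            "n_events": int(np.sum((T > s_days) & (T <= s_days + t_days) & (d == 1))),
        })
    return rows


def evaluate_coverage(preds: dict[str, DynamicPrediction], cohort: Cohort,
                      pop: PopulationParameters, s_days: float,
                      horizon_days: np.ndarray, nominal: float = 0.95) -> list[dict]:
    """Band coverage of the generating truth, per horizon.

    Requires a cohort with retained truth.  For each at-risk subject the
    noise-free biomarker curve b(s+t, psi_true) is checked against the
    trajectory band and the true conditional death probability against
    the risk band.
    """
    if not cohort.subjects:
        raise ValueError("coverage evaluation requires simulated truth")
    if not preds:
        return []
    truth = {s.subject_id: s for s in cohort.subjects}
    in_band_psa, in_band_risk = [], []
    for sid, pred in preds.items():
        psi_true: IndividualParameters = truth[sid].psi_true
        b_true = log_psa_obs_mean(pred.traj_grid, psi_true,
                                  pop.d_fixed, pop.delta_elim_fixed)
        pi_true = true_conditional_death_prob(psi_true, pop, s_days,
                                              pred.horizon_grid)
        in_band_psa.append((pred.traj_lo <= b_true) & (b_true <= pred.traj_hi))
        in_band_risk.append((pred.pi_lo <= pi_true) & (pi_true <= pred.pi_hi))
    prop_psa, lo, hi = coverage(np.array(in_band_psa), nominal)
    prop_risk, _, _ = coverage(np.array(in_band_risk), nominal)
    return [{
        "s_months": s_days / DAYS_PER_MONTH,
        "t_months": t_days / DAYS_PER_MONTH,
        "coverage_psa": prop_psa[j], "coverage_risk": prop_risk[j],
        "envelope_lo": lo, "envelope_hi": hi,
        "n_at_risk": len(in_band_psa), "nominal": nominal,
    } for j, t_days in enumerate(horizon_days)]


def run_experiment(config: ExperimentConfig, outdir=None) -> ExperimentResult:
    """Run the full simulation-study pipeline for every landmark.

    Writes, when ``outdir`` is given: cohort CSVs (+ hidden truth),
    per-landmark predictions and trajectories, ``metrics.csv``,
    ``coverage.csv`` and a reproducibility manifest.
    """
    t_start = time.time()
    pop = config.population.build()
    design = config.design.build(seed=int(
        np.random.SeedSequence(config.seed, spawn_key=(0,)).generate_state(1)[0] % (2**31)))
    cohort = simulate_cohort(pop, design)

    horizon_days = config.horizons.grid_months() * DAYS_PER_MONTH
    settings = config.sampler.build()
    predictions, metric_rows, coverage_rows = {}, [], []
    pred_rows, traj_rows = [], []
    T = np.array([s.T for s in cohort.survival])
    km_ref = km_curve(T, [s.delta_event for s in cohort.survival])

    for s_months in config.landmarks_months:
        s_days = s_months * DAYS_PER_MONTH
        preds = predict_landmark(cohort, pop, s_days, horizon_days,
                                 L=config.L, seed=config.seed, settings=settings)
        predictions[s_days] = preds
        metric_rows += evaluate_predictions(preds, cohort, s_days, horizon_days,
                                            reference_curve=km_ref)
        if cohort.subjects:
            coverage_rows += evaluate_coverage(preds, cohort, pop, s_days,
                                               horizon_days)
        for sid, p in preds.items():
            for j, t_days in enumerate(horizon_days):
                pred_rows.append((sid, s_days, t_days, p.pi_median[j],
                                  p.pi_lo[j], p.pi_hi[j]))
                traj_rows.append((sid, s_days, p.traj_grid[j], p.traj_median[j],
                                  p.traj_lo[j], p.traj_hi[j]))
        logger.info("landmark %.0f months: %d subjects predicted",
                    s_months, len(preds))

    metrics_df = pd.DataFrame(metric_rows)
    coverage_df = pd.DataFrame(coverage_rows)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "design_seed": design.seed,
        "config": config.model_dump(),
        "n_subjects": design.n_subjects,
        "elapsed_seconds": None,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, outdir)
        write_predictions(pred_rows, traj_rows, outdir)
        metrics_df.to_csv(outdir / "metrics.csv", index=False)
        coverage_df.to_csv(outdir / "coverage.csv", index=False)
        dump_config(config, outdir / "config.yaml")
        manifest["elapsed_seconds"] = round(time.time() - t_start, 2)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    else:
        manifest["elapsed_seconds"] = round(time.time() - t_start, 2)

    return ExperimentResult(cohort=cohort, predictions=predictions,
                            metrics=metrics_df, coverage=coverage_df,
                            manifest=manifest)
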