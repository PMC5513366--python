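"""Synthetic mCRPC cohort generation from the joint model.

Subjects are drawn from the population distribution (diagonal-Gaussian
random effects on the transformed scale), their death time is sampled
exactly by inverting the individual survival function, and PSA is
observed every ``visit_interval`` days (default 21, starting at day 0)
until death or the end of the PSA collection window, with additive
Gaussian noise on the log(PSA+1) scale.

Death times are fully observed unless an administrative censoring time
is set; PSA collection always stops at ``max_followup``.  The generating
truth (psi, eta, uncensored event time) is kept in a separate table so
that prediction code can never see it by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .hazard import SurvivalRecord, cumulative_hazard_arrays
from .model import (
    IndividualParameters,
    LongitudinalRecord,
    PopulationParameters,
    RandomEffects,
    log1p_psa_arrays,
    natural_arrays,
    transform_to_natural,
)

__all__ = [
    "DesignSpec",
    "SimulatedSubject",
    "Cohort",
    "draw_random_effects",
    "simulate_event_time",
    "simulate_longitudinal",
    "simulate_cohort",
]

#: Nodes used on the simulation (truth-generation) path.
TRUTH_NODES = 64
#: Upper bound of the event-time root search (days).
MAX_SEARCH_DAYS = 1e5
#: Cap on the bracketing objective, far above any realistic -log(u).
_H_CAP = 1e6


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design of a simulated cohort.

    ``max_followup`` bounds PSA collection only; ``admin_censor``
    (None = never) administratively censors the survival time itself.
    """

    n_subjects: int = 200
    visit_interval: float = 21.0
    max_followup: float = 913.0        # 30 months of 3-weekly PSA
    admin_censor: float | None = None  # death times observed by default
    seed: int = 0

    def __post_init__(self):
        if self.visit_interval <= 0 or self.max_followup <= 0:
            raise ValueError("visit_interval and max_followup must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")


@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    psi_true: IndividualParameters
    eta_true: RandomEffects
    x_true: float                       # uncensored event time, days (inf = never)
    records: list[LongitudinalRecord]
    survival: SurvivalRecord


@dataclass
class Cohort:
    """Observable longitudinal + survival tables, with optional hidden truth."""

    records: list[LongitudinalRecord]
    survival: list[SurvivalRecord]
    subjects: list[SimulatedSubject] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.survival]

    def records_for(self, subject_id: str) -> list[LongitudinalRecord]:
        return [r for r in self.records if r.subject_id == subject_id]


def draw_random_effects(pop: PopulationParameters, n: int, seed) -> list[RandomEffects]:
    """n iid draws eta ~ N(0, diag(omega^2)); reproducible under seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    etas = rng.normal(0.0, 1.0, size=(n, 4)) * pop.omegas
    return [RandomEffects(eta=e) for e in etas]


def _cumhaz_truth(t, psi: IndividualParameters, pop: PopulationParameters):
    r, psa0, eps, tesc = psi.as_arrays()
    return cumulative_hazard_arrays(t, r, psa0, eps, tesc, pop,
                                    n_nodes=TRUTH_NODES, split_at_kink=True)


def simulate_event_time(psi: IndividualParameters, pop: PopulationParameters,
                        u: float) -> float:
    """Invert S(X | psi) = u by bracketed root finding.

    Uses the high-accuracy cumulative hazard (64 nodes, kink split).
    Returns ``inf`` when even the maximal search bound keeps survival
    above u (event beyond any plausible horizon).
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie strictly inside (0, 1)")
    target = -np.log(u)

    def objective(t):
        return float(min(_cumhaz_truth(t, psi, pop), _H_CAP)) - target

    lo, hi = 0.0, 100.0
    while objective(hi) < 0.0:
        lo, hi = hi, hi * 2.0
        if hi > MAX_SEARCH_DAYS:
            return np.inf
    x = brentq(objective, lo, hi, xtol=1e-8, rtol=1e-12)
    return float(x)


def simulate_longitudinal(psi: IndividualParameters, pop: PopulationParameters,
                          design: DesignSpec, seed, subject_id: str = "sim",
                          x_true: float = np.inf) -> list[LongitudinalRecord]:
    """Noisy log(PSA+1) at visits {0, dt, 2dt, ...} up to min(death, window).

    A measurement cannot postdate death: the visit schedule stops at the
    last visit at or before min(x_true, max_followup).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    horizon = min(x_true, design.max_followup)
    times = np.arange(0.0, horizon + 0.5 * design.visit_interval, design.visit_interval)
    times = times[times <= horizon]
    r, psa0, eps, tesc = psi.as_arrays()
    mean = log1p_psa_arrays(times, r, psa0, eps, tesc, pop.d_fixed, pop.delta_elim_fixed)
    y = mean + rng.normal(0.0, pop.sigma, size=times.shape)
    return [LongitudinalRecord(subject_id=subject_id, t=float(t), y=float(v))
            for t, v in zip(times, y)]


def simulate_cohort(pop: PopulationParameters, design: DesignSpec) -> Cohort:
    """Full synthetic cohort; truth retained separately from observables."""
    root = np.random.SeedSequence(design.seed)
    seq_eta, seq_event, seq_long = root.spawn(3)
    rng_eta = np.random.default_rng(seq_eta)
    rng_event = np.random.default_rng(seq_event)
    long_seqs = seq_long.spawn(design.n_subjects)

    etas = draw_random_effects(pop, design.n_subjects, rng_eta)
    subjects = []
    for i, eta in enumerate(etas):
        sid = f"S{i + 1:04d}"
        psi = transform_to_natural(pop, eta)
        u = rng_event.uniform()
        x = simulate_event_time(psi, pop, u)
        if design.admin_censor is not None and x > design.admin_censor:
            T, delta = design.admin_censor, 0
        elif np.isinf(x):
            # event beyond the root-search horizon: censor there
            T, delta = MAX_SEARCH_DAYS, 0
        else:
            T, delta = x, 1
        records = simulate_longitudinal(
            psi, pop, design, np.random.default_rng(long_seqs[i]),
            subject_id=sid, x_true=x)
        subjects.append(SimulatedSubject(
            subject_id=sid, psi_true=psi, eta_true=eta, x_true=x,
            records=records,
            survival=SurvivalRecord(subject_id=sid, T=float(T), delta_event=delta)))
    return Cohort(records=[r for s in subjects for r in s.records],
                  survival=[s.survival for s in subjects],
                  subjects=subjects)


def true_conditional_death_prob(psi: IndividualParameters, pop: PopulationParameters,
                                s: float, t):
    """pi(s+t | s) from the generating psi, on the high-accuracy path."""
    t = np.asarray(t, dtype=float)
    H_s = _cumhaz_truth(np.asarray(s, dtype=float), psi, pop)
    H_st = _cumhaz_truth(s + t, psi, pop)
    return -np.expm1(-(H_st - H_s))
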