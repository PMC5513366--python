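"""Biexponential PSA kinetics and the observation model.

The longitudinal biomarker is log(PSA+1).  PSA dynamics follow a
two-compartment view of treated metastatic prostate cancer: prostatic
cells proliferate at rate ``r`` (day^-1) and die at rate ``d``;
chemotherapy blocks a fraction ``eps`` of proliferation until the escape
time ``tesc`` (days), after which treatment has no effect; PSA produced
by the cells is eliminated from blood at rate ``delta``.  This yields a
piecewise-biexponential closed form with a kink at ``tesc``.

Individual parameters ``psi = (r, psa0, eps, tesc)`` derive from
population fixed effects and Gaussian random effects through log / logit
transforms, so positivity and the (0,1) constraint on ``eps`` hold by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DAYS_PER_MONTH",
    "D_FIXED",
    "DELTA_ELIM_FIXED",
    "PopulationParameters",
    "RandomEffects",
    "IndividualParameters",
    "LongitudinalRecord",
    "transform_to_natural",
    "transform_to_eta",
    "psa_value",
    "log_psa_obs_mean",
    "log_psa_slope",
    "log_psa_area",
]

#: Calendar conversion used at every months<->days interface.
DAYS_PER_MONTH = 365.25 / 12.0

#: Tumor-cell elimination rate (day^-1), half-life ~15 days. Fixed, never estimated.
D_FIXED = 0.046
#: PSA elimination rate from blood (day^-1), half-life ~3 days. Fixed, never estimated.
DELTA_ELIM_FIXED = 0.23

# Guard for the removable singularity in the biexponential solution.
_SINGULARITY_GUARD = 1e-10
# log(PSA) beyond which PSA overflows comfort zone; switch to log-space asymptotics.
_LOG_OVERFLOW = 700.0

_LINK_TYPES = ("none", "current", "slope", "auc")


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class PopulationParameters:
    """Population-level parameter vector of the joint model.

    Defaults are the reference fit of the current-PSA joint model on the
    mCRPC training cohort.  Random-effect standard deviations apply on
    the transformed (log / logit) scale and the covariance is diagonal.
    """

    r_pop: float = 0.054          # proliferation rate, day^-1
    psa0_pop: float = 73.9        # baseline PSA, ng/mL
    eps_pop: float = 0.34         # treatment effectiveness, in (0,1)
    tesc_pop: float = 138.0       # escape time, days
    d_fixed: float = D_FIXED
    delta_elim_fixed: float = DELTA_ELIM_FIXED
    omega_r: float = 0.098
    omega_psa0: float = 1.57
    omega_eps: float = 1.34
    omega_tesc: float = 0.64
    sigma: float = 0.38           # residual SD on log(PSA+1)
    lambda_w: float = 3800.0      # Weibull scale, days
    k_w: float = 1.19             # Weibull shape
    beta_link: float = 0.32
    link_type: str = "current"

    def __post_init__(self):
        for name in ("r_pop", "psa0_pop", "tesc_pop", "lambda_w", "k_w",
                     "sigma", "omega_r", "omega_psa0", "omega_eps", "omega_tesc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.eps_pop < 1.0:
            raise ValueError("eps_pop must lie in the open interval (0, 1)")
        if self.link_type not in _LINK_TYPES:
            raise ValueError(f"link_type must be one of {_LINK_TYPES}")

    @property
    def omegas(self) -> np.ndarray:
        """SDs of (eta_r, eta_psa0, eta_eps, eta_tesc), transformed scale."""
        return np.array([self.omega_r, self.omega_psa0, self.omega_eps, self.omega_tesc])

    def with_link(self, link_type: str, beta_link: float) -> "PopulationParameters":
        return replace(self, link_type=link_type, beta_link=beta_link)


@dataclass(frozen=True)
class RandomEffects:
    """Subject-level deviation vector eta on the transformed scale."""

    eta: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self):
        eta = np.asarray(self.eta, dtype=float)
        if eta.shape != (4,):
            raise ValueError("eta must be a 4-vector")
        if not np.all(np.isfinite(eta)):
            raise ValueError("eta must be finite")
        object.__setattr__(self, "eta", eta)


@dataclass(frozen=True)
class IndividualParameters:
    """Natural-scale kinetic parameters of one subject."""

    r: float
    psa0: float
    eps: float
    tesc: float

    def __post_init__(self):
        if not (self.r > 0 and self.psa0 > 0 and self.tesc > 0):
            raise ValueError("r, psa0 and tesc must be strictly positive")
        if not 0.0 < self.eps < 1.0:
            raise ValueError("eps must lie in (0, 1)")

    def as_arrays(self):
        return (np.asarray(self.r), np.asarray(self.psa0),
                np.asarray(self.eps), np.asarray(self.tesc))


@dataclass(frozen=True)
class LongitudinalRecord:
    """One observation y = log(PSA+1) at time t (days since treatment start)."""

    subject_id: str
    t: float
    y: float

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("observation time must be nonnegative")
        if not np.isfinite(self.y):
            raise ValueError("observation must be finite")


def transform_to_natural(pop: PopulationParameters, eta) -> IndividualParameters:
    """Map random effects to natural-scale individual parameters.

    r, psa0 and tesc are log-normal; eps is logit-normal, so the image
    always satisfies the natural-parameter constraints.
    """
    e = eta.eta if isinstance(eta, RandomEffects) else np.asarray(eta, dtype=float)
    r, p0, ee, te = natural_arrays(pop, e)
    return IndividualParameters(r=float(r), psa0=float(p0), eps=float(ee), tesc=float(te))


def natural_arrays(pop: PopulationParameters, eta: np.ndarray):
    """Vectorized transform: ``eta[..., 4] -> (r, psa0, eps, tesc)`` arrays."""
    eta = np.asarray(eta, dtype=float)
    with np.errstate(over="ignore"):  # absurd eta -> inf, rejected downstream
        r = pop.r_pop * np.exp(eta[..., 0])
        psa0 = pop.psa0_pop * np.exp(eta[..., 1])
        eps = _inv_logit(_logit(pop.eps_pop) + eta[..., 2])
        tesc = pop.tesc_pop * np.exp(eta[..., 3])
    return r, psa0, eps, tesc


def transform_to_eta(pop: PopulationParameters, psi: IndividualParameters) -> RandomEffects:
    """Inverse of :func:`transform_to_natural` (exact round-trip)."""
    eta = np.array([
        np.log(psi.r) - np.log(pop.r_pop),
        np.log(psi.psa0) - np.log(pop.psa0_pop),
        _logit(psi.eps) - _logit(pop.eps_pop),
        np.log(psi.tesc) - np.log(pop.tesc_pop),
    ])
    return RandomEffects(eta=eta)


def _phi(a, t):
    """(exp(a*t) - 1)/a with the removable singularity at a=0 handled."""
    a = np.asarray(a, dtype=float)
    t = np.asarray(t, dtype=float)
    small = np.abs(a) < _SINGULARITY_GUARD
    a_safe = np.where(small, 1.0, a)
    out = np.expm1(a_safe * t) / a_safe
    # second-order series: t*(1 + a t/2), exact to O((a t)^2 t)
    return np.where(small, t * (1.0 + 0.5 * a * t), out)


def _psa_parts(t, r, psa0, eps, tesc, d, delta):
    """Return (psa, log_production) arrays, broadcasting all inputs.

    The closed form is algebraically rearranged as

        on-treatment:  PSA(t) = psa0 e^{-delta t} (1 + delta * phi(a1, t))
        off-treatment: PSA(t) = PSA(tesc) e^{-delta u}
                                + delta psa0 E e^{-delta u} phi(a2, u)

    with a1 = r(1-eps) - d + delta, a2 = r - d + delta, u = t - tesc and
    E = e^{(r(1-eps)-d) tesc}; phi(a,t) = (e^{at}-1)/a.  This form is
    manifestly positive, continuous at tesc, and removes the printed
    formula's poles at a1 = 0 and a2 = 0.

    ``log_production`` is log(psa0) + g(t) with g the piecewise-linear
    growth exponent; PSA'(t) = delta*(e^{log_production} - PSA), and it
    also anchors the log-space asymptotics when PSA overflows.
    """
    t = np.asarray(t, dtype=float)
    b1 = r * (1.0 - eps) - d          # net growth under treatment
    b2 = r - d                        # net growth after escape
    a1 = b1 + delta
    a2 = b2 + delta

    on = t <= tesc
    with np.errstate(over="ignore", invalid="ignore"):
        u = np.where(on, 0.0, t - tesc)
        t_on = np.where(on, t, tesc)

        # on-treatment value evaluated at min(t, tesc)
        psa_on = psa0 * np.exp(-delta * t_on) * (1.0 + delta * _phi(a1, t_on))

        # growth exponent of the production term, piecewise linear in t
        g = np.where(on, b1 * t, b1 * tesc + b2 * u)
        log_prod = np.log(psa0) + g

        psa_off = psa_on * np.exp(-delta * u) + \
            delta * psa0 * np.exp(b1 * tesc) * np.exp(-delta * u) * _phi(a2, u)
        psa = np.where(on, psa_on, psa_off)
    # overflow: dominated by production/elimination balance delta*e^{log_prod}/a2
    big = ~np.isfinite(psa)
    if np.any(big):
        with np.errstate(over="ignore"):
            psa = np.where(big, np.exp(np.minimum(log_prod, _LOG_OVERFLOW)), psa)
    return psa, log_prod


def psa_arrays(t, r, psa0, eps, tesc, d=D_FIXED, delta=DELTA_ELIM_FIXED):
    """Vectorized PSA concentration (ng/mL); broadcasts t against psi arrays."""
    psa, _ = _psa_parts(t, r, psa0, eps, tesc, d, delta)
    return psa


def psa_value(t, psi: IndividualParameters, d: float = D_FIXED,
              delta: float = DELTA_ELIM_FIXED):
    """PSA concentration at time t (days) for one subject.

    Piecewise biexponential, strictly positive and continuous at the
    escape time; accepts scalar or array t.
    """
    r, psa0, eps, tesc = psi.as_arrays()
    out = psa_arrays(t, r, psa0, eps, tesc, d, delta)
    return float(out) if np.isscalar(t) else out


def log1p_psa_arrays(t, r, psa0, eps, tesc, d=D_FIXED, delta=DELTA_ELIM_FIXED):
    """log(PSA(t)+1), switching to the log-space asymptote when PSA overflows."""
    psa, log_prod = _psa_parts(t, r, psa0, eps, tesc, d, delta)
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.log1p(psa)
        huge = log_prod > _LOG_OVERFLOW
        if np.any(huge):
            a2 = r - d + delta
            # log(delta * psa0 * e^{g} / a2); the transient is negligible here
            asym = np.log(delta) + log_prod - np.log(np.maximum(a2, _SINGULARITY_GUARD))
            out = np.where(huge, asym, out)
    return out


def log_psa_obs_mean(t, psi: IndividualParameters, d: float = D_FIXED,
                     delta: float = DELTA_ELIM_FIXED):
    """Mean of the observation model: log(PSA(t)+1); residual SD is sigma."""
    r, psa0, eps, tesc = psi.as_arrays()
    out = log1p_psa_arrays(t, r, psa0, eps, tesc, d, delta)
    return float(out) if np.isscalar(t) else out


def log_psa_slope_arrays(t, r, psa0, eps, tesc, d=D_FIXED, delta=DELTA_ELIM_FIXED):
    """Vectorized d log(PSA+1)/dt; left derivative at the tesc kink.

    Uses the identity PSA'(t) = delta * (psa0 e^{g(t)} - PSA(t)) obtained
    from the underlying production/elimination balance, with g the
    piecewise-linear growth exponent (left branch at t = tesc).
    """
    t = np.asarray(t, dtype=float)
    psa, log_prod = _psa_parts(t, r, psa0, eps, tesc, d, delta)
    # left derivative at the kink: use the on-treatment exponent at t == tesc
    b1 = r * (1.0 - eps) - d
    log_prod = np.where(t == tesc, np.log(psa0) + b1 * t, log_prod)
    with np.errstate(over="ignore"):
        dpsa = delta * (np.exp(np.minimum(log_prod, _LOG_OVERFLOW)) - psa)
    return dpsa / (psa + 1.0)


def log_psa_slope(t, psi: IndividualParameters, d: float = D_FIXED,
                  delta: float = DELTA_ELIM_FIXED):
    """Derivative of log(PSA+1) at t (day^-1); left derivative at tesc."""
    r, psa0, eps, tesc = psi.as_arrays()
    out = log_psa_slope_arrays(t, r, psa0, eps, tesc, d, delta)
    return float(out) if np.isscalar(t) else out


def _leggauss(n):
    return np.polynomial.legendre.leggauss(n)


def log_psa_area_arrays(t, r, psa0, eps, tesc, d=D_FIXED,
                        delta=DELTA_ELIM_FIXED, n_nodes: int = 32):
    """Vectorized integral of log(PSA+1) on [0, t], split at the tesc kink."""
    t = np.asarray(t, dtype=float)
    shape = np.broadcast_shapes(t.shape, np.shape(r), np.shape(psa0),
                                np.shape(eps), np.shape(tesc))
    t, r, psa0, eps, tesc = (np.broadcast_to(np.asarray(x, dtype=float), shape)
                             for x in (t, r, psa0, eps, tesc))
    nodes, weights = _leggauss(n_nodes)
    t1 = np.minimum(t, tesc)                     # panel [0, min(t, tesc)]
    t2 = np.maximum(t - tesc, 0.0)               # panel [tesc, t]
    total = np.zeros(shape)
    for t0, length in ((np.zeros(shape), t1), (tesc, t2)):
        half = length / 2.0
        u = t0[..., None] + half[..., None] * (nodes + 1.0)
        vals = log1p_psa_arrays(u, r[..., None], psa0[..., None],
                                eps[..., None], tesc[..., None], d, delta)
        total = total + half * (vals @ weights)
    return total


def log_psa_area(t, psi: IndividualParameters, d: float = D_FIXED,
                 delta: float = DELTA_ELIM_FIXED, n_nodes: int = 32):
    """Area under log(PSA+1) from 0 to t (days), by Gauss-Legendre quadrature."""
    r, psa0, eps, tesc = psi.as_arrays()
    out = log_psa_area_arrays(t, r, psa0, eps, tesc, d, delta, n_nodes)
    return float(out) if np.isscalar(t) else out
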