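"""Synthetic cohort generation for biomarker-treatment interaction studies.

Each subject carries a binary marker ``M`` (1 = high level) and a binary
treatment ``T`` (1 = experimental).  The joint distribution of ``(M, T)`` is
fixed by the marker prevalence ``p_M``, the treated fraction ``p_T`` and the
marker-treatment odds ratio ``or_MT``.  Event times follow a proportional
hazards model with an exponential (or Weibull) baseline, calibrated so that a
fraction ``q_e`` of reference-group subjects (M=0, T=0) experience the event
by the administrative horizon ``t_end``.  Censoring is non-differential: an
independent exponential time calibrated to ``q_c``, never reading ``M`` or
``T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "cell_probabilities",
    "rate_parameter",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
]

COHORT_COLUMNS = ["id", "M", "T", "time", "event"]


@dataclass(frozen=True)
class ScenarioConfig:
    """All generator and analysis parameters for one simulation scenario.

    Hazard ratios are on the Cox scale: ``hr_M`` for high vs. low marker
    under standard treatment, ``hr_T`` for experimental vs. standard
    treatment at low marker, ``hr_I`` the ratio of treatment hazard ratios
    between marker levels.  ``q_e`` and ``q_c`` are the event and
    (non-administrative) censoring fractions reached by ``t_end`` in the
    reference group.
    """

    n: int = 600
    p_M: float = 0.25
    p_T: float = 0.5
    or_MT: float = 1.0
    hr_M: float = 1.0
    hr_T: float = 1.0
    hr_I: float = 0.5
    q_e: float = 0.2
    q_c: float = 0.2
    t_end: float = 5.0
    baseline: str = "exponential"
    weibull_shape: float = 1.5
    n_reps: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("cohort size n must be >= 4")
        for name in ("p_M", "p_T", "q_e"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if not 0.0 <= self.q_c < 1.0:
            raise ValueError(f"q_c must lie in [0, 1); got {self.q_c}")
        for name in ("or_MT", "hr_M", "hr_T", "hr_I", "t_end"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive; got {v}")
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError("baseline must be 'exponential' or 'weibull'")
        if self.baseline == "weibull" and self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        # fail fast on infeasible (p_M, p_T, or_MT)
        cell_probabilities(self.p_M, self.p_T, self.or_MT)

    @property
    def beta_M(self) -> float:
        return math.log(self.hr_M)

    @property
    def beta_T(self) -> float:
        return math.log(self.hr_T)

    @property
    def beta_I(self) -> float:
        return math.log(self.hr_I)

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


def cell_probabilities(p_M: float, p_T: float, or_MT: float):
    """Joint (M, T) cell probabilities with given margins and odds ratio.

    Returns ``(p00, p01, p10, p11)`` indexed by ``(M, T)`` such that
    ``p10 + p11 = p_M``, ``p01 + p11 = p_T`` and
    ``p11 * p00 / (p10 * p01) = or_MT``.

    The joint cell ``p11`` solves the quadratic implied by the odds-ratio
    constraint under the margin equations; for ``or_MT != 1`` the admissible
    root is the one inside ``(max(0, p_M + p_T - 1), min(p_M, p_T))``, which
    is unique for any finite positive odds ratio.
    """
    if not (0 < p_M < 1 and 0 < p_T < 1):
        raise ValueError("margins must lie in (0, 1)")
    if or_MT <= 0:
        raise ValueError("or_MT must be positive")
    lo = max(0.0, p_M + p_T - 1.0)
    hi = min(p_M, p_T)
    if or_MT == 1.0:
        p11 = p_M * p_T
    else:
        # OR*(p_M - p11)*(p_T - p11) = p11*(1 - p_M - p_T + p11)
        a = or_MT - 1.0
        b = -(or_MT * (p_M + p_T) + (1.0 - p_M - p_T))
        c = or_MT * p_M * p_T
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError("infeasible margin/odds-ratio combination")
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
        inside = [r for r in roots if lo < r < hi]
        if not inside:
            raise ValueError("infeasible margin/odds-ratio combination")
        p11 = inside[0]
    p10 = p_M - p11
    p01 = p_T - p11
    p00 = 1.0 - p_M - p_T + p11
    cells = (p00, p01, p10, p11)
    if any(p <= 0 for p in cells):
        raise ValueError("margins/odds ratio imply a non-positive cell")
    return cells


def rate_parameter(q: float, t_end: float) -> float:
    """Exponential rate reaching cumulative event fraction ``q`` by ``t_end``.

    ``lambda = -log(1 - q) / t_end`` so the survival function satisfies
    ``S(t_end) = 1 - q``.  ``q = 0`` returns 0 (no censoring).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if q == 0:
        return 0.0
    if not 0 < q < 1:
        raise ValueError(f"q must lie in [0, 1); got {q}")
    return -math.log1p(-q) / t_end


def _weibull_scale(q: float, t_end: float, shape: float) -> float:
    # S(t_end) = exp(-(t_end/scale)^shape) = 1 - q
    return t_end / (-math.log1p(-q)) ** (1.0 / shape)


def generate_cohort(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate one cohort as a DataFrame with columns id, M, T, time, event.

    Event times use inverse-CDF sampling under proportional hazards; the
    censoring time is drawn from the reference-group distribution for every
    subject (non-differential censoring).  A subject is an event at ``t_e``
    iff ``t_e < min(t_c, t_end)`` and is otherwise censored at
    ``min(t_c, t_end)``.
    """
    n = config.n
    p00, p01, p10, p11 = cell_probabilities(config.p_M, config.p_T, config.or_MT)
    cell = rng.choice(4, size=n, p=[p00, p01, p10, p11])
    M = (cell >= 2).astype(np.int64)
    T = (cell % 2).astype(np.int64)

    lin = config.beta_M * M + config.beta_T * T + config.beta_I * M * T
    u_e = rng.uniform(size=n)
    if config.baseline == "exponential":
        lam_e = rate_parameter(config.q_e, config.t_end)
        t_e = -np.log(u_e) / (lam_e * np.exp(lin))
    else:
        shape = config.weibull_shape
        scale = _weibull_scale(config.q_e, config.t_end, shape)
        t_e = scale * (-np.log(u_e) / np.exp(lin)) ** (1.0 / shape)

    # censoring: same generator family with all covariate effects zero
    u_c = rng.uniform(size=n)
    lam_c = rate_parameter(config.q_c, config.t_end)
    if lam_c == 0.0:
        t_c = np.full(n, np.inf)
    elif config.baseline == "exponential":
        t_c = -np.log(u_c) / lam_c
    else:
        scale_c = _weibull_scale(config.q_c, config.t_end, config.weibull_shape)
        t_c = scale_c * (-np.log(u_c)) ** (1.0 / config.weibull_shape)

    horizon = np.minimum(t_c, config.t_end)
    event = t_e < horizon
    time = np.where(event, t_e, horizon)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "M": M,
            "T": T,
            "time": time,
            "event": event.astype(np.int64),
        }
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    return df[COHORT_COLUMNS].astype(
        {"id": np.int64, "M": np.int64, "T": np.int64, "time": float, "event": np.int64}
    )
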