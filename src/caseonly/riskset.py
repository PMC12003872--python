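"""Case-only dataset construction.

The case-only design keeps only subjects who experienced the event.  For a
case failing at time ``t_e`` the full-cohort risk set at ``t_e`` (everyone
with follow-up time >= ``t_e``, the failing case included) determines an
offset ``log(p_e / (1 - p_e))``, where ``p_e`` is the experimental-arm
fraction of that risk set.  The offset absorbs the changing treatment-arm
composition over follow-up, so a logistic regression of treatment on marker
among cases recovers the interaction coefficient; non-cases contribute only
their follow-up times and treatment arms, never a marker measurement.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "risk_set_fraction",
    "build_case_only",
    "write_case_only",
    "caseonly_design",
]

logger = logging.getLogger(__name__)

CASEONLY_COLUMNS = ["id", "M", "T", "t_e", "offset"]


def risk_set_fraction(cohort: pd.DataFrame, t: float) -> float:
    """Experimental-arm fraction of the risk set at time ``t``.

    Risk-set membership is ``time >= t``.  Raises if nobody is at risk.
    """
    at_risk = cohort["time"].to_numpy() >= t
    n_risk = int(at_risk.sum())
    if n_risk == 0:
        raise ValueError(f"empty risk set at t={t}")
    return float(cohort["T"].to_numpy()[at_risk].sum()) / n_risk


def build_case_only(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per event with its risk-set offset.

    Ties share the risk set evaluated at their common event time.  Cases with
    a degenerate risk-set fraction (``p_e`` of 0 or 1, infinite offset) are
    dropped; the number dropped is recorded in ``df.attrs['n_degenerate']``
    and logged.

    Returns a DataFrame with columns id, M, T, t_e, offset plus the subgroup
    indicators M_low = 1 - M and M_high = M.
    """
    cases = cohort[cohort["event"] == 1]
    if len(cases) == 0:
        raise ValueError("cohort has no events; case-only dataset is empty")

    times = cohort["time"].to_numpy()
    treat = cohort["T"].to_numpy()
    order = np.argsort(times)[::-1]  # descending: cumulative sums give risk sets
    t_sorted = times[order]
    n_risk_cum = np.arange(1, len(times) + 1)
    n_treat_cum = np.cumsum(treat[order])

    t_e = cases["time"].to_numpy()
    # number at risk at t = count of follow-up times >= t
    idx = np.searchsorted(-t_sorted, -t_e, side="right") - 1
    n_risk = n_risk_cum[idx]
    n_treat = n_treat_cum[idx]
    p_e = n_treat / n_risk

    out = pd.DataFrame(
        {
            "id": cases["id"].to_numpy(),
            "M": cases["M"].to_numpy(),
            "T": cases["T"].to_numpy(),
            "t_e": t_e,
            "p_e": p_e,
        }
    )
    degenerate = (p_e <= 0.0) | (p_e >= 1.0)
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("dropping %d case(s) with degenerate risk-set fraction", n_deg)
    out = out[~degenerate].copy()
    with np.errstate(divide="ignore"):
        out["offset"] = np.log(out["p_e"] / (1.0 - out["p_e"]))
    out["M_low"] = 1 - out["M"]
    out["M_high"] = out["M"]
    out = out.reset_index(drop=True)
    out.attrs["n_degenerate"] = n_deg
    return out


def write_case_only(case_only: pd.DataFrame, path) -> None:
    case_only.to_csv(path, index=False, columns=CASEONLY_COLUMNS)


def caseonly_design(case_only: pd.DataFrame, parametrization: str):
    """Design matrix, response and names for the case-only logistic model.

    ``interaction``: columns (1, M) with coefficients (gamma_T, gamma_I) —
    the treatment log-odds at low marker plus the interaction contrast.
    ``subgroup``: columns (M_low, M_high) with coefficients
    (gamma_TM_low, gamma_TM_high) — treatment log-odds within each marker
    level.  The response is the treatment indicator; the offset column is
    passed to the fitter separately.
    """
    M = case_only["M"].to_numpy(float)
    y = case_only["T"].to_numpy(float)
    if parametrization == "interaction":
        X = np.column_stack([np.ones_like(M), M])
        names = ("gamma_T", "gamma_I")
    elif parametrization == "subgroup":
        X = np.column_stack([1.0 - M, M])
        names = ("gamma_TM_low", "gamma_TM_high")
    else:
        raise ValueError(f"unknown parametrization {parametrization!r}")
    return X, y, names
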