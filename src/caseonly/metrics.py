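"""Simulation performance measures: bias, SE accuracy, coverage, power.

Measures follow the standard simulation-study repertoire: bias (and relative
bias in % when the true value is nonzero), empirical vs. model-based
standard error, CI coverage, and rejection rate of the interaction null —
labelled type-I error when the true interaction is zero and power otherwise.

Two filters apply before anything is averaged: a dataset is *eligible* only
if at least three of the four (marker, treatment) cells contain an event,
and only converged model fits enter the summaries (count ``N_c``).
Profile-likelihood coverage and power are additionally restricted to
replicates where both profile bounds converged (count ``N_c_pl_bounds``),
since an unconverged bound cannot be compared against zero or the truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["eligibility", "cell_event_counts", "summarize"]


def cell_event_counts(cohort: pd.DataFrame) -> np.ndarray:
    """2x2 event counts indexed [M, T]."""
    counts = np.zeros((2, 2), dtype=int)
    ev = cohort[cohort["event"] == 1]
    for (m, t), grp in ev.groupby(["M", "T"]):
        counts[int(m), int(t)] = len(grp)
    return counts


def eligibility(counts) -> bool:
    """True iff at least 3 of the 4 (M, T) cells contain >= 1 event."""
    counts = np.asarray(counts).ravel()
    if counts.size != 4:
        raise ValueError("expected 4 cell counts")
    return int((counts >= 1).sum()) >= 3


def _pct(x) -> float:
    return float(100.0 * x)


def summarize(records: pd.DataFrame, truth: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Per-coefficient performance summary over replicate fit records.

    ``records`` holds one row per replicate with columns ``eligible``,
    ``converged``, ``n_events`` and, per coefficient ``c``: ``est_c``,
    ``var_c``, ``wald_lo_c``, ``wald_hi_c`` and optionally ``pl_lo_c``,
    ``pl_hi_c``, ``pl_ok_c``.  ``truth`` maps coefficient names to their
    generating values.  Coefficients with true value 0 get absolute bias
    only (relative bias undefined) and their rejection rate is labelled
    type-I error.

    Returns one row per coefficient.  Raises if no replicate survives the
    eligibility and convergence filters.
    """
    used = records[(records["eligible"]) & (records["converged"])]
    n_c = len(used)
    if n_c == 0:
        raise ValueError("no eligible converged replicates to summarize")
    rows = []
    for name, beta0 in truth.items():
        est = used[f"est_{name}"].to_numpy(float)
        var = used[f"var_{name}"].to_numpy(float)
        bias = float(np.mean(est) - beta0)
        rel_bias = _pct(bias / abs(beta0)) if beta0 != 0 else np.nan
        emp_se = float(np.std(est, ddof=1)) if n_c > 1 else np.nan
        mod_se = float(np.sqrt(np.mean(var)))
        rel_err_modse = (
            _pct(mod_se / emp_se - 1.0) if emp_se and np.isfinite(emp_se) else np.nan
        )
        w_lo = used[f"wald_lo_{name}"].to_numpy(float)
        w_hi = used[f"wald_hi_{name}"].to_numpy(float)
        cover_w = _pct(np.mean((w_lo <= beta0) & (beta0 <= w_hi)))
        power_w = _pct(np.mean((w_lo > 0.0) | (w_hi < 0.0)))
        row = {
            "coefficient": name,
            "truth": beta0,
            "bias": bias,
            "relative_bias_pct": rel_bias,
            "EmpSE": emp_se,
            "ModSE": mod_se,
            "rel_err_ModSE_pct": rel_err_modse,
            "coverage_wald_pct": cover_w,
            "power_or_type1_wald_pct": power_w,
            "is_type1": beta0 == 0,
            "N_c": n_c,
            "mean_events": float(used["n_events"].mean()),
        }
        if f"pl_ok_{name}" in used.columns:
            ok = used[f"pl_ok_{name}"].to_numpy(bool)
            sub = used[ok]
            n_pl = len(sub)
            row["N_c_pl_bounds"] = n_pl
            if n_pl:
                p_lo = sub[f"pl_lo_{name}"].to_numpy(float)
                p_hi = sub[f"pl_hi_{name}"].to_numpy(float)
                row["coverage_pl_pct"] = _pct(np.mean((p_lo <= beta0) & (beta0 <= p_hi)))
                row["power_or_type1_pl_pct"] = _pct(np.mean((p_lo > 0.0) | (p_hi < 0.0)))
            else:
                row["coverage_pl_pct"] = np.nan
                row["power_or_type1_pl_pct"] = np.nan
        else:
            row["N_c_pl_bounds"] = 0
            row["coverage_pl_pct"] = np.nan
            row["power_or_type1_pl_pct"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
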