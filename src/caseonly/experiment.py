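"""Scenario-grid orchestration: replication, seeding, filtering, reporting.

A scenario is one ScenarioConfig; a grid is the cross product of scenario
parameters with everything else held fixed.  Replicate ``j`` of a scenario
draws from an independent substream derived from the scenario seed and
``j``, so any single dataset can be regenerated in isolation and results do
not depend on execution order.  The scenario seed itself is derived from
the master seed and the scenario's parameter fingerprint, making grid
output invariant to scenario ordering.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, riskset
from .firth_cox import fit_cox
from .firth_logistic import fit_logistic
from .simdata import ScenarioConfig, generate_cohort

__all__ = ["GridSpec", "run_scenario", "run_grid", "scenario_id", "truth_for"]

METHODS = ("caseonly_firth", "caseonly_ml", "cox_firth")

_CASEONLY_TRUTH = {
    "interaction": {"gamma_T": "beta_T", "gamma_I": "beta_I"},
    "subgroup": {"gamma_TM_low": "beta_TM_low", "gamma_TM_high": "beta_TM_high"},
}
_COX_TRUTH = {
    "interaction": {"beta_M": "beta_M", "beta_T": "beta_T", "beta_I": "beta_I"},
    "subgroup": {
        "beta_M": "beta_M",
        "beta_TM_low": "beta_TM_low",
        "beta_TM_high": "beta_TM_high",
    },
}


def truth_for(config: ScenarioConfig, method: str, parametrization: str) -> dict:
    """Generating values for each estimated coefficient.

    Case-only coefficients are evaluated against the Cox-scale truths
    (gamma ~ beta under marker-treatment independence, non-differential
    censoring and rare events); subgroup truths are
    beta_TM_low = log HR_T and beta_TM_high = log(HR_T * HR_I).
    """
    base = {
        "beta_M": config.beta_M,
        "beta_T": config.beta_T,
        "beta_I": config.beta_I,
        "beta_TM_low": config.beta_T,
        "beta_TM_high": config.beta_T + config.beta_I,
    }
    table = _COX_TRUTH if method == "cox_firth" else _CASEONLY_TRUTH
    return {name: base[key] for name, key in table[parametrization].items()}


def scenario_id(config: ScenarioConfig) -> str:
    return (
        f"n{config.n}_pM{config.p_M:g}_pT{config.p_T:g}_orMT{config.or_MT:g}"
        f"_hrM{config.hr_M:g}_hrT{config.hr_T:g}_hrI{config.hr_I:g}"
        f"_qe{config.q_e:g}_qc{config.q_c:g}"
    )


def _scenario_seed_seq(master_seed: int, sid: str) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(master_seed), zlib.crc32(sid.encode())))


def replicate_rng(master_seed: int, sid: str, j: int) -> np.random.Generator:
    """Independent stream for dataset ``j`` of a scenario."""
    ss = _scenario_seed_seq(master_seed, sid)
    return np.random.default_rng(ss.spawn(j + 1)[j])


def _fit_record(method, parametrization, cohort, case_only, level, pl_names):
    """Fit one model and flatten it into a record dict; never raises."""
    rec = {"method": method, "parametrization": parametrization, "converged": False}
    try:
        if method == "cox_firth":
            res = fit_cox(cohort, parametrization, firth=True, level=level)
        else:
            X, y, names = riskset.caseonly_design(case_only, parametrization)
            res = fit_logistic(
                X, y,
                offset=case_only["offset"].to_numpy(),
                firth=(method == "caseonly_firth"),
                names=names,
                level=level,
            )
    except (ValueError, np.linalg.LinAlgError) as err:
        rec["error"] = str(err)
        return rec
    rec["converged"] = res.converged
    rec["iterations"] = res.iterations
    model = res.model
    for j, nm in enumerate(res.names):
        rec[f"est_{nm}"] = res.coefficients[nm]
        rec[f"var_{nm}"] = res.model_se[nm] ** 2
        rec[f"wald_lo_{nm}"], rec[f"wald_hi_{nm}"] = res.wald_ci[nm]
        rec[f"p_wald_{nm}"] = res.p_value[nm]
        if res.converged and pl_names is not None and nm in pl_names:
            (lo, hi), (ok_lo, ok_hi) = model.profile_ci(j, level)
            rec[f"pl_lo_{nm}"] = lo
            rec[f"pl_hi_{nm}"] = hi
            rec[f"pl_ok_{nm}"] = bool(ok_lo and ok_hi)
    return rec


def run_scenario(
    config: ScenarioConfig,
    methods=("caseonly_firth", "cox_firth"),
    parametrizations=("interaction",),
    ci="both",
    level=0.95,
    alpha=0.05,
    pl_names=None,
    n_reps=None,
):
    """Run one scenario: generate, filter, fit, summarize.

    ``ci='wald'`` skips profile-likelihood bounds (they dominate runtime);
    ``pl_names`` restricts PL bounds to the listed coefficients (default:
    the interaction-type coefficients only).  Returns ``(records,
    summaries)`` where ``records`` has one row per replicate x method x
    parametrization and ``summaries`` maps ``(method, parametrization)`` to
    a per-coefficient metrics table.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    if not methods:
        raise ValueError("methods must be non-empty")
    sid = scenario_id(config)
    reps = config.n_reps if n_reps is None else n_reps
    if ci == "wald":
        pl_names = set()
    elif pl_names is None:
        pl_names = {"gamma_I", "beta_I", "gamma_TM_low", "gamma_TM_high",
                    "beta_TM_low", "beta_TM_high"}
    else:
        pl_names = set(pl_names)

    ss = _scenario_seed_seq(config.seed, sid)
    streams = ss.spawn(reps)
    needs_caseonly = any(m.startswith("caseonly") for m in methods)
    rows = []
    for j in range(reps):
        rng = np.random.default_rng(streams[j])
        cohort = generate_cohort(config, rng)
        counts = metrics.cell_event_counts(cohort)
        eligible = metrics.eligibility(counts)
        n_events = int(cohort["event"].sum())
        base = {
            "scenario": sid,
            "j": j,
            "eligible": eligible,
            "n_events": n_events,
            "e00": counts[0, 0], "e01": counts[0, 1],
            "e10": counts[1, 0], "e11": counts[1, 1],
        }
        if not eligible:
            for method in methods:
                for par in parametrizations:
                    rows.append(base | {"method": method, "parametrization": par,
                                        "converged": False})
            continue
        case_only = None
        n_degenerate = 0
        if needs_caseonly:
            case_only = riskset.build_case_only(cohort)
            n_degenerate = case_only.attrs["n_degenerate"]
        for method in methods:
            for par in parametrizations:
                rec = _fit_record(method, par, cohort, case_only, level, pl_names)
                rows.append(base | {"n_degenerate": n_degenerate} | rec)

    records = pd.DataFrame(rows)
    summaries = {}
    for method in methods:
        for par in parametrizations:
            sub = records[(records["method"] == method)
                          & (records["parametrization"] == par)]
            truth = truth_for(config, method, par)
            summ = metrics.summarize(sub, truth, alpha=alpha)
            summ.insert(0, "scenario", sid)
            summ.insert(1, "method", method)
            summ.insert(2, "parametrization", par)
            summaries[(method, par)] = summ
    return records, summaries


@dataclass
class GridSpec:
    """Scenario grid; defaults are the full study grid."""

    n: tuple = (200, 300, 400, 500, 600, 800, 1000)
    p_M: tuple = (0.25, 0.5, 0.75)
    hr_M: tuple = (0.6, 0.8, 1.0, 3.0, 6.0)
    or_MT: tuple = (0.5, 1.0, 2.0)
    hr_I: tuple = (0.25, 0.5, 0.75, 1.0)
    p_T: float = 0.5
    q_e: float = 0.2
    q_c: float = 0.2
    t_end: float = 5.0
    hr_T: float = 1.0
    n_reps: int = 10000
    seed: int = 0
    methods: tuple = ("caseonly_firth", "cox_firth")
    parametrizations: tuple = ("interaction", "subgroup")
    ci: str = "both"
    outdir: str | None = None

    def configs(self):
        for n, p_M, hr_M, or_MT, hr_I in itertools.product(
            self.n, self.p_M, self.hr_M, self.or_MT, self.hr_I
        ):
            yield ScenarioConfig(
                n=n, p_M=p_M, p_T=self.p_T, or_MT=or_MT, hr_M=hr_M,
                hr_T=self.hr_T, hr_I=hr_I, q_e=self.q_e, q_c=self.q_c,
                t_end=self.t_end, n_reps=self.n_reps, seed=self.seed,
            )


def run_grid(grid: GridSpec) -> pd.DataFrame:
    """Run every scenario in the grid; returns the concatenated summary.

    With ``grid.outdir`` set, one summary CSV per scenario is written and
    scenarios whose CSV already exists are loaded instead of re-run, plus a
    concatenated ``grid_summary.csv``.
    """
    if not grid.methods:
        raise ValueError("methods must be non-empty")
    outdir = Path(grid.outdir) if grid.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    parts = []
    for config in grid.configs():
        sid = scenario_id(config)
        dest = outdir / f"{sid}.csv" if outdir else None
        if dest is not None and dest.exists():
            parts.append(pd.read_csv(dest))
            continue
        _, summaries = run_scenario(
            config, methods=grid.methods,
            parametrizations=grid.parametrizations, ci=grid.ci,
        )
        summ = pd.concat(summaries.values(), ignore_index=True)
        if dest is not None:
            summ.to_csv(dest, index=False)
        parts.append(summ)
    table = pd.concat(parts, ignore_index=True)
    if outdir:
        table.to_csv(outdir / "grid_summary.csv", index=False)
    return table
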