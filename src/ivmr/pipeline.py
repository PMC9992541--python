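"""End-to-end orchestration: per-exposure MR workflow and report tables.

The per-exposure workflow is: instrument selection -> LD clumping ->
harmonization -> IVW (fixed/random chosen by the I-squared rule) with the
full sensitivity battery (Egger with SIMEX fallback, weighted median/mode,
Cochran's Q, pleiotropy test, MR-PRESSO, leave-one-out, strength metrics,
power). Variants of the workflow cover strict MR (pleiotropy-blacklisted
instruments removed), multivariable MR, and relaxed-threshold selection
paired with the debiased IVW estimator. Reports are emitted as three tables
(strength, estimates, sensitivity) plus per-plot CSV data and a harmonized
audit trail, so every reported number can be recomputed from the audit files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, estimators
from .harmonize import DEFAULT_PALINDROME_EAF_WINDOW, build_mvmr_set, harmonize
from .instruments import clump, select_instruments, subtract_blacklist
from .io import read_blacklist, read_ld_matrix, read_sumstats
from .types import (
    HarmonizedSet,
    InstrumentConfig,
    LDMatrix,
    MREstimate,
    PowerParams,
    SummaryTable,
)

logger = logging.getLogger(__name__)

DEFAULT_RELAXED_P = 5e-6
DEFAULT_TRUE_OR = 1.05


@dataclass
class ExposureSpec:
    label: str
    sumstats: str
    blacklist: str | None = None


@dataclass
class AnalysisPlan:
    """Declarative description of a full study (loadable from YAML)."""

    exposures: list[ExposureSpec]
    outcome: str
    n_cases: int | None = None
    n_controls: int | None = None
    ld_matrix: str | None = None
    thresholds: InstrumentConfig = field(default_factory=InstrumentConfig)
    relaxed_p: float = DEFAULT_RELAXED_P
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW
    mvmr_groups: list[list[str]] = field(default_factory=list)
    true_or: float = DEFAULT_TRUE_OR
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.exposures:
            raise ValueError("plan needs at least one exposure")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisPlan":
        raw = yaml.safe_load(Path(str(path)).read_text())
        exposures = [ExposureSpec(**e) for e in raw.pop("exposures")]
        thresholds = InstrumentConfig(**raw.pop("thresholds", {}))
        return cls(exposures=exposures, thresholds=thresholds, **raw)


@dataclass
class ExposureReport:
    """One exposure's results: estimate rows, diagnostics, and plot data."""

    label: str
    n_snps: int
    estimates: list[MREstimate] = field(default_factory=list)
    egger: object | None = None
    heterogeneity: object | None = None
    pleiotropy: tuple | None = None
    presso: object | None = None
    strength: object | None = None
    power: float | None = None
    i2_gx: float | None = None
    conditional_f: float | None = None
    divw: MREstimate | None = None
    divw_ivw: MREstimate | None = None
    n_relaxed: int | None = None
    harmonized: HarmonizedSet | None = None
    plots: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)
    error: str | None = None


def _estimate_row(est: MREstimate | None) -> dict:
    if est is None:
        return {"OR": math.nan, "ci_low": math.nan, "ci_high": math.nan, "p": math.nan}
    lo, hi = est.or_ci
    return {"OR": est.odds_ratio, "ci_low": lo, "ci_high": hi, "p": est.pval}


def run_univariable(
    exposure: SummaryTable,
    outcome: SummaryTable,
    ld: LDMatrix | None = None,
    cfg: InstrumentConfig | None = None,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
    true_or: float = DEFAULT_TRUE_OR,
    seed: int = 0,
    presso_nsim: int = 1000,
    bootstrap_B: int = 1000,
    select: bool = True,
) -> ExposureReport:
    """The primary per-exposure workflow.

    Single-instrument exposures degrade to the Wald ratio with multi-SNP
    diagnostics skipped (reasons recorded in ``skipped``); any stage failure
    is caught into ``error`` so a multi-exposure run continues.
    """
    cfg = cfg or InstrumentConfig()
    label = exposure.trait_label
    report = ExposureReport(label=label, n_snps=0)
    try:
        table = select_instruments(exposure, cfg) if select else exposure
        if ld is not None:
            table, _ = clump(table, ld, cfg)
        if len(table) == 0:
            report.error = "no instruments survive selection"
            return report
        hset = harmonize(table, outcome, palindrome_eaf_window)
        report.harmonized = hset
        k = hset.n_snps
        report.n_snps = k
        if k == 0:
            report.error = "no instruments survive harmonization"
            return report

        est, het = estimators.ivw(hset)
        report.estimates.append(est)
        report.heterogeneity = het

        if k >= 3:
            egger_res = estimators.egger(hset)
            report.i2_gx = egger_res.i2_gx
            if egger_res.i2_gx is not None and egger_res.i2_gx < 0.9:
                egger_res = estimators.simex_egger(hset, seed=seed)
            report.egger = egger_res
            report.estimates.append(egger_res.slope)
            report.pleiotropy = (
                egger_res.intercept, egger_res.intercept_se, egger_res.intercept_pval,
            )
            report.estimates.append(
                estimators.weighted_median(hset, B=bootstrap_B, seed=seed + 1)
            )
            report.estimates.append(
                estimators.weighted_mode(hset, B=bootstrap_B, seed=seed + 2)
            )
        else:
            report.skipped["egger"] = report.skipped["weighted_median"] = \
                report.skipped["weighted_mode"] = f"requires >=3 SNPs, have {k}"
            if k >= 2:
                report.i2_gx = estimators.i2_gx(hset)

        if k >= 4:
            report.presso = diagnostics.mr_presso(hset, nsim=presso_nsim, seed=seed + 3)
        else:
            report.skipped["mr_presso"] = f"requires >=4 SNPs, have {k}"

        strength = diagnostics.snp_strength(hset)
        report.strength = strength
        if (
            outcome.n_cases and outcome.n_controls
            and math.isfinite(strength.total_r2) and strength.total_r2 > 0
        ):
            report.power = diagnostics.power_binary(
                PowerParams(
                    n_cases=outcome.n_cases,
                    n_controls=outcome.n_controls,
                    r2=strength.total_r2,
                    true_or=true_or,
                )
            )

        ratio, precision, _ = diagnostics.funnel_data(hset)
        _, se_ratio, _ = estimators.ratio_estimates(hset)
        report.plots["scatter"] = pd.DataFrame(
            {
                "snp_id": hset.snp_ids,
                "beta_x": hset.beta_x, "se_x": hset.se_x,
                "beta_y": hset.beta_y, "se_y": hset.se_y,
            }
        )
        usable = hset.beta_x != 0
        ids = [s for s, u in zip(hset.snp_ids, usable) if u]
        report.plots["forest"] = pd.DataFrame(
            {
                "snp_id": ids,
                "ratio": ratio,
                "ci_low": ratio - 1.96 * se_ratio,
                "ci_high": ratio + 1.96 * se_ratio,
            }
        )
        report.plots["funnel"] = pd.DataFrame(
            {"snp_id": ids, "ratio": ratio, "precision": precision}
        )
        if k >= 2:
            loo = diagnostics.leave_one_out(hset)
            report.plots["leave_one_out"] = pd.DataFrame(
                {
                    "omitted_snp": hset.snp_ids,
                    "beta": [e.beta for e in loo],
                    "ci_low": [e.ci_low for e in loo],
                    "ci_high": [e.ci_high for e in loo],
                }
            )
        else:
            report.skipped["leave_one_out"] = "requires >=2 SNPs"
    except Exception as exc:  # stage failure: record, let siblings continue
        logger.exception("univariable run failed for %s", label)
        report.error = f"{type(exc).__name__}: {exc}"
    return report


def run_strict(
    exposure: SummaryTable,
    outcome: SummaryTable,
    blacklist: set[str],
    **kwargs,
) -> ExposureReport:
    """Strict MR: remove known-pleiotropic instruments, then rerun."""
    stripped, removed = subtract_blacklist(exposure, blacklist)
    if len(stripped) == 0:
        raise ValueError(
            f"strict MR: blacklist removes all {len(exposure)} instruments "
            f"of {exposure.trait_label}"
        )
    stripped.trait_label = f"strict-{exposure.trait_label}"
    report = run_univariable(stripped, outcome, **kwargs)
    report.skipped["blacklist_removed"] = str(removed)
    return report


def run_mvmr(
    exposures: list[SummaryTable],
    outcome: SummaryTable,
    cfg: InstrumentConfig | None = None,
    ld: LDMatrix | None = None,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> dict[str, ExposureReport]:
    """Multivariable MR over a set of exposures sharing the outcome.

    Each exposure contributes its own selected instruments; refusals (too
    few complete SNPs) surface as a report-level error rather than raising.
    """
    cfg = cfg or InstrumentConfig()
    selected = []
    for t in exposures:
        s = select_instruments(t, cfg)
        if ld is not None:
            s, _ = clump(s, ld, cfg)
        selected.append(s)
    out: dict[str, ExposureReport] = {}
    try:
        mset = build_mvmr_set(selected, outcome, palindrome_eaf_window)
    except ValueError as exc:
        for t in exposures:
            rep = ExposureReport(label=f"MVMR-{t.trait_label}", n_snps=0)
            rep.error = str(exc)
            out[rep.label] = rep
        return out
    ests = estimators.mvmr_ivw(mset)
    cond_f = diagnostics.conditional_f(mset)
    for est in ests:
        rep = ExposureReport(label=f"MVMR-{est.exposure}", n_snps=mset.n_snps)
        est.method = "mvmr_ivw"
        rep.estimates.append(est)
        rep.conditional_f = cond_f[est.exposure]
        out[rep.label] = rep
    return out


def run_relaxed_divw(
    exposure: SummaryTable,
    outcome: SummaryTable,
    ld: LDMatrix | None = None,
    cfg: InstrumentConfig | None = None,
    relaxed_p: float = DEFAULT_RELAXED_P,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> tuple[MREstimate | None, MREstimate | None, int]:
    """Relaxed-threshold selection paired with the debiased IVW estimator.

    Returns (debiased estimate, classical IVW on the same relaxed set,
    number of relaxed instruments). Admitting sub-genome-wide instruments
    buys power at the cost of weak-instrument bias, which the debiased
    estimator removes to first order.
    """
    cfg = dataclasses.replace(cfg or InstrumentConfig(), p_threshold=relaxed_p)
    table = select_instruments(exposure, cfg)
    if ld is not None:
        table, _ = clump(table, ld, cfg)
    if len(table) < 2:
        return None, None, len(table)
    hset = harmonize(table, outcome, palindrome_eaf_window)
    if hset.n_snps < 2:
        return None, None, hset.n_snps
    divw = estimators.debiased_ivw(hset)
    classical, _ = estimators.ivw(hset)
    return divw, classical, hset.n_snps


def apply_fdr(reports: dict[str, ExposureReport]) -> pd.DataFrame:
    """BH-adjust the primary IVW p-values across the exposure family."""
    rows = []
    for label, rep in reports.items():
        primary = next(
            (e for e in rep.estimates if e.method in ("ivw_fixed", "ivw_random", "wald_ratio")),
            None,
        )
        if primary is not None:
            rows.append({"exposure": label, "p": primary.pval})
    if not rows:
        return pd.DataFrame(columns=["exposure", "p", "p_fdr", "significant"])
    df = pd.DataFrame(rows)
    df["p_fdr"] = diagnostics.bh_fdr(df["p"].to_numpy())
    df["significant"] = df["p_fdr"] < 0.05
    return df


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

_METHOD_LABELS = {
    "ivw_fixed": "IVW",
    "ivw_random": "IVW",
    "wald_ratio": "IVW",
    "egger_slope": "MR-Egger",
    "egger_simex": "MR-Egger (SIMEX)",
    "weighted_median": "Weighted median",
    "weighted_mode": "Weighted mode",
    "mvmr_ivw": "MVMR (IVW)",
    "debiased_ivw": "Debiased IVW",
}


def strength_table(reports: dict[str, ExposureReport]) -> pd.DataFrame:
    """Instrument-strength summary, one row per exposure."""
    rows = []
    for label, rep in reports.items():
        st = rep.strength
        divw_row = _estimate_row(rep.divw)
        rows.append(
            {
                "exposure": label,
                "N": rep.n_snps,
                "mean_F": None if st is None else st.mean_f,
                "variance_explained_pct": None if st is None else 100.0 * st.total_r2,
                "power": rep.power,
                "I2_GX": rep.i2_gx,
                "simex_applied": bool(rep.egger and getattr(rep.egger, "simex_applied", False)),
                "conditional_F": rep.conditional_f,
                "dIVW_OR": divw_row["OR"],
                "dIVW_p": divw_row["p"],
                "N_relaxed": rep.n_relaxed,
            }
        )
    return pd.DataFrame(rows)


def estimates_table(reports: dict[str, ExposureReport]) -> pd.DataFrame:
    """Method-by-exposure causal estimate grid (OR, 95% CI, p)."""
    rows = []
    for label, rep in reports.items():
        for est in rep.estimates:
            row = _estimate_row(est)
            rows.append(
                {
                    "exposure": label,
                    "N": est.n_snps,
                    "method": _METHOD_LABELS.get(est.method, est.method),
                    "method_detail": est.method,
                    "beta": est.beta,
                    "se": est.se,
                    **row,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_table(reports: dict[str, ExposureReport]) -> pd.DataFrame:
    """Sensitivity summary: MR-PRESSO, pleiotropy, heterogeneity."""
    rows = []
    for label, rep in reports.items():
        het = rep.heterogeneity
        rows.append(
            {
                "exposure": label,
                "N": rep.n_snps,
                "presso_global_p": None if rep.presso is None else rep.presso.global_p,
                "presso_outliers": None if rep.presso is None else ";".join(rep.presso.outlier_snp_ids),
                "pleiotropy_p": None if rep.pleiotropy is None else rep.pleiotropy[2],
                "cochran_q_p": None if het is None else het.pval,
                "I2_pct": None if het is None else 100.0 * het.i2,
                "heterogeneity_band": None if het is None else het.band,
            }
        )
    return pd.DataFrame(rows)


def write_report(
    reports: dict[str, ExposureReport],
    out_dir,
    fdr: pd.DataFrame | None = None,
) -> None:
    """Write the three report tables, plot data, and harmonization audits."""
    out = Path(str(out_dir))
    out.mkdir(parents=True, exist_ok=True)
    strength_table(reports).to_csv(out / "strength.tsv", sep="\t", index=False)
    estimates_table(reports).to_csv(out / "estimates.tsv", sep="\t", index=False)
    sensitivity_table(reports).to_csv(out / "sensitivity.tsv", sep="\t", index=False)
    if fdr is not None:
        fdr.to_csv(out / "fdr.tsv", sep="\t", index=False)
    summary = {}
    for label, rep in reports.items():
        summary[label] = {
            "n_snps": rep.n_snps,
            "error": rep.error,
            "skipped": rep.skipped,
            "estimates": [
                {
                    "method": e.method, "beta": e.beta, "se": e.se,
                    "or": e.odds_ratio, "p": e.pval,
                }
                for e in rep.estimates
            ],
        }
        pdir = out / "plots" / label
        if rep.plots:
            pdir.mkdir(parents=True, exist_ok=True)
            for name, df in rep.plots.items():
                df.to_csv(pdir / f"{name}.csv", index=False)
        if rep.harmonized is not None:
            adir = out / "audit"
            adir.mkdir(parents=True, exist_ok=True)
            rep.harmonized.to_frame(include_audit=True).to_csv(
                adir / f"{label}.harmonized.tsv", sep="\t", index=False
            )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))


def run_plan(plan: AnalysisPlan, out_dir=None) -> dict[str, ExposureReport]:
    """Execute a full analysis plan from files on disk."""
    outcome, _ = read_sumstats(
        plan.outcome, trait_label="outcome", trait_type="binary",
        n_cases=plan.n_cases, n_controls=plan.n_controls,
    )
    ld = read_ld_matrix(plan.ld_matrix) if plan.ld_matrix else None
    reports: dict[str, ExposureReport] = {}
    tables: dict[str, SummaryTable] = {}
    for spec in plan.exposures:
        table, _ = read_sumstats(spec.sumstats, trait_label=spec.label)
        tables[spec.label] = table
        rep = run_univariable(
            table, outcome, ld=ld, cfg=plan.thresholds,
            palindrome_eaf_window=plan.palindrome_eaf_window,
            true_or=plan.true_or, seed=plan.seed,
        )
        divw, classical, n_rel = run_relaxed_divw(
            table, outcome, ld=ld, cfg=plan.thresholds,
            relaxed_p=plan.relaxed_p,
            palindrome_eaf_window=plan.palindrome_eaf_window,
        )
        rep.divw, rep.divw_ivw, rep.n_relaxed = divw, classical, n_rel
        reports[spec.label] = rep
        if spec.blacklist:
            try:
                reports[f"strict-{spec.label}"] = run_strict(
                    table, outcome, read_blacklist(spec.blacklist),
                    ld=ld, cfg=plan.thresholds,
                    palindrome_eaf_window=plan.palindrome_eaf_window,
                    true_or=plan.true_or, seed=plan.seed,
                )
            except ValueError as exc:
                rep_err = ExposureReport(label=f"strict-{spec.label}", n_snps=0)
                rep_err.error = str(exc)
                reports[rep_err.label] = rep_err
    for group in plan.mvmr_groups:
        group_tables = [tables[g] for g in group if g in tables]
        if len(group_tables) >= 2:
            reports.update(
                run_mvmr(group_tables, outcome, cfg=plan.thresholds, ld=ld,
                         palindrome_eaf_window=plan.palindrome_eaf_window)
            )
    fdr = apply_fdr(
        {k: v for k, v in reports.items() if not k.startswith(("strict-", "MVMR-"))}
    )
    if out_dir is not None:
        write_report(reports, out_dir, fdr=fdr)
    return reports
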