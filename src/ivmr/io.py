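"""Readers and writers for the tab-delimited summary-statistic dialect.

Column names are configurable through a schema mapping so tables exported by
different GWAS pipelines can be ingested without editing files. Rows that
violate record invariants (zero SE, non-ACGT alleles, out-of-range p or EAF)
are rejected individually and reported, never silently dropped.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import LDMatrix, SummaryTable, VariantAssociation

#: default header names, matching the common exported-sumstats convention
DEFAULT_SCHEMA = {
    "snp_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "samplesize",
    "chrom": "chr",
    "pos": "pos",
}

MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


class SchemaError(ValueError):
    """A mandatory column is absent from the input header."""


@dataclass
class RowReport:
    """Per-row rejection report from :func:`read_sumstats`."""

    row: int
    snp_id: str | None
    reasons: list[str] = field(default_factory=list)


def _get(row, col, cast=None):
    if col is None or col not in row or pd.isna(row[col]):
        return None
    value = row[col]
    if cast is not None:
        value = cast(value)
    return value


def read_sumstats(
    path,
    trait_label: str | None = None,
    schema: dict | None = None,
    trait_type: str = "continuous",
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> tuple[SummaryTable, list[RowReport]]:
    """Parse a tab-delimited summary-statistics file.

    Returns the table of valid records and a list of per-row rejection
    reports for rows that failed the record invariants.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [f for f in MANDATORY_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise SchemaError(
            f"missing mandatory column(s) {[colmap[f] for f in missing]} in {path}"
        )

    if trait_label is None:
        trait_label = Path(str(path)).stem

    records: list[VariantAssociation] = []
    reports: list[RowReport] = []
    for i, row in df.iterrows():
        snp = _get(row, colmap["snp_id"])
        reasons: list[str] = []
        try:
            rec = VariantAssociation(
                snp_id=str(snp),
                effect_allele=str(_get(row, colmap["effect_allele"]) or "").upper(),
                other_allele=str(_get(row, colmap["other_allele"]) or "").upper(),
                eaf=_get(row, colmap.get("eaf"), float),
                beta=_get(row, colmap["beta"], float) if _get(row, colmap["beta"]) is not None else math.nan,
                se=_get(row, colmap["se"], float) if _get(row, colmap["se"]) is not None else math.nan,
                pval=_get(row, colmap["pval"], float) if _get(row, colmap["pval"]) is not None else math.nan,
                n=_get(row, colmap.get("n"), lambda v: int(float(v))),
                chrom=_get(row, colmap.get("chrom"), str),
                pos=_get(row, colmap.get("pos"), lambda v: int(float(v))),
            )
        except (TypeError, ValueError) as exc:
            reports.append(RowReport(row=int(i), snp_id=None if snp is None else str(snp),
                                     reasons=[f"unparseable row: {exc}"]))
            continue
        reasons = rec.violations()
        if not math.isfinite(rec.pval):
            reasons.append("pval missing or non-numeric")
        if reasons:
            reports.append(RowReport(row=int(i), snp_id=rec.snp_id, reasons=reasons))
        else:
            records.append(rec)

    table = SummaryTable(
        trait_label=trait_label,
        records=records,
        trait_type=trait_type,
        n_cases=n_cases,
        n_controls=n_controls,
    )
    return table, reports


def write_sumstats(table: SummaryTable, path, schema: dict | None = None) -> None:
    """Write a SummaryTable in the same TSV dialect `read_sumstats` parses."""
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = table.to_frame().rename(columns={k: v for k, v in colmap.items()})
    # keep only columns with at least one value, but never drop mandatory ones
    mandatory = {colmap[f] for f in MANDATORY_FIELDS}
    keep = [c for c in df.columns if c in mandatory or df[c].notna().any()]
    df[keep].to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD r2 matrix as TSV with snp ids as header row and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("LD matrix row and column snp ids disagree")
    return LDMatrix(snp_ids=[str(s) for s in df.columns], r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")


def read_blacklist(path) -> set[str]:
    """One snp_id per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    text = Path(str(path)).read_text()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.split()[0])
    return out


def read_proxy_table(path) -> dict[str, tuple[str, float]]:
    """User-supplied proxy lookup: TSV of target_snp, proxy_snp, r2.

    Stands in for online proxy search services, which this package does not
    call; the best proxy (highest r2) per target is retained.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = [c.lower() for c in df.columns]
    need = {"target_snp", "proxy_snp", "r2"}
    if not need.issubset(df.columns):
        raise SchemaError(f"proxy table must have columns {sorted(need)}")
    best: dict[str, tuple[str, float]] = {}
    for _, row in df.iterrows():
        t, p, r2 = str(row["target_snp"]), str(row["proxy_snp"]), float(row["r2"])
        if t not in best or r2 > best[t][1]:
            best[t] = (p, r2)
    return best
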