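"""Instrument construction: significance/MAF filtering, LD clumping, blacklists.

The selection rules mirror standard MR practice: genome-wide significance
(p < 5e-8, optionally relaxed), a minor-allele-frequency floor, and greedy
LD clumping at a stringent r2 cutoff so the retained variants are
approximately independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .types import InstrumentConfig, LDMatrix, SummaryTable, VariantAssociation

logger = logging.getLogger(__name__)


def select_instruments(
    table: SummaryTable, cfg: InstrumentConfig | None = None
) -> SummaryTable:
    """Keep variants reaching the significance threshold and the MAF floor.

    A record with missing EAF fails the MAF filter in strict mode
    (``cfg.drop_missing_eaf``, the default); relax the flag to keep such
    records. Input order is preserved, and the operation is idempotent.
    """
    cfg = cfg or InstrumentConfig()
    kept: list[VariantAssociation] = []
    for rec in table.records:
        if not (rec.pval < cfg.p_threshold):
            continue
        maf = rec.maf
        if maf is None:
            if cfg.drop_missing_eaf:
                continue
        elif maf < cfg.maf_min:
            continue
        kept.append(rec)
    if not kept:
        logger.warning("no instruments pass selection for %s", table.trait_label)
    return table.with_records(kept)


@dataclass
class ClumpReport:
    kept: list[str] = field(default_factory=list)
    removed: dict[str, str] = field(default_factory=dict)  # snp -> index snp it clumped with
    unresolved: list[str] = field(default_factory=list)    # no LD info, retained with warning


def _within_window(a: VariantAssociation, b: VariantAssociation, window_kb: float) -> bool:
    if a.pos is None or b.pos is None:
        return True  # no positional information: the window cannot exclude the pair
    if a.chrom is not None and b.chrom is not None and a.chrom != b.chrom:
        return False
    return abs(a.pos - b.pos) <= window_kb * 1000.0


def clump(
    table: SummaryTable,
    ld: LDMatrix,
    cfg: InstrumentConfig | None = None,
) -> tuple[SummaryTable, ClumpReport]:
    """Greedy LD clumping by ascending p-value.

    Variants are visited from most to least significant (ties broken by
    ascending snp_id so output is order-invariant) and accepted iff their r2
    with every already-accepted variant inside the distance window is below
    ``cfg.clump_r2``. Variants absent from the LD matrix cannot be assessed;
    they are retained and flagged in the report.
    """
    cfg = cfg or InstrumentConfig()
    report = ClumpReport()

    order = sorted(table.records, key=lambda r: (r.pval, r.snp_id))
    accepted: list[VariantAssociation] = []
    for rec in order:
        if rec.snp_id not in ld:
            logger.warning("%s absent from LD matrix; retained unclumped", rec.snp_id)
            report.unresolved.append(rec.snp_id)
            accepted.append(rec)
            continue
        clash = None
        for kept in accepted:
            if kept.snp_id not in ld:
                continue
            if not _within_window(rec, kept, cfg.clump_window_kb):
                continue
            if ld.r2_between(rec.snp_id, kept.snp_id) >= cfg.clump_r2:
                clash = kept.snp_id
                break
        if clash is None:
            accepted.append(rec)
        else:
            report.removed[rec.snp_id] = clash

    keep_ids = {r.snp_id for r in accepted}
    report.kept = [r.snp_id for r in table.records if r.snp_id in keep_ids]
    # preserve the input table's record order
    return table.with_records([r for r in table.records if r.snp_id in keep_ids]), report


def subtract_blacklist(
    table: SummaryTable, blacklist: set[str]
) -> tuple[SummaryTable, int]:
    """Remove blacklisted variants (e.g. known-pleiotropic SNPs); report count."""
    kept = [r for r in table.records if r.snp_id not in blacklist]
    removed = len(table.records) - len(kept)
    if removed:
        logger.info(
            "%s: removed %d blacklisted instruments (%d -> %d)",
            table.trait_label, removed, len(table.records), len(kept),
        )
    return table.with_records(kept), removed


def substitute_proxies(
    instruments: SummaryTable,
    outcome: SummaryTable,
    proxy_table: dict[str, tuple[str, float]],
    cfg: InstrumentConfig | None = None,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Map instruments missing from the outcome GWAS to user-supplied proxies.

    Returns (substitutions as (target, proxy) pairs, instruments with no
    acceptable proxy). The proxy lookup itself is a user-supplied table; this
    package performs no online searches.
    """
    cfg = cfg or InstrumentConfig()
    outcome_ids = set(outcome.snp_ids)
    substitutions: list[tuple[str, str]] = []
    unproxied: list[str] = []
    for rec in instruments.records:
        if rec.snp_id in outcome_ids:
            continue
        proxy = proxy_table.get(rec.snp_id)
        if proxy is not None and proxy[1] > cfg.proxy_r2_min and proxy[0] in outcome_ids:
            substitutions.append((rec.snp_id, proxy[0]))
        else:
            unproxied.append(rec.snp_id)
    return substitutions, unproxied
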