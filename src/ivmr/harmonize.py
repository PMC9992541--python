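"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR needs both studies' effects expressed for the same allele of
each variant. Four situations arise: the outcome already reports the
exposure's effect allele (kept); it reports the other allele (outcome beta
negated, frequency complemented); it reports the pair on the opposite strand
(recoded via Watson-Crick complement, then matched); or the allele pairs are
irreconcilable (dropped). Palindromic variants (A/T, C/G) are strand-ambiguous
and are resolved by allele frequency only when both studies' frequencies sit
clearly on the same side of 0.5; otherwise they are dropped.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    HarmonizedRecord,
    HarmonizedSet,
    MVMRSet,
    SummaryTable,
    VariantAssociation,
    complement_allele,
    is_palindromic,
)

logger = logging.getLogger(__name__)

#: drop palindromic variants whose EAF falls within 0.5 +/- this window
DEFAULT_PALINDROME_EAF_WINDOW = 0.08


def _record(snp, x: VariantAssociation, y_beta, y_se, y_eaf, status) -> HarmonizedRecord:
    # after alignment the shared effect allele is the exposure's effect allele
    return HarmonizedRecord(
        snp_id=snp,
        beta_x=x.beta, se_x=x.se, eaf_x=x.eaf,
        beta_y=y_beta, se_y=y_se, eaf_y=y_eaf,
        status=status, n_x=x.n,
        effect_allele=x.effect_allele, other_allele=x.other_allele,
    )


def _harmonize_pair(
    x: VariantAssociation, y: VariantAssociation, window: float
) -> HarmonizedRecord:
    snp = x.snp_id
    ea, oa = x.effect_allele, x.other_allele

    if is_palindromic(ea, oa):
        # strand cannot be resolved from alleles; use allele frequencies
        if {y.effect_allele, y.other_allele} != {ea, oa}:
            return _record(snp, x, y.beta, y.se, y.eaf, "dropped_incompatible")
        fx, fy_raw = x.eaf, y.eaf
        fy = fy_raw if y.effect_allele == ea else (None if fy_raw is None else 1 - fy_raw)
        if fx is None or fy is None:
            return _record(snp, x, y.beta, y.se, fy, "dropped_palindromic")
        lo, hi = 0.5 - window, 0.5 + window
        ambiguous = (lo <= fx <= hi) or (lo <= fy <= hi)
        same_side = (fx < 0.5) == (fy < 0.5)
        if ambiguous or not same_side:
            return _record(snp, x, y.beta, y.se, fy, "dropped_palindromic")
        if y.effect_allele == ea:
            return _record(snp, x, y.beta, y.se, fy, "kept")
        return _record(snp, x, -y.beta, y.se, fy, "flipped")

    if (y.effect_allele, y.other_allele) == (ea, oa):
        return _record(snp, x, y.beta, y.se, y.eaf, "kept")
    if (y.effect_allele, y.other_allele) == (oa, ea):
        yy = y.flipped()
        return _record(snp, x, yy.beta, yy.se, yy.eaf, "flipped")

    # try the complementary strand
    cea, coa = complement_allele(y.effect_allele), complement_allele(y.other_allele)
    if (cea, coa) == (ea, oa):
        return _record(snp, x, y.beta, y.se, y.eaf, "strand_corrected")
    if (cea, coa) == (oa, ea):
        yy = y.flipped()
        return _record(snp, x, yy.beta, yy.se, yy.eaf, "strand_corrected")

    return _record(snp, x, y.beta, y.se, y.eaf, "dropped_incompatible")


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> HarmonizedSet:
    """Align outcome effects onto each instrument's exposure effect allele.

    Parameters
    ----------
    exposure, outcome
        Instrument associations and outcome associations, keyed by snp_id.
    palindrome_eaf_window
        Half-width of the frequency band around 0.5 inside which palindromic
        variants are considered unresolvable and dropped.
    """
    outcome_by_id = {r.snp_id: r for r in outcome.records}
    missing = [r.snp_id for r in exposure.records if r.snp_id not in outcome_by_id]
    kept: list[HarmonizedRecord] = []
    audit: list[HarmonizedRecord] = []
    for x in exposure.records:
        y = outcome_by_id.get(x.snp_id)
        if y is None:
            continue
        rec = _harmonize_pair(x, y, palindrome_eaf_window)
        (kept if rec.kept else audit).append(rec)

    if not kept and not audit:
        raise ValueError(
            f"no instrument of {exposure.trait_label} found in outcome "
            f"{outcome.trait_label}; missing: {missing}"
        )
    if missing:
        logger.warning(
            "%s: %d instruments absent from outcome data: %s",
            exposure.trait_label, len(missing), missing,
        )
    return HarmonizedSet(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        records=kept,
        audit=audit,
    )


def build_mvmr_set(
    exposures: list[SummaryTable],
    outcome: SummaryTable,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
    min_snps: int = 4,
) -> MVMRSet:
    """Assemble the L x K instrument matrix for multivariable MR.

    Each exposure is harmonized against the outcome individually; the SNPs
    entering the matrix are the intersection of the harmonizable sets, so
    every retained SNP carries a complete row of exposure effects with a
    common allele orientation (the outcome's, fixed by the first exposure's
    harmonization). Fewer than ``min_snps`` usable SNPs is a refusal: with
    three or fewer SNPs the multivariable system is not worth fitting.
    """
    labels = [t.trait_label for t in exposures]
    if len(labels) != len(set(labels)):
        raise ValueError("collinear exposure labels: duplicated exposure tables")
    if len(exposures) < 2:
        raise ValueError("MVMR requires at least two exposures")

    hsets = [harmonize(t, outcome, palindrome_eaf_window) for t in exposures]
    common = set(hsets[0].snp_ids)
    for hs in hsets[1:]:
        common &= set(hs.snp_ids)
    audit = []
    for hs in hsets:
        for sid in hs.snp_ids:
            if sid not in common:
                audit.append(f"{sid}: missing in at least one exposure, dropped")

    snp_ids = [sid for sid in hsets[0].snp_ids if sid in common]
    L, K = len(snp_ids), len(exposures)
    if L <= 3:
        raise ValueError(
            f"MVMR not applied: only {L} usable SNPs across {K} exposures "
            f"(more than three required)"
        )

    by_id = [{r.snp_id: r for r in hs.records} for hs in hsets]
    beta_x = np.empty((L, K))
    se_x = np.empty((L, K))
    beta_y = np.empty(L)
    se_y = np.empty(L)
    for i, sid in enumerate(snp_ids):
        ref = by_id[0][sid]
        beta_y[i] = ref.beta_y
        se_y[i] = ref.se_y
        for k in range(K):
            rec = by_id[k][sid]
            # realign every exposure onto the first exposure's effect allele
            if rec.effect_allele == ref.effect_allele:
                sign = 1.0
            elif rec.effect_allele == ref.other_allele or (
                rec.effect_allele is not None
                and ref.effect_allele is not None
                and complement_allele(rec.effect_allele) == ref.other_allele
            ):
                sign = -1.0
            else:
                sign = 1.0  # same strand labels after per-exposure harmonization
            beta_x[i, k] = sign * rec.beta_x
            se_x[i, k] = rec.se_x

    return MVMRSet(
        exposure_labels=labels,
        snp_ids=snp_ids,
        beta_x=beta_x,
        se_x=se_x,
        beta_y=beta_y,
        se_y=se_y,
        audit=audit,
    )
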