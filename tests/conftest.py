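import numpy as np
import pytest

from ivmr.types import (
    HarmonizedRecord,
    HarmonizedSet,
    SummaryTable,
    VariantAssociation,
)

ALLELES = [("A", "G"), ("T", "C"), ("G", "A"), ("C", "T"), ("A", "C"), ("T", "G")]


def make_hset(bx, sx, by, sy, eaf=None, n=None, label="exposure"):
    """Hand-built harmonized set from plain effect vectors."""
    k = len(bx)
    records = [
        HarmonizedRecord(
            snp_id=f"rs{i + 1}",
            beta_x=float(bx[i]), se_x=float(sx[i]),
            beta_y=float(by[i]), se_y=float(sy[i]),
            eaf_x=None if eaf is None else float(eaf[i]),
            eaf_y=None, status="kept",
            effect_allele=ALLELES[i % len(ALLELES)][0],
            other_allele=ALLELES[i % len(ALLELES)][1],
            n_x=None if n is None else int(n),
        )
        for i in range(k)
    ]
    return HarmonizedSet(exposure_label=label, outcome_label="outcome", records=records)


def make_table(rows, label="trait", **kw):
    """SummaryTable from (snp, ea, oa, eaf, beta, se, pval[, n[, chrom, pos]]) tuples."""
    records = []
    for row in rows:
        snp, ea, oa, eaf, beta, se, pval = row[:7]
        n = row[7] if len(row) > 7 else None
        chrom = row[8] if len(row) > 8 else None
        pos = row[9] if len(row) > 9 else None
        records.append(
            VariantAssociation(
                snp_id=snp, effect_allele=ea, other_allele=oa, eaf=eaf,
                beta=beta, se=se, pval=pval, n=n, chrom=chrom, pos=pos,
            )
        )
    return SummaryTable(trait_label=label, records=records, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20230222)


@pytest.fixture
def small_hset():
    return make_hset(
        bx=[0.2, 0.4, 0.3, 0.25, 0.35],
        sx=[0.02, 0.02, 0.02, 0.02, 0.02],
        by=[0.011, 0.019, 0.016, 0.012, 0.018],
        sy=[0.01, 0.01, 0.01, 0.01, 0.01],
        eaf=[0.3, 0.4, 0.2, 0.25, 0.35],
        n=20000,
    )
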