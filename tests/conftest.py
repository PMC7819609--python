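import numpy as np
import pytest

from neurotarget.sumstats import SumstatRecord


def make_record(
    variant_id="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    p=None,
    n=1286,
    trait_id="expression",
    gene_id="GENE1",
):
    """Record factory with a p-value consistent with beta/se by default."""
    from scipy import stats

    if p is None:
        z = beta / se if se > 0 else 0.0
        p = max(float(2 * stats.norm.sf(abs(z))), 1e-300)
    return SumstatRecord(
        variant_id=variant_id, chrom=chrom, pos=pos,
        effect_allele=ea, other_allele=oa, eaf=eaf,
        beta=beta, se=se, p=p, n=n, trait_id=trait_id, gene_id=gene_id,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(20240926)


def random_records(rng, n, trait_id="expression", gene_id="GENE1"):
    """n valid records with random (but invariant-satisfying) fields."""
    records = []
    alleles = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    for i in range(n):
        ea, oa = alleles[int(rng.integers(len(alleles)))]
        beta = float(rng.normal(0, 0.2))
        se = float(rng.uniform(0.01, 0.1))
        records.append(make_record(
            variant_id=f"rs{i:05d}",
            pos=1_000_000 + i * 1_000,
            ea=ea, oa=oa,
            eaf=float(rng.uniform(0.05, 0.95)),
            beta=beta, se=se,
            n=int(rng.integers(500, 5000)),
            trait_id=trait_id, gene_id=gene_id,
        ))
    return records
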