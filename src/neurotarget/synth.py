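"""Synthetic cis-region summary statistics under explicit causal scenarios.

Summary statistics are generated directly at the z-score level: for a
region with signed LD matrix R and joint per-SNP standardized effects λ,
the marginal z-scores follow

    z ~ MVN( R·λ·√n , R )

(the standard summary-statistics likelihood), so the LD structure the
clumping and colocalization stages consume is exact by construction, and
no individual-level genotypes are needed. Betas and SEs are back-filled on
the per-allele scale via se = 1/sqrt(2·maf·(1−maf)·n), beta = z·se.

Scenario kinds map onto the five colocalization hypotheses plus the two
failure modes of MR:

========================  =============================  ===========
kind                      generative structure           expected
========================  =============================  ===========
null                      no signal either trait         H0
eqtl_only                 eQTL signal, no disease        H1
gwas_only                 disease signal, no eQTL        H2
distinct_variants         different causal SNPs          H3
shared_variant            disease = γ × expression       H4
reverse_causation         expression = γ × liability     H4
horizontal_pleiotropy     direct SNP→disease effect      H4
========================  =============================  ===========

The true causal effect of expression on disease (``TruthRecord.true_wald``)
is γ only under ``shared_variant``; it is zero in every other scenario,
including the two H4 lookalikes — that asymmetry is exactly what the
directionality and sensitivity stages must detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import block_diag

from .sumstats import LdReference, SumstatRecord

__all__ = [
    "Scenario",
    "TruthRecord",
    "BidirectionalTruth",
    "SCENARIO_KINDS",
    "simulate_ld",
    "simulate_region",
    "simulate_bidirectional",
    "simulate_phewas",
]

SCENARIO_KINDS = (
    "null",
    "eqtl_only",
    "gwas_only",
    "distinct_variants",
    "shared_variant",
    "reverse_causation",
    "horizontal_pleiotropy",
)

_EXPECTED_HYPOTHESIS = {
    "null": "H0",
    "eqtl_only": "H1",
    "gwas_only": "H2",
    "distinct_variants": "H3",
    "shared_variant": "H4",
    "reverse_causation": "H4",
    "horizontal_pleiotropy": "H4",
}

#: smallest p-value reported; |z| ≈ 37 already exhausts double precision
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class Scenario:
    """Generative conditions for one cis region.

    ``gamma`` is the causal effect of expression on disease liability
    (log-odds per SD of expression) for ``shared_variant``; for
    ``reverse_causation`` it is the disease→expression response, and for
    ``horizontal_pleiotropy``/``gwas_only``/``distinct_variants`` it
    scales the direct disease effect (γ·√PVE on the standardized scale)
    so statistical power matches the shared-variant case. ``eqtl_pve`` is
    the expression variance explained by the causal eQTL (for
    ``reverse_causation`` it is read as the disease variance explained by
    the causal SNP). Defaults emulate the study conditions: a brain-cortex
    eQTL panel of n = 1,286, a disease GWAS of effective n = 50,000, and
    cis regions of 100 SNPs with AR(1) LD decay ρ = 0.9.
    """

    kind: str
    gamma: float = 0.2
    eqtl_pve: float = 0.02
    n_eqtl: int = 1286
    n_gwas: int = 50_000
    m_snps: int = 100
    ld_rho: float = 0.9
    causal_indices: tuple[int, ...] | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not (0.0 < self.eqtl_pve < 1.0):
            raise ValueError("eqtl_pve must be in (0, 1)")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.causal_indices is not None:
            if any(not (0 <= c < self.m_snps) for c in self.causal_indices):
                raise ValueError("causal_indices must lie in [0, m_snps)")
            if self.kind == "distinct_variants" and len(self.causal_indices) != 2:
                raise ValueError("distinct_variants needs exactly 2 causal indices")

    def resolved_causal_indices(self) -> tuple[int, ...]:
        if self.causal_indices is not None:
            return tuple(self.causal_indices)
        if self.kind == "null":
            return ()
        if self.kind == "distinct_variants":
            return (self.m_snps // 4, 3 * self.m_snps // 4)
        return (self.m_snps // 2,)


@dataclass(frozen=True)
class TruthRecord:
    scenario: Scenario
    true_wald: float
    causal_variant_ids: tuple[str, ...]
    expected_coloc_hypothesis: str


@dataclass(frozen=True)
class BidirectionalTruth:
    direction: str  # "forward" | "reverse"
    gamma: float
    causal_variant_ids: tuple[str, ...]


_chol_cache: dict[tuple[int, float], np.ndarray] = {}


def _ar1_matrix(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _ar1_cholesky(m: int, rho: float) -> np.ndarray:
    key = (m, round(rho, 12))
    if key not in _chol_cache:
        _chol_cache[key] = np.linalg.cholesky(
            _ar1_matrix(m, rho) + 1e-12 * np.eye(m)
        )
    return _chol_cache[key]


def simulate_ld(
    m_snps: int,
    ld_rho: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> tuple[LdReference, np.ndarray]:
    """Exact AR(1) LD reference r(i,j) = ρ^|i−j| plus uniform MAFs."""
    if m_snps < 1:
        raise ValueError("need at least 1 SNP")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = [f"rs{i:05d}" for i in range(m_snps)]
    mafs = rng.uniform(*maf_range, size=m_snps)
    return LdReference(ids, _ar1_matrix(m_snps, ld_rho)), mafs


def _records_from_z(
    z: np.ndarray,
    mafs: np.ndarray,
    n: int,
    *,
    ids: list[str],
    chrom: str,
    pos0: int,
    spacing: int,
    trait_id: str,
    gene_id: str | None,
) -> list[SumstatRecord]:
    se = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs) * n)
    beta = z * se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR)
    return [
        SumstatRecord(
            variant_id=ids[i],
            chrom=chrom,
            pos=pos0 + i * spacing,
            effect_allele="A",
            other_allele="G",
            eaf=float(mafs[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            p=float(p[i]),
            n=n,
            trait_id=trait_id,
            gene_id=gene_id,
        )
        for i in range(z.size)
    ]


def _scenario_lambdas(sc: Scenario) -> tuple[np.ndarray, np.ndarray]:
    """Joint standardized per-SNP effects (λ_eqtl, λ_gwas) for a scenario."""
    lam_e = np.zeros(sc.m_snps)
    lam_g = np.zeros(sc.m_snps)
    causal = sc.resolved_causal_indices()
    b_e = math.sqrt(sc.eqtl_pve / max(len(causal), 1))
    b_g_direct = sc.gamma * math.sqrt(sc.eqtl_pve)

    if sc.kind == "null":
        pass
    elif sc.kind == "eqtl_only":
        lam_e[list(causal)] = b_e
    elif sc.kind == "gwas_only":
        lam_g[list(causal)] = b_g_direct
    elif sc.kind == "shared_variant":
        lam_e[list(causal)] = b_e
        lam_g = sc.gamma * lam_e
    elif sc.kind == "distinct_variants":
        c_e, c_g = causal
        lam_e[c_e] = math.sqrt(sc.eqtl_pve)
        lam_g[c_g] = b_g_direct
    elif sc.kind == "reverse_causation":
        # eqtl_pve read as the disease variance explained by the causal SNP;
        # expression responds to liability with coefficient gamma
        lam_g[list(causal)] = math.sqrt(sc.eqtl_pve / max(len(causal), 1))
        lam_e = sc.gamma * lam_g
    elif sc.kind == "horizontal_pleiotropy":
        lam_e[list(causal)] = b_e
        lam_g[list(causal)] = b_g_direct  # direct effect, not via expression
    return lam_e, lam_g


def simulate_region(
    scenario: Scenario,
) -> tuple[list[SumstatRecord], list[SumstatRecord], LdReference, TruthRecord]:
    """One cis region: (eQTL sumstats, GWAS sumstats, LD reference, truth)."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    ld, mafs = simulate_ld(sc.m_snps, sc.ld_rho, sc.maf_range, seed=sc.seed)
    R = ld.r_matrix
    L = _ar1_cholesky(sc.m_snps, sc.ld_rho)
    lam_e, lam_g = _scenario_lambdas(sc)

    z_e = R @ lam_e * math.sqrt(sc.n_eqtl) + L @ rng.standard_normal(sc.m_snps)
    z_g = R @ lam_g * math.sqrt(sc.n_gwas) + L @ rng.standard_normal(sc.m_snps)

    common = dict(ids=ld.variant_ids, chrom="1", pos0=1_000_000, spacing=1_000)
    eqtl = _records_from_z(
        z_e, mafs, sc.n_eqtl, trait_id="expression", gene_id="GENE1", **common
    )
    gwas = _records_from_z(
        z_g, mafs, sc.n_gwas, trait_id="disease", gene_id=None, **common
    )
    causal = sc.resolved_causal_indices()
    truth = TruthRecord(
        scenario=sc,
        true_wald=sc.gamma if sc.kind == "shared_variant" else 0.0,
        causal_variant_ids=tuple(ld.variant_ids[c] for c in causal),
        expected_coloc_hypothesis=_EXPECTED_HYPOTHESIS[sc.kind],
    )
    return eqtl, gwas, ld, truth


def simulate_bidirectional(
    direction: str,
    *,
    n_loci: int = 15,
    m_per_locus: int = 11,
    ld_rho: float = 0.9,
    disease_pve: float = 8e-4,
    gamma: float = 0.2,
    n_gwas: int = 50_000,
    n_eqtl: int = 31_684,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> tuple[list[SumstatRecord], list[SumstatRecord], LdReference, BidirectionalTruth]:
    """Multi-locus disease architecture for reverse-MR testing.

    ``n_loci`` independent regions each carry one disease causal variant
    explaining ``disease_pve`` of liability. Under ``forward`` the gene's
    expression is unrelated to these loci (its own cis locus lies
    elsewhere); under ``reverse`` expression responds to disease liability
    with coefficient ``gamma``, so every disease hit carries a
    proportional expression effect. The expression panel defaults to a
    blood-eQTL scale (n = 31,684), mirroring the reverse-MR design of
    looking up disease instruments in a large expression dataset.
    Returns genome-wide (GWAS, eQTL, block-diagonal LD, truth).
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    rng = np.random.default_rng(seed)
    L = _ar1_cholesky(m_per_locus, ld_rho)
    R = _ar1_matrix(m_per_locus, ld_rho)
    c = m_per_locus // 2
    b_d = math.sqrt(disease_pve)

    gwas: list[SumstatRecord] = []
    eqtl: list[SumstatRecord] = []
    blocks = []
    all_ids: list[str] = []
    causal_ids: list[str] = []
    for locus in range(n_loci):
        ids = [f"rs{locus:02d}_{i:03d}" for i in range(m_per_locus)]
        mafs = rng.uniform(*maf_range, size=m_per_locus)
        lam_g = np.zeros(m_per_locus)
        lam_g[c] = b_d
        lam_e = gamma * lam_g if direction == "reverse" else np.zeros(m_per_locus)
        z_g = R @ lam_g * math.sqrt(n_gwas) + L @ rng.standard_normal(m_per_locus)
        z_e = R @ lam_e * math.sqrt(n_eqtl) + L @ rng.standard_normal(m_per_locus)
        common = dict(
            ids=ids, chrom=str(locus + 1), pos0=1_000_000, spacing=1_000
        )
        gwas.extend(_records_from_z(z_g, mafs, n_gwas, trait_id="disease", gene_id=None, **common))
        eqtl.extend(_records_from_z(z_e, mafs, n_eqtl, trait_id="expression", gene_id="GENE1", **common))
        blocks.append(R)
        all_ids.extend(ids)
        causal_ids.append(ids[c])
    ld = LdReference(all_ids, block_diag(*blocks))
    return gwas, eqtl, ld, BidirectionalTruth(direction, gamma, tuple(causal_ids))


def simulate_phewas(
    n_instruments: int,
    n_traits: int,
    brain_fraction: float = 0.17,
    planted_effects: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
):
    """Null phenome-wide scan matrix with optional planted signals.

    Null cells draw z ~ N(0, 1) (uniform p); a planted effect
    ``(instrument_index, trait_index, z_mean)`` shifts that cell's z.
    Trait indices below ``round(brain_fraction·n_traits)`` are labelled
    brain-related. Returns a (:class:`~neurotarget.pleiotropy.PhewasMatrix`,
    truth DataFrame) pair.
    """
    import pandas as pd

    from .pleiotropy import PhewasMatrix

    if n_instruments < 1 or n_traits < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    n_brain = int(round(brain_fraction * n_traits))
    categories = {
        f"trait{t:03d}": ("brain" if t < n_brain else "other")
        for t in range(n_traits)
    }
    z = rng.standard_normal((n_instruments, n_traits))
    truth_rows = []
    for i, t, z_mean in planted_effects or []:
        z[i, t] += z_mean
        truth_rows.append({"instrument": i, "trait_id": f"trait{t:03d}", "z_mean": z_mean})
    se_wr = 0.05
    rows = []
    for i in range(n_instruments):
        for t in range(n_traits):
            trait_id = f"trait{t:03d}"
            rows.append({
                "gene_id": f"GENE{i:03d}",
                "variant_id": f"rs_inst{i:03d}",
                "trait_id": trait_id,
                "category": categories[trait_id],
                "wr": float(z[i, t] * se_wr),
                "se": se_wr,
                "p": float(max(2.0 * stats.norm.sf(abs(z[i, t])), _P_FLOOR)),
                "pp4": np.nan,
                "coloc_pass": False,
            })
    return PhewasMatrix(pd.DataFrame(rows), categories), pd.DataFrame(truth_rows)
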