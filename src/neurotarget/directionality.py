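"""Directionality checks: Steiger filtering and reverse MR.

MR assumes the instrument acts on the outcome through the exposure. If
instead genetic predisposition to disease alters gene expression, the
instrument-outcome correlation can rival or exceed the instrument-exposure
correlation. The Steiger test compares |ρ_gx| and |ρ_gy| after Fisher
z-transformation; reverse MR re-runs the analysis with disease-associated
SNPs as instruments and expression as the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from . import mr
from .instruments import clump, make_instrument, significance_filter
from .sumstats import LdReference, SumstatRecord, harmonize

__all__ = ["SteigerResult", "steiger_test", "r_from_assoc", "reverse_mr", "ReverseMrResult"]


@dataclass(frozen=True)
class SteigerResult:
    r_gx: float
    r_gy: float
    direction_correct: bool  # r_gx² > r_gy²: exposure → outcome orientation supported
    p_steiger: float
    n_x: int
    n_y: int


def steiger_test(r_gx: float, n_x: int, r_gy: float, n_y: int) -> SteigerResult:
    """Two-sample z test on Fisher-transformed correlation magnitudes.

    The statistic is (atanh|r_gx| − atanh|r_gy|) over its standard error
    sqrt(1/(n_x−3) + 1/(n_y−3)); the p-value is invariant to the sign of
    either correlation.
    """
    if abs(r_gx) >= 1.0 or abs(r_gy) >= 1.0:
        raise ValueError("correlations must satisfy |r| < 1")
    if n_x < 4 or n_y < 4:
        raise ValueError("need n >= 4 in both samples")
    z = (math.atanh(abs(r_gx)) - math.atanh(abs(r_gy))) / math.sqrt(
        1.0 / (n_x - 3) + 1.0 / (n_y - 3)
    )
    return SteigerResult(
        r_gx=r_gx,
        r_gy=r_gy,
        direction_correct=r_gx**2 > r_gy**2,
        p_steiger=float(2.0 * stats.norm.sf(abs(z))),
        n_x=n_x,
        n_y=n_y,
    )


def r_from_assoc(record: SumstatRecord, trait_kind: str = "quantitative") -> float:
    """Instrument-trait correlation from a summary-statistics record.

    Quantitative traits: r = sign(β)·√PVE after standardization. Binary
    traits: observed-scale approximation r ≈ z/√n, which preserves the
    ordering the Steiger filter needs.
    """
    if trait_kind == "binary":
        return record.z / math.sqrt(record.n)
    if trait_kind != "quantitative":
        raise ValueError(f"trait_kind must be 'quantitative' or 'binary', got {trait_kind!r}")
    inst = make_instrument(record)
    return math.copysign(math.sqrt(inst.pve), record.beta)


@dataclass(frozen=True)
class ReverseMrResult:
    gene_id: str
    trait_id: str
    results: tuple  # MultiSnpResult and/or WaldResult entries
    n_instruments: int
    single_snp: bool  # Wald fallback used (only one instrument survived)


def reverse_mr(
    outcome_gwas: list[SumstatRecord],
    eqtl_outcome: list[SumstatRecord],
    ld: LdReference,
    p_threshold: float = 5e-8,
    methods: frozenset[str] = frozenset({"ivw", "egger", "weighted_median"}),
    *,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
    seed: int = 0,
) -> list[ReverseMrResult]:
    """Reverse MR: disease as exposure, gene expression as outcome.

    Instruments are genome-wide significant, LD-clumped disease SNPs; for
    each gene in the expression dataset the multi-SNP estimators are run
    on the harmonized effects (Wald ratio fallback when only a single
    instrument harmonizes, flagged ``single_snp``).
    """
    hits = significance_filter(outcome_gwas, p_threshold)
    clumped = clump(hits, ld, r2_threshold, window_bp)
    if not clumped:
        return []

    genes: dict[str, dict[str, SumstatRecord]] = {}
    for rec in eqtl_outcome:
        genes.setdefault(rec.gene_id or "", {})[rec.variant_id] = rec

    out: list[ReverseMrResult] = []
    for gene_id, by_variant in sorted(genes.items()):
        bx, sx, by, sy, vids = [], [], [], [], []
        for inst_rec in clumped:
            eqtl_rec = by_variant.get(inst_rec.variant_id)
            if eqtl_rec is None:
                continue
            pair = harmonize(inst_rec, eqtl_rec)
            if pair.dropped:
                continue
            bx.append(pair.exposure.beta)
            sx.append(pair.exposure.se)
            by.append(pair.outcome.beta)
            sy.append(pair.outcome.se)
            vids.append(inst_rec.variant_id)
        if not bx:
            continue
        trait_id = clumped[0].trait_id
        if len(bx) == 1:
            # single-instrument fallback: raw-scale Wald ratio (disease → expression)
            variant_id = vids[0]
            wr = by[0] / bx[0]
            se = sy[0] / abs(bx[0])
            zstat = wr / se
            wres = mr.WaldResult(
                gene_id=gene_id,
                trait_id=trait_id,
                variant_id=variant_id,
                wr=wr,
                se=se,
                p=float(2.0 * stats.norm.sf(abs(zstat))),
            )
            out.append(ReverseMrResult(gene_id, trait_id, (wres,), 1, single_snp=True))
            continue
        results = []
        if "ivw" in methods:
            results.append(mr.ivw(bx, by, sy))
        if "egger" in methods and len(bx) >= 3:
            results.append(mr.egger(bx, by, sy))
        if "weighted_median" in methods:
            results.append(mr.weighted_median(bx, sx, by, sy, seed=seed))
        out.append(ReverseMrResult(gene_id, trait_id, tuple(results), len(bx), single_snp=False))
    return out
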