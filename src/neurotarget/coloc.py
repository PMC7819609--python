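"""Bayesian colocalization over a cis region.

For a ±500 kb window around an instrument, compares five hypotheses about
two traits' association patterns under a single-causal-variant-per-trait
assumption:

    H0  neither trait associated in the region
    H1  only trait 1 (gene expression) associated
    H2  only trait 2 (outcome) associated
    H3  both associated, different causal variants
    H4  both associated, same causal variant

Evidence per SNP is the Wakefield approximate Bayes factor. With V = se²,
W = prior effect variance and z = β/se:

    log ABF = 0.5·[ ln(V/(V+W)) + z²·W/(V+W) ]

Hypothesis likelihoods are sums of per-SNP (products of) ABFs, weighted by
per-SNP priors p1, p2, p12 and normalized to posteriors PP0..PP4. All sums
run in log space: brain eQTLs reach |z| ≈ 40, far beyond naive
exponentiation range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .sumstats import SumstatRecord

__all__ = [
    "ColocPriors",
    "ColocResult",
    "extract_region",
    "intersect_regions",
    "log_abf",
    "log_abf_vector",
    "coloc_posteriors",
    "coloc_pass",
    "run_coloc",
]


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities and prior effect scales.

    p1/p2: prior that a SNP associates with trait 1 / trait 2 only;
    p12: prior that it associates with both. w_quant / w_cc are the prior
    effect SDs for quantitative and case-control (log-odds) traits.
    """

    p1: float = 5e-4
    p2: float = 5e-4
    p12: float = 5e-5
    w_quant: float = 0.15
    w_cc: float = 0.2

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.p12 > min(self.p1, self.p2):
            warnings.warn(
                "p12 exceeds min(p1, p2); shared-variant prior larger than "
                "single-trait priors is rarely intended",
                stacklevel=2,
            )

    def prior_sd(self, trait_type: str) -> float:
        if trait_type == "quant":
            return self.w_quant
        if trait_type == "cc":
            return self.w_cc
        raise ValueError(f"trait_type must be 'quant' or 'cc', got {trait_type!r}")


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    labf1: np.ndarray
    labf2: np.ndarray
    window: tuple[str, int, int] | None = None

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    def best_hypothesis(self) -> str:
        return f"H{int(np.argmax(self.posteriors))}"


def extract_region(
    records: list[SumstatRecord],
    anchor_variant_id: str,
    half_window_bp: int = 500_000,
) -> list[SumstatRecord]:
    """Records within ± ``half_window_bp`` (inclusive) of the anchor variant."""
    anchor = next((r for r in records if r.variant_id == anchor_variant_id), None)
    if anchor is None:
        raise ValueError(f"anchor variant {anchor_variant_id!r} not present")
    return [
        r for r in records
        if r.chrom == anchor.chrom and abs(r.pos - anchor.pos) <= half_window_bp
    ]


def intersect_regions(
    records1: list[SumstatRecord], records2: list[SumstatRecord]
) -> tuple[list[SumstatRecord], list[SumstatRecord]]:
    """Restrict both traits to their common variants, position-ordered."""
    by_id2 = {r.variant_id: r for r in records2}
    common1 = sorted(
        (r for r in records1 if r.variant_id in by_id2),
        key=lambda r: (r.chrom, r.pos, r.variant_id),
    )
    return common1, [by_id2[r.variant_id] for r in common1]


def log_abf(record: SumstatRecord, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one association."""
    return float(log_abf_vector([record.beta], [record.se], prior_sd)[0])


def log_abf_vector(betas, ses, prior_sd: float) -> np.ndarray:
    beta = np.asarray(betas, dtype=float)
    se = np.asarray(ses, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all se must be > 0")
    V = se**2
    W = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(V / (V + W)) + z2 * W / (V + W))


def _log_diff_exp(a: float, b: float) -> float:
    """log(e^a − e^b), −inf when the difference is non-positive."""
    if a <= b:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(
    labf1, labf2, priors: ColocPriors = ColocPriors()
) -> ColocResult:
    """Posterior probabilities of H0..H4 from per-SNP log-ABF vectors."""
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("labf vectors must have equal length")
    if l1.size == 0:
        raise ValueError("no SNPs in region")

    log_s1 = float(logsumexp(l1))
    log_s2 = float(logsumexp(l2))
    log_s12 = float(logsumexp(l1 + l2))
    # sum over ordered pairs i != j equals S1*S2 - S12
    log_cross = _log_diff_exp(log_s1 + log_s2, log_s12)

    logw = np.array([
        0.0,
        np.log(priors.p1) + log_s1,
        np.log(priors.p2) + log_s2,
        np.log(priors.p1) + np.log(priors.p2) + log_cross,
        np.log(priors.p12) + log_s12,
    ])
    pp = np.exp(logw - logsumexp(logw))
    pp /= pp.sum()
    return ColocResult(*pp, n_snps=int(l1.size), labf1=l1, labf2=l2)


def coloc_pass(result: ColocResult, threshold: float = 0.70) -> bool:
    """True when PP4 strictly exceeds the threshold (default 70%)."""
    return result.pp4 > threshold


def run_coloc(
    trait1: list[SumstatRecord],
    trait2: list[SumstatRecord],
    anchor_variant_id: str,
    priors: ColocPriors = ColocPriors(),
    *,
    trait1_type: str = "quant",
    trait2_type: str = "cc",
    half_window_bp: int = 500_000,
) -> ColocResult:
    """Extract a ±window region around the anchor, intersect the traits,
    and compute colocalization posteriors."""
    region1 = extract_region(trait1, anchor_variant_id, half_window_bp)
    region2 = [r for r in trait2 if r.variant_id in {x.variant_id for x in region1}]
    common1, common2 = intersect_regions(region1, region2)
    if len(common1) < len(region1):
        warnings.warn(
            f"{len(region1) - len(common1)} region variant(s) absent from the "
            f"second trait; analyzing {len(common1)} common variants",
            stacklevel=2,
        )
    if not common1:
        raise ValueError("no variants shared between traits in the region")
    labf1 = log_abf_vector(
        [r.beta for r in common1], [r.se for r in common1], priors.prior_sd(trait1_type)
    )
    labf2 = log_abf_vector(
        [r.beta for r in common2], [r.se for r in common2], priors.prior_sd(trait2_type)
    )
    result = coloc_posteriors(labf1, labf2, priors)
    positions = [r.pos for r in common1]
    result.window = (common1[0].chrom, min(positions), max(positions))
    return result
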