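"""Phenome-wide pleiotropy assessment.

Instruments that pass the primary MR are screened against a wide panel of
disease and risk-factor traits (MR-PheWAS). Three summaries follow:

* enrichment of colocalization among brain-related vs other traits
  (Fisher's exact test on a 2×2 table);
* a permutation null for cross-disease effect sharing — how often would a
  random draw of the same number of non-brain traits show at least the
  observed proportion of nominal (P < 0.05) Wald effects;
* molecular (cis) pleiotropy — how many different genes' expression a
  single instrument associates with, Bonferroni-corrected over the number
  of transcript effects extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import coloc as coloc_mod
from . import mr
from .instruments import Instrument, make_instrument
from .sumstats import SumstatRecord, harmonize

__all__ = [
    "PhewasMatrix",
    "PermutationOutcome",
    "EnrichmentResult",
    "phewas_scan",
    "enrichment_test",
    "fisher_enrichment",
    "sharing_permutation",
    "molecular_pleiotropy",
]


@dataclass
class PhewasMatrix:
    """Long-format instrument × trait Wald-ratio scan.

    ``results`` columns: gene_id, variant_id, trait_id, category
    ("brain" | "other"), wr, se, p, pp4 (NaN when colocalization was not
    attempted), coloc_pass (bool).
    """

    results: pd.DataFrame
    categories: dict[str, str]  # trait_id -> "brain" | "other"

    def __post_init__(self) -> None:
        traits = set(self.results["trait_id"])
        labels = set(self.categories.get(t) for t in traits)
        if not labels <= {"brain", "other"}:
            raise ValueError("every trait must be categorized 'brain' or 'other'")

    @property
    def n_tests(self) -> int:
        return len(self.results)


@dataclass(frozen=True)
class PermutationOutcome:
    observed_count: int
    observed_prop: float
    null_props: np.ndarray
    empirical_p: float
    ci95: tuple[float, float]
    n_iter: int
    subset_size: int
    pool_size: int
    seed: int


@dataclass(frozen=True)
class EnrichmentResult:
    table: np.ndarray  # [[brain_hit, brain_miss], [other_hit, other_miss]]
    odds_ratio: float
    p: float


def phewas_scan(
    instruments: list[Instrument],
    trait_sumstats: dict[str, list[SumstatRecord]],
    categories: dict[str, str],
    alpha: float = 0.05,
    *,
    coloc_regions: dict[str, list[SumstatRecord]] | None = None,
    priors: coloc_mod.ColocPriors = coloc_mod.ColocPriors(),
    pp4_threshold: float = 0.70,
) -> PhewasMatrix:
    """Wald-ratio every instrument against every trait.

    Colocalization is attempted only for cells with p < ``alpha`` and only
    when regional eQTL summary statistics are supplied via
    ``coloc_regions`` (keyed by gene_id).
    """
    rows = []
    for inst in instruments:
        for trait_id, records in sorted(trait_sumstats.items()):
            outcome = next(
                (r for r in records if r.variant_id == inst.variant_id), None
            )
            if outcome is None:
                continue
            pair = harmonize(inst.record, outcome)
            if pair.dropped:
                continue
            res = mr.wald_ratio(inst, pair.outcome)
            pp4 = np.nan
            passed = False
            if res.p < alpha and coloc_regions and inst.gene_id in coloc_regions:
                try:
                    cres = coloc_mod.run_coloc(
                        coloc_regions[inst.gene_id], records, inst.variant_id,
                        priors=priors,
                    )
                except ValueError:
                    cres = None
                if cres is not None:
                    pp4 = cres.pp4
                    passed = coloc_mod.coloc_pass(cres, pp4_threshold)
            rows.append({
                "gene_id": inst.gene_id,
                "variant_id": inst.variant_id,
                "trait_id": trait_id,
                "category": categories[trait_id],
                "wr": res.wr,
                "se": res.se,
                "p": res.p,
                "pp4": pp4,
                "coloc_pass": passed,
            })
    return PhewasMatrix(pd.DataFrame(rows), dict(categories))


def fisher_enrichment(table) -> EnrichmentResult:
    """Two-sided Fisher's exact test on a 2×2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return EnrichmentResult(table=t, odds_ratio=float(odds), p=float(p))


def enrichment_test(
    matrix: PhewasMatrix, strict_alpha: float, loose_alpha: float = 0.05
) -> dict[float, EnrichmentResult]:
    """Brain-vs-other colocalization enrichment at two Wald p thresholds.

    A cell counts as a hit at a threshold when its Wald p is below the
    threshold and it passed colocalization.
    """
    df = matrix.results
    if not {"brain", "other"} <= set(df["category"]):
        raise ValueError("both brain and other categories must be non-empty")
    out = {}
    for alpha in (strict_alpha, loose_alpha):
        hit = (df["p"] < alpha) & df["coloc_pass"]
        brain = df["category"] == "brain"
        table = [
            [int((hit & brain).sum()), int((~hit & brain).sum())],
            [int((hit & ~brain).sum()), int((~hit & ~brain).sum())],
        ]
        out[alpha] = fisher_enrichment(table)
    return out


def sharing_permutation(
    matrix: PhewasMatrix,
    observed: tuple[int, int],
    subset_size: int,
    n_iter: int = 10_000,
    seed: int = 0,
    *,
    alpha: float = 0.05,
) -> PermutationOutcome:
    """Permutation null for the proportion of shared (P < alpha) effects.

    Each iteration samples ``subset_size`` traits without replacement from
    the non-brain pool and computes the proportion of Wald cells with
    p < alpha. The empirical p-value uses the add-one estimator
    (1 + #{null ≥ observed}) / (n_iter + 1), so it can never be zero.
    """
    observed_count, observed_total = observed
    if observed_total == 0:
        raise ValueError("observed total must be positive")
    observed_prop = observed_count / observed_total

    df = matrix.results
    pool = sorted(set(df.loc[df["category"] == "other", "trait_id"]))
    if subset_size > len(pool):
        raise ValueError("subset_size exceeds the non-brain trait pool")
    hits_by_trait = df.groupby("trait_id")["p"].apply(lambda s: int((s < alpha).sum()))
    cells_by_trait = df.groupby("trait_id")["p"].size()

    rng = np.random.default_rng(seed)
    null_props = np.empty(n_iter)
    exceed = 0
    for it in range(n_iter):
        chosen = rng.choice(pool, size=subset_size, replace=False)
        count = int(hits_by_trait.loc[chosen].sum())
        total = int(cells_by_trait.loc[chosen].sum())
        prop = count / total if total else 0.0
        null_props[it] = prop
        if prop >= observed_prop:
            exceed += 1
    return PermutationOutcome(
        observed_count=observed_count,
        observed_prop=observed_prop,
        null_props=null_props,
        empirical_p=(1 + exceed) / (n_iter + 1),
        ci95=(
            float(np.percentile(null_props, 2.5)),
            float(np.percentile(null_props, 97.5)),
        ),
        n_iter=n_iter,
        subset_size=subset_size,
        pool_size=len(pool),
        seed=seed,
    )


def molecular_pleiotropy(
    variant_id: str,
    eqtl_all_genes: list[SumstatRecord],
    outcome: list[SumstatRecord],
    alpha: float = 0.05,
    *,
    priors: coloc_mod.ColocPriors = coloc_mod.ColocPriors(),
    pp4_threshold: float = 0.70,
) -> pd.DataFrame:
    """Cis pleiotropy scan for one instrument.

    Extracts every transcript effect for the variant (no p filter),
    applies Bonferroni over the number extracted, and colocalizes each
    passing gene's regional signal against the primary outcome. Columns:
    gene_id, beta, se, p, passes_bonferroni, pp4, coloc_pass.
    """
    effects = [r for r in eqtl_all_genes if r.variant_id == variant_id]
    if not effects:
        return pd.DataFrame(
            columns=["gene_id", "beta", "se", "p", "passes_bonferroni", "pp4", "coloc_pass"]
        )
    threshold = mr.bonferroni_threshold(alpha, len(effects))
    rows = []
    for rec in sorted(effects, key=lambda r: r.gene_id or ""):
        passes = rec.p < threshold
        pp4 = np.nan
        cpass = False
        if passes:
            gene_records = [r for r in eqtl_all_genes if r.gene_id == rec.gene_id]
            try:
                cres = coloc_mod.run_coloc(gene_records, outcome, variant_id, priors=priors)
                pp4 = cres.pp4
                cpass = coloc_mod.coloc_pass(cres, pp4_threshold)
            except ValueError:
                pass
        rows.append({
            "gene_id": rec.gene_id,
            "beta": rec.beta,
            "se": rec.se,
            "p": rec.p,
            "passes_bonferroni": passes,
            "pp4": pp4,
            "coloc_pass": cpass,
        })
    return pd.DataFrame(rows)
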