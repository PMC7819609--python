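"""Drug-target triage from MR + colocalization hits.

Candidate genes that pass both the Bonferroni MR gate and colocalization
are assessed against three criteria held in an offline annotation table:
an allelic series (coding variants causing a monogenic CNS or behavioural
phenotype on record), druggability (a clinical-stage target, at least
Phase 0 completed), and a satisfying safety profile (no adverse
colocalized phenome-wide trait). The recommended drug action follows the
Wald ratio sign: a positive effect (higher expression → higher risk)
calls for inhibition, a negative one for promotion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coloc import ColocResult
from .mr import WaldResult

__all__ = [
    "GeneAnnotation",
    "TargetCall",
    "read_annotations",
    "derive_action",
    "prioritize",
    "report",
]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    allelic_series: bool
    druggable: bool
    adverse_traits: tuple[str, ...] = ()


@dataclass
class TargetCall:
    gene_id: str
    indication: str
    action: str  # "inhibition" | "promotion"
    wald: WaldResult
    coloc: ColocResult | None
    criteria_met: frozenset[str] = frozenset()
    safety_flags: tuple[str, ...] = ()
    secondary_indications: tuple[str, ...] = ()

    @property
    def top_ranked(self) -> bool:
        c = self.criteria_met
        return ("allelic_series" in c or "druggable" in c) and "safety_ok" in c


def read_annotations(path) -> dict[str, GeneAnnotation]:
    """Annotation TSV: gene_id, allelic_series, druggable, adverse_traits
    (comma-separated, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for row in df.to_dict("records"):
        adverse = tuple(t for t in row.get("adverse_traits", "").split(",") if t)
        out[row["gene_id"]] = GeneAnnotation(
            gene_id=row["gene_id"],
            allelic_series=row["allelic_series"].strip() in ("1", "true", "True"),
            druggable=row["druggable"].strip() in ("1", "true", "True"),
            adverse_traits=adverse,
        )
    return out


def derive_action(wr: WaldResult) -> str:
    """Positive Wald ratio → inhibition; negative → promotion."""
    if wr.wr > 0:
        return "inhibition"
    if wr.wr < 0:
        return "promotion"
    raise ValueError(f"{wr.gene_id}: zero Wald ratio, drug action undefined")


def prioritize(
    hits: list[tuple[WaldResult, ColocResult | None]],
    annotations: dict[str, GeneAnnotation],
    *,
    colocalized_phewas_traits: dict[str, list[str]] | None = None,
) -> list[TargetCall]:
    """Rank MR+coloc hits by the three-criterion rule.

    Genes absent from the annotation table get all criteria false.
    Safety is flagged, not hard-excluded: a gene fails ``safety_ok`` only
    when one of its colocalized phenome-wide traits appears in its
    adverse-trait annotation. Returns top-ranked genes first, then by
    Wald p within rank.
    """
    phewas = colocalized_phewas_traits or {}
    calls: list[TargetCall] = []
    for wald, coloc_res in hits:
        ann = annotations.get(wald.gene_id)
        secondary = tuple(phewas.get(wald.gene_id, ()))
        criteria = set()
        flags: tuple[str, ...] = ()
        if ann is not None:
            if ann.allelic_series:
                criteria.add("allelic_series")
            if ann.druggable:
                criteria.add("druggable")
            flags = tuple(t for t in secondary if t in ann.adverse_traits)
            if not flags:
                criteria.add("safety_ok")
        calls.append(TargetCall(
            gene_id=wald.gene_id,
            indication=wald.trait_id,
            action=derive_action(wald),
            wald=wald,
            coloc=coloc_res,
            criteria_met=frozenset(criteria),
            safety_flags=flags,
            secondary_indications=secondary,
        ))
    return sorted(calls, key=lambda c: (not c.top_ranked, c.wald.p, c.gene_id))


def report(calls: list[TargetCall]) -> pd.DataFrame:
    """Result table: outcome, gene, SNP, WR, SE, P, coloc (percent, 1 dp)."""
    rows = [
        {
            "outcome": c.indication,
            "gene": c.gene_id,
            "SNP": c.wald.variant_id,
            "WR": round(c.wald.wr, 3),
            "SE": round(c.wald.se, 3),
            "P": f"{c.wald.p:.2e}",
            "coloc": f"{100.0 * c.coloc.pp4:.1f}" if c.coloc is not None else "",
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["outcome", "gene", "SNP", "WR", "SE", "P", "coloc"]
    )
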