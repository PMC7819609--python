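"""Summary-statistics I/O, LD references, and allele harmonization.

GWAS and eQTL summary statistics travel as tab-separated files with a
named-column header. Column names are configurable through a *dialect*
mapping so files from different providers can be read without rewriting
them; the default dialect is ``chrom, pos, rsid, ea, oa, eaf, beta, se,
p, n`` (+ ``gene`` for eQTL files).

Two-sample Mendelian randomization requires the exposure and outcome
effects to be expressed relative to the same allele. :func:`harmonize`
re-signs outcome records to the exposure effect allele, resolving strand
flips by complementing and dropping palindromic (A/T, C/G) variants whose
allele frequency is too close to 0.5 to orient reliably.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("neurotarget")

__all__ = [
    "SumstatRecord",
    "LdReference",
    "HarmonizeAction",
    "HarmonizedPair",
    "SumstatsFormatError",
    "DEFAULT_DIALECT",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "read_ld_triplets",
    "write_ld_matrix",
    "harmonize",
]

#: field name -> column name in the TSV header
DEFAULT_DIALECT: dict[str, str] = {
    "chrom": "chrom",
    "pos": "pos",
    "variant_id": "rsid",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p": "p",
    "n": "n",
    "gene_id": "gene",
    "trait_id": "trait",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsFormatError(ValueError):
    """A summary-statistics file is structurally unreadable (bad header)."""


@dataclass(frozen=True)
class SumstatRecord:
    """One variant's association with one trait.

    ``beta`` is a per-effect-allele estimate: log-odds for binary traits,
    expression units or SD for eQTLs. ``n`` is the per-variant sample size
    (a study-wide value is an accepted fallback).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int
    trait_id: str = ""
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.variant_id}: p {self.p} outside (0, 1]")
        if self.n <= 0:
            raise ValueError(f"{self.variant_id}: n must be positive")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))

    def is_palindromic(self) -> bool:
        a, b = self.effect_allele, self.other_allele
        return _COMPLEMENT.get(a) == b


@dataclass
class LdReference:
    """Signed pairwise correlation (r) between variants; r² derived on demand."""

    variant_ids: list[str]
    r_matrix: np.ndarray
    build_tag: str = "hg19"

    def __post_init__(self) -> None:
        r = np.asarray(self.r_matrix, dtype=float)
        if r.shape != (len(self.variant_ids), len(self.variant_ids)):
            raise ValueError("LD matrix shape does not match variant list")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(r) > 1.0 + 1e-8):
            raise ValueError("|r| must not exceed 1")
        self.r_matrix = r
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r(self, a: str, b: str) -> float:
        return float(self.r_matrix[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2

    def subset(self, variant_ids: Sequence[str]) -> "LdReference":
        idx = [self._index[v] for v in variant_ids]
        return LdReference(list(variant_ids), self.r_matrix[np.ix_(idx, idx)], self.build_tag)


class HarmonizeAction(str, Enum):
    UNCHANGED = "unchanged"
    SIGN_FLIPPED = "sign_flipped"
    STRAND_FLIPPED = "strand_flipped"
    DROPPED_PALINDROMIC = "dropped_palindromic"
    DROPPED_UNMATCHED = "dropped_unmatched"


@dataclass(frozen=True)
class HarmonizedPair:
    exposure: SumstatRecord
    outcome: SumstatRecord
    action_taken: HarmonizeAction

    @property
    def dropped(self) -> bool:
        return self.action_taken in (
            HarmonizeAction.DROPPED_PALINDROMIC,
            HarmonizeAction.DROPPED_UNMATCHED,
        )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_MANDATORY = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
              "eaf", "beta", "se", "p"]


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    trait_id: str = "",
    study_n: int | None = None,
) -> list[SumstatRecord]:
    """Read a tab-separated summary-statistics file into validated records.

    Rows violating record invariants (e.g. se == 0) are rejected with a
    row-numbered warning rather than aborting the read. ``study_n`` is the
    study-wide sample size used when the file has no per-variant n column.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype={d["chrom"]: str}, float_precision="round_trip")
    missing = [f for f in _MANDATORY if d[f] not in df.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing mandatory column(s) {[d[f] for f in missing]}"
        )
    has_n = d["n"] in df.columns
    if not has_n and study_n is None:
        raise SumstatsFormatError(f"{path}: no n column and no study_n fallback given")
    has_gene = d["gene_id"] in df.columns
    has_trait = d["trait_id"] in df.columns

    records: list[SumstatRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # header = line 1
        try:
            rec = SumstatRecord(
                variant_id=str(row[d["variant_id"]]),
                chrom=str(row[d["chrom"]]),
                pos=int(row[d["pos"]]),
                effect_allele=str(row[d["effect_allele"]]).upper(),
                other_allele=str(row[d["other_allele"]]).upper(),
                eaf=float(row[d["eaf"]]),
                beta=float(row[d["beta"]]),
                se=float(row[d["se"]]),
                p=float(row[d["p"]]),
                n=int(row[d["n"]]) if has_n else int(study_n),
                trait_id=str(row[d["trait_id"]]) if has_trait else trait_id,
                gene_id=str(row[d["gene_id"]]) if has_gene else None,
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(f"{path} line {i}: row rejected ({exc})", stacklevel=2)
            continue
        records.append(rec)
    return records


def write_sumstats(records: Iterable[SumstatRecord], path, dialect: Mapping[str, str] | None = None) -> None:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    records = list(records)
    cols = {
        d["chrom"]: [r.chrom for r in records],
        d["pos"]: [r.pos for r in records],
        d["variant_id"]: [r.variant_id for r in records],
        d["effect_allele"]: [r.effect_allele for r in records],
        d["other_allele"]: [r.other_allele for r in records],
        d["eaf"]: [r.eaf for r in records],
        d["beta"]: [r.beta for r in records],
        d["se"]: [r.se for r in records],
        d["p"]: [r.p for r in records],
        d["n"]: [r.n for r in records],
    }
    if any(r.gene_id is not None for r in records):
        cols[d["gene_id"]] = [r.gene_id or "" for r in records]
    if any(r.trait_id for r in records):
        cols[d["trait_id"]] = [r.trait_id for r in records]
    # repr round-trips doubles exactly, so read(write(x)) is the identity
    pd.DataFrame(cols).to_csv(
        path, sep="\t", index=False, float_format=lambda x: repr(float(x))
    )


def read_ld_matrix(path, build_tag: str = "hg19") -> LdReference:
    """Square correlation matrix: header row of variant ids, id column first."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return LdReference(list(df.columns), df.to_numpy(dtype=float), build_tag)


def write_ld_matrix(ld: LdReference, path) -> None:
    pd.DataFrame(ld.r_matrix, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


def read_ld_triplets(path, build_tag: str = "hg19") -> LdReference:
    """plink-style long format (id1, id2, r), densified with a unit diagonal."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id1", "id2", "r"])
    ids = sorted(set(df["id1"]).union(df["id2"]))
    index = {v: i for i, v in enumerate(ids)}
    r = np.eye(len(ids))
    for id1, id2, val in df.itertuples(index=False):
        r[index[id1], index[id2]] = val
        r[index[id2], index[id1]] = val
    return LdReference(ids, r, build_tag)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _complement_alleles(rec: SumstatRecord) -> SumstatRecord:
    return replace(
        rec,
        effect_allele=_COMPLEMENT.get(rec.effect_allele, rec.effect_allele),
        other_allele=_COMPLEMENT.get(rec.other_allele, rec.other_allele),
    )


def _sign_flip(rec: SumstatRecord) -> SumstatRecord:
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=1.0 - rec.eaf,
    )


def harmonize(
    exposure: SumstatRecord,
    outcome: SumstatRecord,
    palindrome_eaf_band: float = 0.08,
) -> HarmonizedPair:
    """Express the outcome record relative to the exposure effect allele.

    Palindromic variants (A/T or C/G) are dropped outright when the minor
    allele frequency is within ``palindrome_eaf_band`` of 0.5 in either
    study; otherwise their orientation is inferred from allele frequency
    agreement. Alleles irreconcilable even after strand complementing are
    dropped as unmatched.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError("harmonize requires records for the same variant")

    if exposure.is_palindromic():
        cutoff = 0.5 - palindrome_eaf_band
        if exposure.maf > cutoff or outcome.maf > cutoff:
            return HarmonizedPair(exposure, outcome, HarmonizeAction.DROPPED_PALINDROMIC)
        # orient by frequency: effect alleles agree iff eafs on the same side of 0.5
        same_side = (exposure.eaf < 0.5) == (outcome.eaf < 0.5)
        if exposure.effect_allele == outcome.effect_allele:
            if same_side:
                return HarmonizedPair(exposure, outcome, HarmonizeAction.UNCHANGED)
            return HarmonizedPair(exposure, _sign_flip(outcome), HarmonizeAction.SIGN_FLIPPED)
        # complementary labelling; align labels first, then check frequency
        flipped = _sign_flip(outcome)
        if (exposure.eaf < 0.5) == (flipped.eaf < 0.5):
            return HarmonizedPair(exposure, flipped, HarmonizeAction.SIGN_FLIPPED)
        return HarmonizedPair(exposure, outcome, HarmonizeAction.DROPPED_PALINDROMIC)

    candidates = [(outcome, False)]
    comp = _complement_alleles(outcome)
    if comp.alleles != outcome.alleles:
        candidates.append((comp, True))
    for cand, strand_flipped in candidates:
        if (cand.effect_allele == exposure.effect_allele
                and cand.other_allele == exposure.other_allele):
            action = (HarmonizeAction.STRAND_FLIPPED if strand_flipped
                      else HarmonizeAction.UNCHANGED)
            return HarmonizedPair(exposure, cand, action)
        if (cand.effect_allele == exposure.other_allele
                and cand.other_allele == exposure.effect_allele):
            return HarmonizedPair(exposure, _sign_flip(cand), HarmonizeAction.SIGN_FLIPPED)
    return HarmonizedPair(exposure, outcome, HarmonizeAction.DROPPED_UNMATCHED)
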