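"""Cis-eQTL instrument selection.

The instrument funnel: mask the MHC region (extreme LD complexity), keep
genome-wide significant associations (P < 5e-8, strict), greedily LD-clump
to an approximately independent set per gene (r² > 0.001 removed within a
10 Mb window of each index SNP), standardize effects to a per-SD-expression
scale, and compute instrument-strength statistics (PVE and the
Cragg–Donald F).

Standardization from summary statistics (z = β/se, MAF = min(eaf, 1−eaf)):

    β_std = z / sqrt(2·MAF·(1−MAF)·(n + z²))
    SE_std = 1 / sqrt(2·MAF·(1−MAF)·(n + z²))

Instrument strength:

    PVE = β² / (β² + se²·n)
    F   = PVE·(n − 1 − k) / ((1 − PVE)·k)

with k the number of instruments in the MR estimate (k = 1 for single-SNP
Wald MR, where F ≈ z²).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .sumstats import LdReference, SumstatRecord

__all__ = [
    "Instrument",
    "MHC_REGION",
    "mask_mhc",
    "significance_filter",
    "clump",
    "standardize",
    "instrument_strength",
    "make_instrument",
]

#: (chrom, start, end) of the major histocompatibility complex, hg19, inclusive.
MHC_REGION = ("6", 24_000_000, 36_000_000)


@dataclass(frozen=True)
class Instrument:
    """A standardized, clumped cis-eQTL instrument with strength statistics."""

    record: SumstatRecord
    z: float
    beta_std: float
    se_std: float
    gene_id: str
    pve: float = float("nan")
    f_stat: float = float("nan")

    @property
    def variant_id(self) -> str:
        return self.record.variant_id


def _norm_chrom(chrom: str) -> str:
    return chrom.lower().removeprefix("chr")


def mask_mhc(
    records: list[SumstatRecord],
    chrom: str = MHC_REGION[0],
    start_bp: int = MHC_REGION[1],
    end_bp: int = MHC_REGION[2],
) -> list[SumstatRecord]:
    """Remove variants inside [start_bp, end_bp] (inclusive) on ``chrom``."""
    c = _norm_chrom(chrom)
    return [
        r for r in records
        if not (_norm_chrom(r.chrom) == c and start_bp <= r.pos <= end_bp)
    ]


def significance_filter(records: list[SumstatRecord], p_threshold: float = 5e-8) -> list[SumstatRecord]:
    """Keep records with p strictly below the threshold."""
    return [r for r in records if r.p < p_threshold]


def clump(
    records: list[SumstatRecord],
    ld: LdReference,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
) -> list[SumstatRecord]:
    """Greedy LD clumping to an approximately independent instrument set.

    Repeatedly keeps the lowest-p remaining record (ties broken by (chrom,
    pos, variant_id) for determinism) and removes every record with
    r² > ``r2_threshold`` within ± ``window_bp``/2 of it. Variants absent
    from the LD reference are dropped beforehand with a warning.
    """
    missing = [r.variant_id for r in records if r.variant_id not in ld]
    if missing:
        warnings.warn(
            f"{len(missing)} variant(s) absent from LD reference dropped before "
            f"clumping: {missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    pool = sorted(
        (r for r in records if r.variant_id in ld),
        key=lambda r: (r.p, r.chrom, r.pos, r.variant_id),
    )
    half_window = window_bp / 2
    kept: list[SumstatRecord] = []
    while pool:
        index = pool.pop(0)
        kept.append(index)
        pool = [
            r for r in pool
            if not (
                _norm_chrom(r.chrom) == _norm_chrom(index.chrom)
                and abs(r.pos - index.pos) <= half_window
                and ld.r2(index.variant_id, r.variant_id) > r2_threshold
            )
        ]
    return sorted(kept, key=lambda r: (r.chrom, r.pos, r.variant_id))


def standardize(record: SumstatRecord) -> Instrument:
    """Rescale an eQTL effect to per-SD-of-expression units.

    Strength statistics are left unset; use :func:`make_instrument` for a
    complete instrument.
    """
    if record.eaf <= 0.0 or record.eaf >= 1.0:
        raise ValueError(
            f"{record.variant_id}: degenerate allele frequency {record.eaf}"
        )
    z = record.beta / record.se
    maf = record.maf
    denom = math.sqrt(2.0 * maf * (1.0 - maf) * (record.n + z * z))
    se_std = 1.0 / denom
    return Instrument(
        record=record,
        z=z,
        beta_std=z * se_std,
        se_std=se_std,
        gene_id=record.gene_id or "",
    )


def instrument_strength(
    beta_std: float, se_std: float, n: int, k: int = 1
) -> tuple[float, float]:
    """PVE and Cragg–Donald F-statistic for an instrument.

    ``n`` is the instrument sample size (average over instruments if k > 1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pve = beta_std**2 / (beta_std**2 + se_std**2 * n)
    if pve >= 1.0:
        warnings.warn("PVE >= 1 numerically; clipping", stacklevel=2)
        pve = 1.0 - 1e-12
    if pve == 0.0:
        return 0.0, 0.0
    f = pve * (n - 1 - k) / ((1.0 - pve) * k)
    return pve, f


def make_instrument(record: SumstatRecord, k: int = 1) -> Instrument:
    """Standardize a record and fill in PVE and F."""
    partial = standardize(record)
    pve, f = instrument_strength(partial.beta_std, partial.se_std, record.n, k)
    return Instrument(
        record=partial.record,
        z=partial.z,
        beta_std=partial.beta_std,
        se_std=partial.se_std,
        gene_id=partial.gene_id,
        pve=pve,
        f_stat=f,
    )
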