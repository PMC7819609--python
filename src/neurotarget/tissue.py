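"""Cross-dataset and cross-tissue comparison, fixed-effects meta-analysis,
and GWAS-by-proxy construction.

Fixed-effects inverse-variance meta-analysis with Cochran's Q for
heterogeneity (flagged at Q p < 0.001) supports two uses: pooling an eQTL
effect across brain tissues, and combining a case-control GWAS with a
family-history (GWAS-by-proxy) study whose log-odds effects have first
been rescaled by a factor of two to the case-control scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .sumstats import SumstatRecord

__all__ = [
    "MetaResult",
    "CompareResult",
    "fixed_effects_meta",
    "cross_dataset_compare",
    "proxy_gwas_scale",
    "proxy_meta",
]

HET_P_THRESHOLD = 0.001


@dataclass(frozen=True)
class MetaResult:
    beta_fixed: float
    se_fixed: float
    q_stat: float
    q_df: int
    q_p: float
    het_flag: bool  # Cochran's Q p strictly below 0.001


@dataclass(frozen=True)
class CompareResult:
    pearson_r: float
    ci95: tuple[float, float]
    n: int
    n_sig: int            # dataset-b effects below sig_threshold
    n_sign_agree: int     # among b effects with p < 0.05
    n_sign_disagree: int


def fixed_effects_meta(effects: list[tuple[float, float]]) -> MetaResult:
    """Inverse-variance weighted fixed-effects pooling of (beta, se) pairs."""
    if len(effects) < 2:
        raise ValueError("meta-analysis requires at least 2 effects")
    beta = np.array([b for b, _ in effects], dtype=float)
    se = np.array([s for _, s in effects], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all se must be > 0")
    w = 1.0 / se**2
    beta_fixed = float(np.sum(w * beta) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (beta - beta_fixed) ** 2))
    df = len(effects) - 1
    q_p = float(stats.chi2.sf(q, df))
    return MetaResult(beta_fixed, se_fixed, q, df, q_p, het_flag=q_p < HET_P_THRESHOLD)


def cross_dataset_compare(
    beta_a,
    beta_b,
    p_b,
    sig_threshold: float = 5e-8,
    *,
    nominal_alpha: float = 0.05,
) -> CompareResult:
    """Agreement between matched effect estimates from two datasets.

    Pearson correlation with a Fisher-z 95% CI (variance 1/(n−3)); counts
    of dataset-b effects reaching ``sig_threshold`` and of sign
    (dis)agreement among b effects with p < 0.05. Effects must be
    harmonized to common alleles before matching.
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    pb = np.asarray(p_b, dtype=float)
    if not (a.shape == b.shape == pb.shape):
        raise ValueError("matched vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 matched pairs for a Fisher-z CI")
    r = float(stats.pearsonr(a, b).statistic)
    if abs(r) < 1.0:
        zr = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(a.size - 3)
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    else:
        ci = (r, r)
    nominal = pb < nominal_alpha
    agree = int(np.sum(nominal & (np.sign(a) == np.sign(b))))
    disagree = int(np.sum(nominal & (np.sign(a) != np.sign(b))))
    return CompareResult(
        pearson_r=r,
        ci95=ci,
        n=int(a.size),
        n_sig=int(np.sum(pb < sig_threshold)),
        n_sign_agree=agree,
        n_sign_disagree=disagree,
    )


def proxy_gwas_scale(records: list[SumstatRecord], factor: float = 2.0) -> list[SumstatRecord]:
    """Rescale family-history (proxy) log-odds effects to the case-control
    scale: beta and se both multiplied by ``factor``; z and p unchanged."""
    return [replace(r, beta=r.beta * factor, se=r.se * factor) for r in records]


def proxy_meta(
    case_gwas: list[SumstatRecord],
    proxy_gwas_scaled: list[SumstatRecord],
) -> tuple[list[SumstatRecord], list[bool]]:
    """Per-variant fixed-effects meta of a case-control and a scaled proxy GWAS.

    Variant sets must be harmonized to common alleles. Variants present in
    only one study are passed through unchanged with a ``False`` flag in
    the parallel meta-analyzed indicator list.
    """
    proxy_by_id = {r.variant_id: r for r in proxy_gwas_scaled}
    out: list[SumstatRecord] = []
    meta_flags: list[bool] = []
    seen = set()
    for rec in case_gwas:
        other = proxy_by_id.get(rec.variant_id)
        if other is None:
            out.append(rec)
            meta_flags.append(False)
            continue
        seen.add(rec.variant_id)
        m = fixed_effects_meta([(rec.beta, rec.se), (other.beta, other.se)])
        z = m.beta_fixed / m.se_fixed
        n_eff = rec.n + other.n
        eaf = (rec.eaf * rec.n + other.eaf * other.n) / n_eff
        out.append(replace(
            rec,
            beta=m.beta_fixed,
            se=m.se_fixed,
            p=float(2.0 * stats.norm.sf(abs(z))),
            n=n_eff,
            eaf=eaf,
        ))
        meta_flags.append(True)
    for rec in proxy_gwas_scaled:
        if rec.variant_id not in seen:
            out.append(rec)
            meta_flags.append(False)
    return out, meta_flags
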