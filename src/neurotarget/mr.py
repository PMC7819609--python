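"""Mendelian-randomization estimators.

The primary estimator is the single-SNP Wald ratio: with a standardized
eQTL exposure effect β_x (per SD of expression) and a harmonized outcome
effect β_y (log-odds for disease traits),

    WR = β_y / β_x,
    SE(WR) = sqrt( SE_y² + WR²·SE_x² ) / |β_x|   (first-order delta),

so a positive Wald ratio means higher expression raises disease risk.
The SE is the full first-order delta for a ratio; the exposure-noise term
WR²·SE_x² matters whenever the outcome association is as strong as the
instrument (routinely the case for genome-wide significant hits) and
dropping it produces anti-conservative confidence intervals. Second- and
higher-order terms are neglected (negligible at instrument F > 10). The
p-value, by contrast, is the score test of a zero causal effect — the
two-sided normal tail of β_y/SE_y, identical to WR over the outcome-only
SE — which stays exactly calibrated under the null at any instrument
strength, where a Wald test built on the delta SE would be conservative.
Multi-SNP estimators (inverse-variance weighted regression, MR-Egger with
a free pleiotropy intercept, and the weighted median) are provided for the
reverse-MR direction where several instruments are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .instruments import Instrument
from .sumstats import SumstatRecord

__all__ = [
    "WaldResult",
    "MultiSnpResult",
    "wald_ratio",
    "wald_ratio_components",
    "bonferroni_threshold",
    "ivw",
    "egger",
    "weighted_median",
]


@dataclass(frozen=True)
class WaldResult:
    """Single-SNP MR estimate: log-odds change in risk per SD of expression."""

    gene_id: str
    trait_id: str
    variant_id: str
    wr: float
    se: float
    p: float
    passes_bonferroni: bool = False


@dataclass(frozen=True)
class MultiSnpResult:
    method: str  # "ivw" | "egger" | "weighted_median"
    slope: float
    slope_se: float
    p: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


def _two_sided_normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio_components(
    beta_exp: float, beta_out: float, se_out: float, se_exp: float = 0.0
) -> tuple[float, float, float]:
    """(WR, SE, p) from raw components.

    The p-value is the score test of zero causal effect, the two-sided
    tail of β_y/SE_y — equal to WR over the outcome-only SE — which is
    exactly calibrated under the null regardless of instrument strength.
    The reported SE is the full delta form for interval construction;
    with ``se_exp = 0`` it reduces to the outcome-only SE and the two
    coincide.
    """
    if beta_exp == 0.0:
        raise ValueError("zero exposure effect; Wald ratio undefined")
    wr = beta_out / beta_exp
    se = np.sqrt(se_out**2 + wr**2 * se_exp**2) / abs(beta_exp)
    return wr, float(se), _two_sided_normal_p(beta_out / se_out)


def wald_ratio(
    instrument: Instrument,
    outcome: SumstatRecord,
    *,
    bonferroni_p: float | None = None,
) -> WaldResult:
    """Wald ratio for one instrument against a harmonized outcome record.

    ``outcome`` must already be expressed relative to the instrument's
    effect allele (see :func:`neurotarget.sumstats.harmonize`).
    """
    if instrument.beta_std == 0.0:
        raise ValueError(f"{instrument.variant_id}: zero exposure effect; Wald ratio undefined")
    wr, se, p = wald_ratio_components(
        instrument.beta_std, outcome.beta, outcome.se, instrument.se_std
    )
    return WaldResult(
        gene_id=instrument.gene_id,
        trait_id=outcome.trait_id,
        variant_id=instrument.variant_id,
        wr=wr,
        se=se,
        p=p,
        passes_bonferroni=(bonferroni_p is not None and p < bonferroni_p),
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error threshold alpha / n_tests (full precision)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _as_arrays(beta_exp, beta_out, se_out):
    bx = np.asarray(beta_exp, dtype=float)
    by = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    if not (bx.shape == by.shape == sy.shape):
        raise ValueError("effect vectors must have equal length")
    return bx, by, sy


def ivw(beta_exp, beta_out, se_out) -> MultiSnpResult:
    """Inverse-variance weighted regression through the origin.

    Weighted least squares of outcome betas on exposure betas with weights
    1/se_out² and no intercept (fixed-effect IVW).
    """
    bx, by, sy = _as_arrays(beta_exp, beta_out, se_out)
    if bx.size < 2:
        raise ValueError("IVW requires at least 2 instruments")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    slope = float(np.sum(w * bx * by)) / sxx
    slope_se = 1.0 / np.sqrt(sxx)
    return MultiSnpResult(
        method="ivw",
        slope=slope,
        slope_se=slope_se,
        p=_two_sided_normal_p(slope / slope_se),
        n_snps=int(bx.size),
    )


def egger(beta_exp, beta_out, se_out) -> MultiSnpResult:
    """MR-Egger: weighted regression with a free intercept.

    Exposure effects are oriented positive first (flipping the outcome
    accordingly) so the intercept captures average directional pleiotropy.
    P-values use the t distribution with n−2 df.
    """
    bx, by, sy = _as_arrays(beta_exp, beta_out, se_out)
    if bx.size < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    return MultiSnpResult(
        method="egger",
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n_snps=int(bx.size),
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        intercept_p=float(fit.pvalues[0]),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(
    beta_exp, se_exp, beta_out, se_out, n_boot: int = 1000, seed: int | None = None
) -> MultiSnpResult:
    """Inverse-variance weighted median of per-SNP ratios.

    Robust to up to 50% invalid instruments by weight. The SE comes from a
    seeded parametric bootstrap: both effect vectors are resampled from
    their normal sampling distributions ``n_boot`` times.
    """
    bx, by, sy = _as_arrays(beta_exp, beta_out, se_out)
    sx = np.asarray(se_exp, dtype=float)
    if bx.size < 2:
        raise ValueError("weighted median requires at least 2 instruments")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for the bootstrap")
    ratios = by / bx
    ratio_se = sy / np.abs(bx)
    est = _weighted_median(ratios, 1.0 / ratio_se**2)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        rb = byb[ok] / bxb[ok]
        wb = (np.abs(bxb[ok]) / sy[ok]) ** 2
        boot[b] = _weighted_median(rb, wb)
    se = float(np.std(boot, ddof=1))
    p = _two_sided_normal_p(est / se) if se > 0 else (1.0 if est == 0 else 0.0)
    return MultiSnpResult(
        method="weighted_median",
        slope=est,
        slope_se=se,
        p=p,
        n_snps=int(bx.size),
    )
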