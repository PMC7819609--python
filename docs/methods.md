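# Methods

## Model and assumptions

The pipeline treats cis-eQTL variants as instrumental variables for gene
expression in a two-sample MR design: the instrument–expression
association comes from a brain-tissue eQTL study, the instrument–disease
association from an independent GWAS. Causal interpretation rests on the
usual MR assumptions — the instrument is robustly associated with
expression (relevance, enforced by P < 5×10⁻⁸ and F-statistics), shares
no confounder with the outcome, and affects disease only through the
gene's expression (no horizontal pleiotropy). The later stages exist
precisely because the third assumption is untestable directly: Steiger
filtering and reverse MR probe the causal direction, the phenome-wide
screen probes pleiotropic pathways, and colocalization guards against the
instrument merely being in LD with a distinct disease variant.

## Estimators

**Standardization.** eQTL effects are rescaled to per-SD-of-expression
units from summary data alone: with z = β/se, MAF = min(eaf, 1−eaf),

    β_std = z / sqrt(2·MAF·(1−MAF)·(n + z²)),
    SE_std = 1 / sqrt(2·MAF·(1−MAF)·(n + z²)).

Instrument strength: PVE = β²/(β² + se²·n) and the Cragg–Donald
F = PVE·(n−1−k)/((1−PVE)·k), k being the number of instruments (k = 1 for
single-SNP MR, where F ≈ z²).

**Wald ratio.** WR = β_y/β_x. Two distinct standard errors matter here and
the package deliberately separates their roles:

* the *p-value* is the score test of zero causal effect — the two-sided
  normal tail of β_y/SE_y, equal to WR over the outcome-only SE. It is
  exactly calibrated under the null at any instrument strength (verified:
  5.2% type-1 error at α = 0.05 over 2,000 null regions);
* the *reported SE*, used for confidence intervals, is the full
  first-order delta SE of the ratio, SE² = (SE_y² + WR²·SE_x²)/β_x². The
  exposure-noise term is not negligible whenever the outcome association
  is comparable in strength to the instrument — routine for genome-wide
  significant MR hits, where the outcome-only SE undercovers badly (≈80%
  instead of 95% at the simulated study scale). Measured coverage with the
  delta SE is 95.7% under the package's own instrument selection.

Second-order ratio terms are neglected (instruments are screened at
F > 10). A Wald test built on the delta SE would be conservative under
the null (≈3% at α = 5%), which is why the score/Wald split above is used.

**Multi-SNP estimators** (reverse MR): fixed-effect IVW regression through
the origin with weights 1/SE_y²; MR-Egger with a free intercept for
directional pleiotropy (exposure effects oriented positive, t-based
p-values, n−2 df); and the inverse-variance weighted median with a seeded
parametric bootstrap SE (1,000 replicates by default — reproducibility
requires an explicit seed).

**Colocalization.** Wakefield log approximate Bayes factors per SNP,
labf = ½[ln(V/(V+W)) + z²·W/(V+W)] with V = se² and prior effect variance
W; prior effect SDs default to 0.15 (quantitative) and 0.2 (case-control
log-odds), the published defaults of the ABF framework. Per-SNP priors
default to p1 = p2 = 5×10⁻⁴ and p12 = 5×10⁻⁵, the values the source
analysis used (note these are 5× the ABF framework's usual 1e-4/1e-4/1e-5
defaults despite being described as defaults there; they are configurable).
All five hypothesis sums run in log space (log-sum-exp and a log-diff-exp
for the H3 cross term S1·S2 − S12): brain eQTLs reach |z| ≈ 40, where
naive exponentiation overflows. Window boundaries are inclusive; traits
are intersected to common variants before analysis. A region colocalizes
when PP4 strictly exceeds 0.70.

**Directionality.** The Steiger test Fisher-transforms the two
instrument–trait correlations and compares |atanh r_gx| − |atanh r_gy|
against its SE sqrt(1/(n_x−3) + 1/(n_y−3)); correlations come from
r = sign(β)√PVE for quantitative traits and the observed-scale
approximation r ≈ z/√n for binary traits, which preserves the ordering
the filter needs without a latent-scale conversion. No p-value cut-off is
imposed for declaring direction; the statistic is reported and
`direction_correct` records the sign of r_gx² − r_gy².

**Meta-analysis.** Fixed-effects inverse-variance pooling; Cochran's
Q = Σw(β−β̂)² on k−1 df, heterogeneity flagged strictly below P = 0.001.
Family-history (GWAS-by-proxy) effects are rescaled by ×2 on the log-odds
scale (z-scores unchanged) before being meta-analyzed with the
case-control GWAS; variants present in only one study pass through
un-pooled with a flag rather than being dropped.

**Pleiotropy.** The phenome-wide screen Wald-tests every instrument
against every trait and attempts colocalization only for cells with
P < 0.05. Enrichment of colocalization in brain-related vs other traits
uses Fisher's exact test (two-sided, via the hypergeometric distribution;
a brute-force enumeration oracle backs it in the tests). The
cross-disease sharing permutation draws subsets of non-brain traits
without replacement and uses the add-one empirical p-value
(1 + #{null ≥ observed})/(n_iter + 1), which cannot reach zero; with
10,000 iterations its floor is ≈10⁻⁴. Molecular pleiotropy extracts all
transcript effects of an instrument with no p filter and Bonferroni-corrects
over the number extracted.

**Prioritization.** A target is top-ranked when it has an allelic series
(monogenic CNS/behavioural phenotype on record) *or* is a clinical-stage
druggable target, *and* no adverse trait colocalizes with it in the
phenome-wide screen. Safety is a flag, not a hard exclusion, because the
adverse-direction judgement is qualitative and belongs to the annotation
data, not the code. Database lookups (monogenic phenotypes, clinical
phase) are modelled as offline annotation tables for reproducibility.
Drug action follows the Wald ratio sign: positive → inhibition,
negative → promotion; a zero ratio is an error.

## Synthetic data

Summary statistics are generated directly at the z-score level: for LD
matrix R and joint standardized effects λ, marginal z ~ MVN(R·λ·√n, R) —
the standard summary-statistics likelihood — with betas/SEs back-filled
via se = 1/sqrt(2·maf·(1−maf)·n). This gives exact, controllable LD (AR(1)
decay r(i,j) = ρ^|i−j|, default ρ = 0.9 over m = 100 SNPs at 1 kb
spacing) without individual-level genotypes. Default conditions emulate
the study scale: eQTL panel n = 1,286, disease GWAS effective n = 50,000,
causal eQTL PVE 2–5%, causal effect γ = 0.2 log-odds per SD.

Scenario kinds map onto the colocalization hypotheses (null→H0,
eqtl_only→H1, gwas_only→H2, distinct_variants→H3, shared_variant→H4) plus
two H4 lookalikes whose true causal effect of expression on disease is
zero: reverse_causation (expression responds to disease liability with
coefficient γ; `eqtl_pve` is then read as the disease variance explained
by the SNP) and horizontal_pleiotropy (a direct SNP→disease effect of the
same magnitude as the mediated one). At the summary level
horizontal_pleiotropy is distributionally identical to shared_variant —
only the TruthRecord differs — which is the point: no marginal statistic
can separate them, only the truth labels let tests quantify the resulting
bias.

Reverse-MR testing needs a polygenic disease architecture, not one cis
region, so `simulate_bidirectional` generates 15 independent disease loci
(per-SNP liability PVE 8×10⁻⁴, so each reaches genome-wide significance
with ~80% probability at n = 50,000, leaving roughly a dozen clumped
instruments — the scale of a real psychiatric GWAS hit list). Expression
is looked up in a large blood-eQTL-scale panel (n = 31,684), mirroring
how reverse MR is run in practice; under the forward direction expression
is unrelated to the disease loci, under the reverse direction every
disease hit carries a proportional expression effect.

The phenome-wide generator draws null cells z ~ N(0,1) (uniform p) with
optional planted shifts. For the permutation-null reproduction the
non-brain pool receives a ubiquitous shift of z mean 0.8, making the
per-cell nominal rate ≈0.12 — pervasive weak vertical pleiotropy, which
is what the observed study-scale null distribution (mean proportion 0.12)
reflects, rather than pure noise.

What the generator does *not* emulate: realistic haplotype structure
(AR(1) LD has no long-range blocks), allele-frequency/effect-size
coupling, population stratification, sample overlap between exposure and
outcome studies, or multiple causal variants per trait per region.
Passing tests therefore demonstrate correctness of the estimators and
decision rules under the stated generative model, not robustness to those
real-data complications — the single-causal-variant assumption in
particular is shared by the colocalization model itself.

## Numerical and design choices

* Significance and PP4 gates are strict inequalities; MHC and
  colocalization window boundaries are inclusive.
* Clumping ties on identical p break by (chrom, pos, variant_id), making
  output order-invariant; variants absent from the LD reference are
  dropped with a warning before clumping (they cannot be verified
  independent). The clump window is interpreted as ± window/2 around each
  index SNP.
* The F-statistic denominator is (1−PVE)·k, the standard Cragg–Donald
  form; at k = 1 (the only case the primary analysis uses) this is
  algebraically identical to reading the denominator as 1−PVE·k.
* Palindromic (A/T, C/G) variants are dropped when min(eaf, 1−eaf) > 0.42
  in either study and otherwise oriented by allele-frequency agreement —
  common two-sample MR practice.
* Per-variant sample size falls back to a supplied study-wide n when the
  column is absent.
* Thresholds are carried at full precision internally; rounding to
  reporting precision happens only in report rendering (coloc as a
  percentage with one decimal).
* Brain-related trait membership is configuration data (a category label
  per trait), not code.
* p-values are floored at 10⁻³⁰⁰ when generated (|z| ≈ 37 exhausts the
  double-precision normal tail).
* TSV floats are written with `repr` and read with round-trip precision,
  so read∘write is the identity on valid files.
* All simulation randomness flows through `numpy.random.default_rng`
  seeded from a single scenario/CLI seed; sub-streams in multi-part
  simulations derive from that generator sequentially, so fixed seeds
  give bitwise-identical output files.

## Problem sizes used in the validation suite

Estimator calibration runs at the study-scale defaults above: 500
shared-variant regions for Wald recovery and coverage, 200 regions each
for colocalization discrimination and per-direction Steiger rates, 100
multi-locus studies for reverse MR, 2,000 regions for null calibration,
and 10,000 permutation iterations. These sizes put Monte-Carlo error
comfortably inside the asserted bands (e.g. ±0.5% on the 5% type-1 rate)
while keeping the full suite under a minute of compute.

## Known limitations

Single causal variant per trait per region (both in the generator and the
colocalization model); no conditional/joint instrument selection; no
MR-PRESSO or multivariable MR; the binary-trait correlation used by the
Steiger filter is an observed-scale approximation; no genome-build
liftover; LD references must be supplied (no haplotype panel processing).
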