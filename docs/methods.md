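# Methods

This note documents the statistical models, the numerical choices that were
genuinely open, the synthetic-data generators and what passing tests do and
do not establish about real data.

## Exon-level stability ranking

Expression is quantified as TPM per exon:
TPM_es = (count_es/length_e) / Σ_e(count/length)_s × 10⁶, so each sample
column sums to 10⁶.  A candidate sequence is a single exon or a neighbour
combination (adjacent pair, skip pair, trio); its per-sample expression is
the **sum** of member-exon TPM.  Summing mirrors what an exon-border-
spanning amplicon reports; a mean differs only by a constant factor and,
because the CV is scale-invariant, yields identical rankings — the choice
is consequence-free and documented rather than inferred.  The CV uses the
sample SD (n−1): cohorts of 7–15 samples are small enough that the
denominator convention matters.  Combinations with zero mean are dropped;
the default ceiling CV ≤ 1 discards sequences that are useless as
normalizers anyway.  Ties are broken by higher mean abundance (robust
assays prefer abundant templates), then lexicographically, so output is
deterministic.  No minimum-abundance floor is applied by default; the CV
ceiling is the only filter.

GO-term enrichment uses the two-sided Fisher exact test on the standard
2×2 table with Benjamini–Hochberg correction across tested terms and an
FDR < 0.01 report threshold.  The two-sided tail is summed with exact
integer arithmetic (`math.comb`), avoiding the floating-point tie guard a
general-purpose implementation needs; p-values therefore match a
rational-arithmetic oracle to full precision.

## Amplification efficiency and Cq processing

Per-well efficiency comes from the raw, not baseline-corrected curve.  The
estimator (a) estimates the baseline as the median of the first 5 cycles,
(b) restricts attention to cycles whose baseline-subtracted fluorescence
lies between 2% and 90% of the plateau, (c) slides a 5-cycle window over
that region, fitting log₁₀ F_b against cycle by least squares, and
(d) keeps the window maximizing R², reporting E = 10^slope − 1.  When the
curve has visibly plateaued (tail rise < 5% of the signal), the fit uses
the exact logistic linearization log₁₀(F_b/(P−F_b)) with the plateau P
taken from the tail mean — on a logistic curve this removes saturation
bias entirely, and on a still-rising (purely exponential) curve the plain
log fit applies, so both limits are exact when noise-free.  Estimates with
best R² below 0.99 carry a low-confidence flag; flat curves raise a typed
no-amplification signal.  All knobs (window length, fractional bounds, R²
threshold, baseline cycles) live in `EfficiencyConfig`.

At realistic well noise (≤ 1% of the plateau) a single 5-point window has
an irreducible estimator SD of ≈ 0.04–0.06, so recovery to ±0.05 is the
property of the **assay-level mean** E_fi over wells — which is exactly
the quantity the adjustment uses — while individual wells reach ±0.05
only at small noise (≈ 0.2% of plateau).  The estimator is unbiased to
±0.002 across E ∈ {0.7, 0.85, 1.0}.

Adjusted Cq = Cq · log₁₀(E_fi+1)/log₁₀2 is linear in Cq and the identity
at E_fi = 1; adjusted differences are exact log₂ fold changes.  The
0.5-cycle quadruplicate rule removes the leave-one-out SD minimizer (the
only deterministic reading of "the replicate that caused" the excess SD);
if no single removal suffices, all four wells are kept and the case
escalates to the cDNA rule.  The 1-cycle cDNA rule drops the replicate
deviating more from the assay's cohort-wide mean of adjusted Cq (all wells
of the assay); ties drop replicate 2, flagged.  At most one well per
quadruplicate and one cDNA replicate per cell can be removed, and every
removal is written to the audit log with its rule id.

dPCR: λ = −ln(1 − positives/partitions), concentration λ/volume, copies in
reaction λ·partitions.  Zero positives gives λ = 0; all-positive chips
raise a saturation error rather than ±∞.  Copies follow from a calibrator
as copies_cal · 2^(ΔCq_adj).

## Stability algorithms

* **geNorm** — V_jk = SD_s log₂(q_j/q_k); M_j = mean_k V_jk.  Stepwise
  exclusion of the max-M gene (ties: reverse-lexicographic, deterministic)
  recomputes M from scratch each round; the final two genes are reported
  as a tie at fractional rank 1.5 because the algorithm cannot separate
  them.  NF_n is the per-sample geometric mean of the n most stable genes;
  V_n = SD_s log₂(NF_n/NF_{n+1}); the optimal count n* is the smallest n
  with V_n below the 0.15 convention.  M and V are invariant to per-gene
  positive rescaling, so the exact provenance of the linear quantities
  (any 2^(minCq−Cq)-style transform) cannot change rankings.
* **NormFinder** (default group-free; single-condition cohorts) — the
  stability of a gene is the SD over samples of its log₂ quantity after
  removing per-sample means: the residual of the additive sample+gene
  model.  The grouped variant combines the absolute inter-group gene
  effect with the within-group residual standard error, a simplified form
  of the published bias-corrected combination; it needs ≥ 2 samples per
  group.
* **BestKeeper** — descriptive SD(Cq) and CV% plus Pearson r against the
  index (per-sample geometric mean Cq).  The original tool ranks
  descriptively; SD(Cq) ascending is the single primary key used here so
  its output can enter rank aggregation, with SD > 1 flagged inconsistent.
* **comparative ΔCq** — mean over partner genes of SD_s(ΔCq); invariant
  under per-gene additive Cq shifts.

geNorm/NormFinder consume linear quantities (log₂ internally); BestKeeper
and ΔCq consume adjusted Cq directly — each tool's own published input
convention.

## Rank aggregation

The consensus minimizes the summed Spearman footrule distance to the input
lists.  Ties inside a list enter as shared fractional ranks.  The default
distance is unweighted; the weighted mode maps each item's displacement
onto the reference list's normalized score ladder (so swapping near-tied
items is nearly free).  Unweighted is the default because the appropriate
weight vector is context-dependent and no single choice is canonical.

The cross-entropy Monte Carlo sampler draws orders position-by-position
from a (position × item) probability matrix, keeps the ρ = 0.1 elite of
n_samples = 10k² draws, and moves the matrix toward the elite frequencies
with learning rate 0.3 until the matrix changes by < 10⁻⁶ or 1000
iterations pass; the best order ever sampled is returned with a converged
flag, and everything is deterministic given the seed.  An exhaustive
enumerator (≤ 8 items) provides the exact optimum; on random ≤ 6-item
instances the sampler attains it in ≥ 98% of runs (100% in the shipped
check).

## qIHC scoring

Optical density uses OD = −log₁₀((I+1)/256) per 8-bit channel (the +1
keeps OD finite at I = 0); the synthetic forward model is the exact
inverse, so deconvolution inverts it to machine precision before
quantization.  Stain vectors default to the standard H-DAB pair with an
orthogonal residual third vector.  The scoring pipeline: tissue mask =
pixels whose mean intensity ≤ 200 (whiter pixels are slide background);
deconvolved DAB channel rendered back to 8-bit display intensity;
bilateral filter (spatial σ 3 px, range σ 25 — mild edge-preserving
denoising; the protocol's own parameters are not published, these defaults
pass all round-trip tolerances); positivity = display ≤ 200 (darker than
background); 8-connected components smaller than ceil(15 µm²/resolution²)
pixels removed as granular artefacts; p = positive/tissue pixels.  Both
200-thresholds are separately configurable because an intensity threshold
can defensibly be read pre- or post-deconvolution; the post-deconvolution
reading is the default.  logit(p) handles p ∈ {0, 1} by clamping at half a
pixel of positive area (ε = 1/(2·tissue pixels)) or, on request, raising.

## The readout

x = log₁₀(normalized copies), y = logit(p).  Spearman ρ is exact-p for
n ≤ 12 via the exact null distribution of T = Σ i·σ(i), computed by a
bitmask dynamic program over assigned ranks — identical to enumerating all
n! permutations at a fraction of the cost — and t-approximated above (the
cohorts of interest, 7–13 samples, straddle that boundary).  Pearson r
accompanies ρ with two-sided p.  `evaluate_normalizers` ranks candidates
by ρ (ties: higher r, then lexicographic) and flags ties.  Grubbs
flags — never removes — its outlier candidate (two-sided, t-mapping
p = min(1, 2n·sf(t, n−2))); KS normality uses the Lilliefors correction
because parameters are estimated from the data; the paired Wilcoxon test
is exact for n ≤ 25 with zero differences dropped (all-zero: p = 1).  The
choice between alternative section scores of a single sample maximizes the
regression r² with all other samples held fixed and always emits a
selection-bias warning, because the choice is post hoc.

## Synthetic data: what it emulates and what it does not

Gene abundance across samples is log-normal with σ² = ln(1+CV²), matching
the multiplicative variation expression data show; exon counts distribute
gene abundance over exons by length with Poisson noise; splicing
perturbation multiplies one interior exon by a per-sample Beta(2,2)
inclusion factor, producing exactly the single-exon instability the
neighbour-pair design guards against.  Cq wells follow
intercept − log_(1+E)(copies) plus a cDNA-replicate effect and well noise;
injected outliers shift one well by 2.5 cycles or one cDNA replicate by
2 cycles — comfortably beyond the 0.5- and 1-cycle triggers.  Curves are
logistic with early-phase ratio exactly 1+E.  Images are Beer–Lambert
renderings of a compact positive region covering the requested tissue
fraction plus optional sub-15-px speckles.  The coupled cohort draws
log₁₀ copies uniformly over about two decades and links
logit(p) = α + β log₁₀(copies) + ε; defaults (n = 13, β = 1.5,
ε_sd = 0.4) emulate a readout near ρ ≈ 0.8.  The normalizer benchmark
multiplies true copies by a shared log-normal nuisance (SD 0.5 log₂
units) and offers a tracking and an independent candidate; its defaults
(β = 2.0, ε_sd = 0.1, 1.5 decades) put the selection task in a regime
where the designed normalizer wins ≥ 95 of 100 cohorts.  The end-to-end
bundle raises the nuisance to 1.2 log₂ units so that input-mass
normalization visibly degrades the readout, as poorly normalized
measurements do in practice.

Not emulated: read-level sequencing artefacts (GC bias, mapping errors,
duplicates), between-run qPCR drift, melt-curve behaviour, chromatic
aberration or uneven illumination in imaging, spatial tumour
heterogeneity across sections, and any mRNA–protein link other than the
logit-linear form.  Passing recovery tests therefore shows the estimators
invert their own generative assumptions correctly — not that those
assumptions exhaust real tissue data.

## Problem sizes and determinism

The shipped checks use 200-gene × 10-sample count tables, 100 curves per
efficiency level, 100 selection cohorts of 13 samples, 200 coupled cohorts,
50 aggregation instances and 192–256 px images; these sizes give stable
rates while keeping a full run in well under a minute.  Every stochastic
path takes an explicit seed; identical seeds give byte-identical tables
and pixel-identical images, and output files carry a config-hash/seed
provenance header.

## Known limitations

* The three cohort worked-example tests require externally supplied
  workbook exports; without them they fail by design rather than silently
  skipping.
* NormFinder's grouped mode is a simplified variance combination, not a
  line-by-line port of the original spreadsheet.
* BestKeeper's descriptive output is reduced to one sort key for
  aggregation; users wanting the full descriptive table get it in the
  result frame.
* The efficiency estimator assumes a single sigmoidal rise; multiphasic
  curves (primer-dimer plus product) will fit the dominant phase and flag
  low confidence at best.
* Footrule aggregation treats all algorithms equally unless weights are
  supplied; the four algorithms share information, so the consensus is not
  a statistical meta-analysis.
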