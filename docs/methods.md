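# Methods

This note documents the models implemented in `epiherit`, the defaults and
their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Study design being modelled

Two breeds (wild ancestor RJF, domesticated WL), two families per breed,
two generations. Parents are assayed individually (8 arrays); offspring are
assayed as pools of six same-sex birds, two pools per family (8 arrays).
Expression is a log2 gene × sample matrix; methylation is a two-colour
MeDIP tiling array with probes every ~100 bp across a window from 7.25 kb
upstream to 3.25 kb downstream of each TSS (105 probes of 50 bp per
promoter). Selective sweeps are fixed 40 kb intervals supplied as input on
a "covered genome" (975 Mb by default) — they are an input to enrichment
testing, never an inference target here.

## Moderated t and FDR

Each two-group contrast is tested per feature with an empirical-Bayes
moderated t. Pooled residual variances s²_g with d = n₁+n₂−2 df are shrunk
toward a prior (d₀, s₀²) estimated by moment matching on z_g = log s²_g:
with e_g = z_g − ψ(d/2) + log(d/2), the excess of var(e) over ψ′(d/2)
identifies d₀ through ψ′(d₀/2), and s₀² follows from mean(e). The
moderated statistic uses s̃² = (d₀s₀² + d·s²)/(d₀+d) on d₀+d df, two-sided.

Degenerate regimes: with fewer than two features carrying a positive
residual variance the prior is unestimable and d₀ = 0 (classical pooled t);
when the spread of log-variances does not exceed its sampling expectation,
d₀ = ∞ (complete shrinkage, s̃² ≡ s₀²); when the log-variances are exactly
constant the common s² itself is taken as s₀² (the moment correction
assumes sampling spread that is absent). Zero residual variance with a
non-zero contrast yields t = ±∞, p = 0.

BH adjustment is the standard step-up, implemented directly and verified
in the tests against an O(n²) tail-minimum oracle and statsmodels.

FDR is controlled separately within each analysis (generation × data kind),
matching how such designs report their counts. Promoter significance uses
the best probe's probe-level adjusted p with no additional per-promoter
correction; this mirrors the probe-wise procedure but is anti-conservative
at the promoter level, and is documented as such. The best probe is the
minimal raw p, ties broken by larger |log2FC| then smaller start
coordinate. Sign convention throughout: positive log2FC = higher in the
domesticated breed, so "+" DM means hypermethylated in WL.

Family contrasts are fit as within-breed two-group comparisons, not as
interaction terms of a multi-factor model — with two families of two
samples per breed there is nothing to gain from the larger model.

## Tiling-array preprocessing

Within arrays, M values are centred by a one-step Tukey biweight (start at
the median, weights (1−u²)² with u = (x−med)/(c·MAD+ε), c = 5, ε = 1e-4 as
a floor for constant data). One step, not iterated: the estimator is then
exactly shift-equivariant, hence idempotent, and rank-preserving. Between
arrays, A values are quantile-normalized to the mean of sorted A vectors
with rank-average tie handling; M values pass through bit-identically.
M and A are taken as given (log-ratio and average log-intensity of the
enriched and reference channels); background correction is out of scope.

## Stability statistics

*Top-K concordance*: both generations ranked by |log2FC| descending (ties
by smaller raw p), top-1000 sets intersected, Pearson r on signed log2FC of
the intersection. Ranking by absolute fold change keeps both tails; K = ∞
degrades to the plain cross-generation fold-change correlation. Fewer than
3 shared features flags the result degenerate instead of reporting r.

*Family correlation*: for each parental array, the mean Pearson correlation
of its full feature vector with own-family offspring pools minus the mean
against other families' pools, then a paired one-sample t across the 8
parents (df = 7, SEM = sd/√8). Raw coefficients are averaged (no Fisher z)
since the quantity reported is a raw mean difference. Comparison pools are
restricted to the same breed by default (`between_scope="breed"`), so breed
effects do not masquerade as family inheritance; `"all"` is available.

*Overlap fraction*: |A∩B|/|A| with A the parent-significant set.

*Direction bias*: 1-df goodness-of-fit χ² of the hyper/hypo split against
50:50, upper-tail p, no continuity correction (the uncorrected statistic is
the one conventionally reported for this comparison: 115/30 of 145 gives
χ² = 49.8).

## Sweep-proximity permutation test

A gene counts as proximal when the end-to-start gap to the nearest
same-chromosome sweep is ≤ w (50 kb default; overlap = distance 0; the
boundary is inclusive). The null redraws each gene interval with its own
length, uniformly over all covered positions that admit it wholly (regions
weighted by admissible starts; random intervals may overlap each other),
1000 sets by default, and reports the add-one estimate
p = (1+#{null ≥ obs})/(n_sets+1), which can never be zero. Proximity
testing uses merged sweep±w zones with binary search, so the 500-dataset
calibration runs in seconds; placements are drawn in order of interval
length, making the result exactly invariant to query input order and
chromosome relabeling at a fixed seed. Queries without coordinates should
be dropped by the caller (the pipeline logs such counts).

## MS-HRM quantification

Curves are normalized between linear baselines fitted in a pre-melt and a
post-melt window (defaults: first and last 1.5 °C of the grid — HRM
instruments typically show flat plateaus of at least this width), scaled to
0–100 and clipped. T_md is the grid temperature maximizing the absolute
difference between the normalized fully-methylated and unmethylated
controls, ties to the lowest temperature, degenerate (identical controls)
flagged. Group comparison is a Welch two-sample t on per-sample normalized
intensities at T_md — unequal variances are the safe default at 6–8 samples
per group. Percent methylation interpolates piecewise-linearly between the
calibration mixtures (0/25/50/75/100 %), requiring strict monotonicity of
intensity in fraction, clipping and flagging out-of-range samples.
Technical replicates (triplicates in the usual assay) are averaged into one
curve per sample before analysis.

## Synthetic-data generator

One top-level seed is split into fixed named substreams (truth, genome,
expression, methylation, melt), so adding genes never perturbs sweep
placement and identical configs are byte-identical.

*Expression*: value = baseline_g + de_effect_g·I(domestic) +
family_effect_{g,f} + noise. Baselines ~ N(8, 1.5); `n_de_genes` (default
300 of 2000) carry breed effects ~ N(0, breed_effect_sd = 1); family
effects ~ N(0, family_effect_sd = 0.3) for every gene; residual noise
sd = 0.5 (log2 units), divided by √6 for offspring pools — pooling is
modelled as averaging six independent residuals on one array, which
preserves the variance-reduction structure though a physical pool also
averages biological variation before hybridisation. The within-pool
variance of six-bird pools is not known from data; the √6 scaling is an
assumption. `heritability` scales the breed and family effects of
offspring arrays linearly (1 = fully transmitted, 0 = none) — a single
interpretable knob, not a genetic model.

*Methylation*: per tiled promoter, 105 probes at 100 bp spacing across
[−7250, +3250) around the TSS. `n_dm_promoters` (default 30 of 400 tiled,
mirroring study-scale DM sparsity) carry an effect of magnitude
breed_effect_sd·U(0.75, 1.5) and direction +1 with probability
`frac_hyper_in_domestic` (default 0.79), applied over a contiguous probe
sub-window of uniform length 3–20 probes — differential methylation is
local, not promoter-wide. Family effects act on the same sub-window, for
the same reason. Per-array M offsets (sd 0.2) emulate dye/enrichment bias
and are exactly removed by the within-array centring; A values get probe
baselines ~ N(10, 1) plus array effects, giving the between-array
normalization real work. Promoter windows that would spill over a
chromosome end are relocated inward and the count logged.

*Genome*: sweeps are `sweep_length` (40 kb) intervals placed non-overlapping
by rejection over the genome (975 Mb across 5 chromosomes by default, 149
sweeps). Gene intervals are the promoter windows. A truly affected gene
lands inside the merged sweep±50 kb zones with probability
min(1, enrichment_factor·p₀), where p₀ is the uniform-placement
probability — enrichment_factor = 1 therefore reduces exactly to uniform
placement, which is what the type-I calibration uses. No heterozygosity
statistics are simulated.

*Melting curves*: F(T) = f·S(T; Tm_meth) + (1−f)·S(T; Tm_unmeth) + noise,
S a decreasing logistic; default grid 70–90 °C in 0.05 °C steps (401
points), Tm 78/82 °C, width 0.5 °C. The pipeline draws per-bird methylated
fractions around breed means (0.25 wild / 0.70 domestic, sd 0.05).

What passing tests on this generator do **not** show about real data: no
probe-sequence or GC effects, no spatial array artifacts, no SNPs
disturbing probe hybridisation or melting, no bisulfite-conversion
inefficiency, Gaussian residuals with a single shared sd, and gene
placement independent of genome annotation structure. Results on synthetic
data demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-world violations.

## Problem sizes used in checks

The calibration and recovery experiments run at deliberately compact
scales chosen to keep the whole battery within a few minutes on one CPU
while leaving Monte-Carlo error well below the margins tested: 500 null
genomes of 200 genes (permutation type-I), 100 genomes of 135 genes at
five-fold enrichment (power), 100 + 30 expression datasets of 2000 genes
(heritability recovery at h = 1 and h = 0), one methylation dataset of
1000 promoters with 200 DM (bias recovery), and a 400-gene end-to-end
pipeline run executed twice for byte-identical determinism.

The bias-recovery experiment sets family_effect_sd = 0: with only two
families per breed, family effects create genuine incidental breed-level
methylation differences whose directions are symmetric, attenuating the
estimated hyper fraction toward 0.5 — a property of the sampled design
rather than of the estimator, so the calibration isolates the parameter
under test. Family effects are exercised separately by the
family-correlation tests.

## Known limitations

- Promoter-level significance inherits probe-level FDR (anti-conservative).
- The family correlation test treats pools as single samples; pool-size
  heterogeneity is not propagated into the paired t.
- The permutation null conditions on the observed interval lengths but not
  on chromosome assignment or local gene density.
- The moderated-t model assumes independent features; correlated probes
  within a promoter violate this at the probe level (the promoter
  reduction mitigates but does not remove it).
- HRM quantification assumes two-state melting and a monotone calibration;
  heteroduplex plateaus and multi-domain amplicons are out of scope.
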