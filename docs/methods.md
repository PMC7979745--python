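# Methods

This note records the models, parameter choices, numerical conventions,
and known limitations of `crescreen`. Everything stated here is computed
by the test suite or `scripts/acceptance.py`; nothing is quoted from
external data.

## Synthetic study design

The generators in `crescreen.simulate` define the study conditions the
package is validated under. One `SimConfig.seed` fans out to independent
per-generator streams (`default_rng([stream_id, seed])`), so adding draws
to one generator never shifts another and every output is byte-reproducible.

**Mini-genome.** `make_genome` packs `n_regions` non-overlapping
`region_length` bp target regions (default 400 bp, the conventional DNase
hypersensitive-site window) into a random ACGT background, requiring at
least 2× slack. PAM-rich regions are tiled with NGG triplets whose N is
drawn from {A, T, G}: a GG dinucleotide occurs at least every 3 bp, so a
protospacer candidate exists at ≥ 1 position per 3 bp while guide GC stays
mostly inside the [0.20, 0.80] efficiency band (N = C is excluded
precisely to keep GC below the ceiling).

**Screen counts.** Day-0 counts are NB(depth · a_g, α) with lognormal
abundances a_g (σ = 0.5, mean 1) mimicking library skew; the default depth
of 500 reads per guide stands in for the several-hundred-cell per-guide
representation of pooled screens, and the default dispersion α = 0.05 is a
mid-range value for replicate screens. Both are placeholders — the real
library's skew and dispersion are not published — and both are config
fields. Day-16 expected counts are scaled by 2^effect for guides whose cut
site lies in a planted region; the affected guides and their true log2FCs
are emitted as a sidecar truth table (never encoded in sequence names).
Variance is NB (Var = μ + αμ²; α = 0 degenerates to Poisson). Read-level
FASTQ simulation (sequencing error, PCR jackpotting) is out of scope:
counts are emitted directly.

**Signal tracks.** Per-region values are 10 + 2·(ρ·z + √(1−ρ²)·ε) with
standardized essentiality z, written as three bedGraph intervals per
region (half-height shoulders flanking the peak) so maximum-extraction is
exercised non-trivially. The linear construction keeps the Pearson
correlation of per-region maxima with z at ρ up to sampling error; ρ = ±1
is exactly noiseless.

**Cohort.** Genotype ~ Binomial(2, maf = 0.3); methylation is a 50:50
Beta(2, 8) / Beta(8, 2) mixture — bimodal like a variably methylated CTCF
site, without claiming the real shape; latent focal expression is
β_geno · G · 1[meth > τ] + ε with τ = 0.5 (the trough between the mixture
modes, so the truth threshold and the median split approximately agree).
The residual SD is 0.5: with n ≈ 64 per stratum and Var(G) = 0.42 this
puts the power of the high-stratum test at β = 0.4 near 0.95, i.e. the
planted effect is designed to be detectable at cohort scale rather than
marginal. One neighbor gene is mixed as r·z_focal + √(1−r²)·η (r = 0.7)
in the high stratum only. Latent values pass through the inverse Box-Cox
(λ = −0.1, clipped so 1 + λy > 0) to strictly positive, right-skewed
stored expression; the analysis-side forward transform restores the
latent scale exactly.

## Guide design

Coordinates are 0-based half-open everywhere internally; BED native on
disk; 1-based only in human-readable reports. Cut sites follow the Cas9
blunt cut 3 bp 5′ of the PAM (between protospacer positions 17/18); the
stored coordinate is the base PAM-proximal to the cut, symmetric across
strands.

Efficiency is rule-based and documented rather than a learned score: GC
fraction in [0.20, 0.80], no TTTT run (Pol III terminator), no
homopolymer > 5, protospacer length 20 (19 allowed). Specificity is exact
(0-mismatch) occurrence counting of protospacer+NGG on both strands of
the whole genome — the same contract as 0-mismatch short-read alignment —
and a guide passes only with exactly one genome-wide site.
Mismatch-tolerant off-target scores (CFD/MIT) are deliberately out of
scope.

Declustering places anchors at the centers of consecutive `spacing`-bp
bins (default 20 bp → floor(length/spacing) anchors) and solves a
minimum-total-|cut − anchor| assignment (Hungarian algorithm), which is
deterministic and invariant to candidate input order; ties break toward
the smaller coordinate, then the lexicographically smaller protospacer.
When splitting long elements into 400 bp windows, a trailing remainder
< 200 bp is merged into the previous window, ≥ 200 bp stands alone —
the convention is logged per region since no standard exists. Duplicate
protospacers across regions are emitted once, flagged ambiguous, and
excluded from window statistics by default. Oligos are the exact
concatenation flank5 + protospacer + flank3 with the conventional U6
scaffold homology arms as defaults.

## Screen scoring

Size factors are median-of-ratios (guides with any zero excluded from the
geometric-mean reference). The guide test treats normalized counts as NB
with a single pooled dispersion α̂ obtained by regressing (s² − m) on m²
through the origin across guides and timepoints with ≥ 2 replicates,
clamped at 0; with one replicate per arm it warns and falls back to
Poisson. The Wald statistic is log2FC (pseudocount 0.5, symmetric,
avoids log 0) over its delta-method SE; one-sided depletion p is half the
two-sided p on the depleted side. Measured type-I error at nominal 0.05
is ≈ 0.054 over 20 seeds × 2000 guides.

A note on normalization invariance: multiplying one sample's raw counts
by c rescales *all* median-of-ratios-normalized counts by c^(1/S) (the
per-guide geometric-mean reference absorbs c^(1/S)), so the Poisson term
of the variance, and hence p values, move slightly (< 0.02 here; log2FCs
move only through the pseudocount). Exact p invariance is impossible
under this size-factor definition; the tests assert the near-invariance.

Windows start at region_start + 50k, span 100 bp wholly inside the region
(no overhang), and need ≥ 2 member guides (assignment by cut site — the
CRISPRi effect centers there — configurable). The α-RRA gate (guides with
one-sided p < 0.25 count toward the order statistic) follows standard
α-RRA practice; the gate is applied on the percentile scale so observed
and permuted windows are scored by one function. Window p values come
from re-drawing m guides from the library percentile pool: exhaustive
enumeration when C(N, m) ≤ 10⁶, otherwise seeded Monte Carlo (default
10,000 draws; the pipeline and tests use smaller draws, 200–2000, which
only affects the resolution of p_window, not the RRA-based ranking).
Region essentiality is the best (min-p) window, sibling 400 bp splits of
one parent element are merged to the single most essential window, and
regions without a qualifying window get p = 1 and a flag. Ranking by
guide one-sided p (rather than a fold-change score) before aggregation is
a convention choice; it is recorded here because the alternative is
equally defensible.

## Cross-screen comparison

The outlier test refers each externally studentized residual to t(n−3)
with Bonferroni multiplier n and flags adjusted p < 0.1; it is equivalent
to the t-statistic of a per-point mean-shift dummy regressor (asserted to
1e-8) and affine-invariant. The reported regression removes flagged
outliers once and refits (flag-remove-refit, one iteration).

Empirical Brown's method transforms each condition's score vector to
w = −2 log(right-tail ECDF), calibrates f = 2(2k)²/Var(Σw) and
c = Var/(2·2k) from the empirical covariance, and evaluates
P(χ²_f > −2Σlog p / c); f is capped at 2k (independence ⇒ Fisher), k = 1
passes through, and duplicated rows collapse to the single p in the
analytic limit. Because the quantity the combined p should aggregate is
genuinely ambiguous in cross-screen settings, the function takes any
aligned (p-vector, data-matrix) pair and the caller decides what is
combined.

"Essential" for locus enrichment is an explicit threshold object
(default p_region < 0.05) recorded in the output, not a hidden constant;
the χ² is Pearson, 1 df, no continuity correction, with a Fisher-exact
fallback flagged when an expected cell drops below 1.

## Epigenomic association

bedGraph is the canonical signal dialect (text, diffable, desk-scale);
uncovered bases contribute 0, matching coverage-track semantics. The
rank-based inverse normal transform uses Φ⁻¹((r−½)/n) with average ranks
for ties. The representative SNP odds ratio searches the element ± 100 bp
(a 400 bp core → 600 bp window; the flank is configurable since the
window definition is conventional). "Top" regions are reported both per
screen and as the cross-screen intersection. PWM scores are min–max
normalized per matrix ((S − S_min)/(S_max − S_min)), scanned on both
strands with hits reported in forward-strand coordinates; threshold 1.0
returns exactly the consensus windows. The methylation–binding Spearman
test enumerates all pairings exactly for n ≤ 10 and uses the asymptotic
approximation otherwise.

## Stratified eQTL

λ is a fixed input (−0.1 default), never re-estimated. Median ties go to
the low stratum (deterministic; recorded). Genotype is coded additively
(0/1/2 risk alleles). No covariates enter the regression by default; the
model is OLS per stratum plus a pooled genotype × stratum interaction.
Monomorphic strata return NA with a reason rather than a degenerate fit.
Co-expression is Pearson on the Box-Cox scale per stratum.

## Problem sizes

Defaults used by the test suite and acceptance script: 20-region / 20 kb
genomes (~400 guides), 2000-guide calibration libraries, 20 seeds for
screen-level rates, 100 seeds for cohort-level rates, 500 replicates for
null calibrations, 200–2000 window permutations. These sizes keep every
check re-runnable on a single CPU in minutes while leaving the measured
rates' sampling error well inside the asserted bands.

## What passing does and does not show

The generators plant clean, additive effects with NB count noise,
piecewise-constant signal, and Gaussian latent expression. Passing
recovery tests therefore demonstrates that the estimators are correct and
calibrated under their own model assumptions — not that they are robust
to copy-number artifacts, MOI effects, UMI-less PCR duplicates, guide
efficiency heterogeneity, population structure in the cohort, or
confounded methylation–expression coupling, none of which are modeled.
Reproducing any published screen's specific numbers additionally requires
the deposited count/cohort data, which this package does not ship.
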