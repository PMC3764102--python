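# Methods

This note documents the statistical models, the numerical choices and the
synthetic-data assumptions behind `rootplast`, and what the test suite does
and does not establish about real data.

## Trait derivation and clustering

Seven traits are derived per seedling: primary root length PR (cm), lateral
root count LR#, lateral root density LR#/PR (cm⁻¹), the branching-zone
fraction L_B/PR (L_B is the parent-root span from the shoot base to the
most rootward emerged lateral root, so L_B/PR ∈ [0, 1]), total lateral root
length LRtot (cm), total root length PR+LRtot (cm) and mean lateral root
length LRlengthave (cm). LRlengthave is undefined (missing) for seedlings
with no lateral roots; LRdensity and L_B/PR are undefined when PR = 0.
Records with lateral roots on a zero-length primary root, or with
L_B > PR, are rejected as inconsistent.

Trait columns are scaled to [0, 1] as (x − low)/(high − low) with the
anchors taken from the column itself; response (δ highN−lowN) matrices are
scaled with their own anchors rather than those of the underlying
environment tables. Missing values are set to 0 on the scaled scale before
clustering — a conservative convention that keeps every accession in the
tree. Constant columns are emitted as all-zero with a warning.

Accessions (and later, genes) are clustered by average linkage on the
1 − Pearson distance. Rows with zero variance have undefined correlations
and are assigned distance 1 to every other row (0 to exact duplicates),
with a warning. The tree is cut at the cluster count k ∈ {2, …,
min(15, n−1)} that maximises the mean silhouette width, ties resolved
toward smaller k; silhouette widths are computed on the same precomputed
distances. PCA centres the already-scaled columns without re-standardising
and reports percent variance over all retained components (they sum to
100).

## Mixed ANOVA and heritability

The genotype-by-environment ANOVA is the balanced two-way mixed model with
environment fixed and genotype random. Under the random-genotype
expected-mean-square convention the environment and genotype mean squares
are tested against the interaction mean square and the interaction against
the residual. Unbalanced or incomplete designs are rejected rather than
approximated.

Heritabilities are variance-component ratios estimated by REML.
Within-environment: Phenotype = Accession(random) + Error, H² =
σ²_G/(σ²_G + σ²_E). Plasticity: Phenotype = Accession + NitrogenLevel
(fixed) + Accession×NitrogenLevel + Error, H² = σ²_GxE/σ_P². For balanced
designs with interior optima the REML equations have the closed-form ANOVA
(method-of-moments) solution, which is used directly; unbalanced one-way
data are fit by maximising the restricted likelihood expressed through the
group means and pooled within-group sum of squares, and unbalanced two-way
data through `statsmodels` MixedLM with a variance component per
environment within accession. Negative component estimates are truncated
at zero before the ratio is formed, and H² is clipped to [0, 1]; a
zero-variance dataset returns H² = 0.

## Mixed-model association scan

Per SNP the model is y = Xβ + u + ε with cov(u) = σ²_g K and X = [1, g].
K is the identity-by-state allele-sharing fraction over SNPs non-missing
in both accessions (unit diagonal, entries in [0, 1]; for complete 0/1
data it is a Gram matrix and hence positive semidefinite). The variance
ratio δ = σ²_e/σ²_g is profiled on the nonzero spectrum of S K S (S the
fixed-effect projection): a 100-point grid on log₁₀ δ ∈ [−5, 5] brackets
the REML optimum, which is then solved to high precision from the analytic
gradient by Brent's method. The SNP coefficient is Wald-tested on n − q
degrees of freedom; with K = I the construction collapses exactly to the
OLS F-test, which the tests verify to 1e-6 relative error. Accessions with
missing calls are dropped per SNP (complete case). Re-estimating δ per
marker is the default; a shared null-model δ (EMMAX-style approximation)
is available via `per_snp_reml=False`. Per-SNP R² is the one-way ANOVA
model sum of squares over the total.

Tests remain slightly anti-conservative under very strong structure (the
Wald test ignores variance-component uncertainty); measured empirical size
on two-subpopulation nulls is ≈ 0.05–0.09 at α = 0.05 versus ≈ 0.14–0.38
for the structure-naive scan.

q-values follow the Storey procedure: π̂₀ from the smoother over λ ∈
{0, 0.05, …, 0.90} (cubic polynomial evaluated at max λ, clipped to
(0, 1]; π̂₀ = 1 when m < 100), q_(i) = min over p_(j) ≥ p_(i) of
π̂₀·m·p_(j)/j. With π₀ forced to 1 this is exactly Benjamini–Hochberg.
q-values are computed separately per trait.

Windows span [pos − 10 kb, pos + 10 kb] clipped at 1; a gene belongs to a
window iff its 1-based inclusive interval overlaps it at all,
strand-agnostic. The recorded signed distance is 0 for a SNP inside the
gene, positive when the gene lies downstream (right) of the SNP and
negative when upstream. Windows merge into groups by transitive closure of
interval overlap per chromosome (by default across traits, pooling their
labels; a per-trait mode is available).

The power simulation treats the empirical phenotypes as random deviates:
x = round(MAF·n) accessions receive an additive effect of (multiplier ×
phenotypic SD), the mixed-model test runs against the real K, and power is
the rejection fraction at α = 0.05. The same random assignments are reused
across effect multipliers within a MAF, which reduces Monte-Carlo noise in
the monotonicity comparison.

## Probe-element outlier masking and summarisation

Expression arrays designed against a reference genotype measure each gene
with ≤ 11 probe elements whose affinities are fixed, so the within-probe-
set rank order of element signals should be reproducible across arrays;
sequence variants in another accession weaken individual elements and
depress their ranks. Elements are ranked ascending within each probe set
on each array (average ranks on ties); the consensus is the per-element
median rank over the reference accession's arrays. The detection statistic
for a (probe set, element, accession) triple is the mean over the
accession's arrays of (consensus rank − observed rank), one-sided toward
rank decrease.

The statistic's null distribution cannot be read off per-array deviations:
deviations of one element are strongly correlated across arrays through
the probe set's tie geometry (nearly equal affinities flip consistently),
so an i.i.d. resampling null is badly anti-conservative while reference-
only split-half nulls are so conservative they destroy sensitivity. The
null used here is a permutation null that keeps the geometry: under no
sequence divergence the reference and tested arrays are exchangeable, so
they are pooled, randomly reassigned into "reference" and "tested" halves,
the consensus recomputed and the statistic re-evaluated, with draws pooled
across probe sets (stratified by element count). An element is flagged
when its statistic exceeds the (1 − α) permutation quantile, α = 0.01 by
default, per element. On planted-truth synthetic cubes this yields a
false-flag rate of ≈ 0.006 and sensitivity ≈ 0.9–0.95 against 60%
attenuation. Flags apply per accession (the analysis compares treatments
within accession); masking can be applied globally by expanding the mask.
An element already at the bottom of the within-probe-set ranking has no
rank headroom, so rank-based detection cannot register it in principle;
the generator's dict-form planting therefore samples elements with
affinity rank ≥ 4 of 11, and sensitivity statements refer to such
detectable plantings.

Summarisation is a one-step Tukey biweight (c = 5, ε = 1e-4) of the log2
element signals surviving the mask, exponentiated back to the signal
scale — the closest documented open equivalent of the classic robust
probe-set summariser. Probe sets left with fewer than 3 elements for an
accession are set missing for that accession. Per-array scale
normalisation equalises each array's median summary to a fixed target
(500); operating on the median of the log2 summaries makes the
normalisation exact under common rescaling of an array and insensitive to
the minority of genes with real effects, where a trimmed mean on the
natural scale leaks composition shifts into every gene's ANOVA. Note that
a one-step biweight already zero-weights grossly attenuated elements in a
minority of probe-set geometries (tightly packed affinities), so masking
improves the summary in most — not all — affected probe sets; the tests
assert a strict-majority improvement and a halving of mean error rather
than uniform dominance.

Probe flags: 1 = non-nuclear or no gene match (including probes missing
from the annotation), 2 = multi-gene match, 3 = several probe sets per
gene, 4 = mean summarised signal below the detection cutoff (default
100, a configurable calibration constant). Flags 1, 2 and 4 exclude a
probe from the analysis set.

## Expression ANOVA and classification

Gene signals are analysed on the log2 scale (variance stabilisation; the
synthetic generator's effects are log-additive, making the two-factor
model correctly specified there). Stage 1 fits the full accession ×
treatment model with interaction per gene and keeps genes whose overall
model F-test passes Benjamini–Hochberg at FDR 0.1. Stage 2 simplifies by
nested F-tests in a fixed order — interaction first, then treatment, then
accession, each family BH-corrected at 0.1 — and assigns the class from
the retained terms (interaction ⇒ N×Accession; treatment+accession ⇒
N,Accession; single terms ⇒ N-only / Accession-only; none ⇒ none). The
stage-1 and stage-2 families are corrected separately. Genes with missing
cells are skipped with a warning; an all-constant gene gets p = 1 and
class none. Balanced closed-form sums of squares are vectorised across
genes, so thousands of genes classify in milliseconds. Per-class response
clustering reuses the trait clustering machinery on per-treatment means,
log2-converted and row mean-centred.

## Network and candidate genes

Gene response profiles (per-accession mean log2 control − treated) are
clustered by average linkage on 1 − Pearson and the tree cut at distance
0.3 (correlation 0.7). The "major cluster" size threshold is re-derived
per dataset: each gene's profile is independently permuted across
accessions (destroying inter-gene correlation, preserving marginals), the
clustering repeated, and the threshold set to the smallest size whose
exceedance frequency among randomised maxima falls below 10%; at least 20
randomisations are required. Major-cluster centroids are correlated with
scaled trait responses across the shared accessions; |R| > 0.7 defines an
edge. The stringent set is the union of N×Accession genes and members of
clusters correlated with any LRlengthave variant (lowN, highN or δ).
Candidate genes are genes inside SNP groups associated with the target
trait, annotated with their ANOVA class and stringent membership and
sorted by stringent membership, then any-effect tier, then absolute SNP
distance.

## Synthetic data

`simulate_genotypes` draws ancestral allele frequencies uniform on
[0.1, 0.9] and subpopulation frequencies Beta-distributed around them with
variance F·p(1−p) (divergence F), inbred calls Bernoulli per accession —
the simplest structure generator that stresses kinship correction.
Positions accumulate random strides of 100–5000 bp over 5 chromosomes.

`simulate_root_traits` builds a latent growth factor u = accession +
environment + interaction + SNP effects with the specified variance
components (environment realised as a fixed ±√σ²_env offset; SNP effects
in units of the within-environment SD √(σ²_A + σ²_AxE + σ²_R), added to
high nitrogen only when flagged environment-specific). PR carries u
additively plus Gaussian replicate noise, so its variance decomposition
matches the specification exactly — variance-component recovery tests
target PR. Lateral root counts are Poisson and lengths gamma (shape 4)
with environment-dependent means modulated by u (defaults: 4 vs 8 roots
and 0.6 vs 1.0 cm mean length on low vs high N), giving the derived
ratio traits realistic coupling without an exact decomposition; the
branching zone is a Beta(5, 2) fraction of PR. With zero residual
variance every replicate-level draw collapses to its mean, making the
degenerate case exactly reproducible.

`simulate_expression_study` assigns the five effect classes by the given
proportions (default 60% none, 20% accession-only, 5% N-only, 5%
N,Accession, 10% N×Accession — a nitrogen-responsive minority, as in real
root profiles), with log2 cell means built from a N(9, 1) baseline,
N(0, effect²) accession offsets, ±effect common responses and N(0,
effect²) per-accession interaction responses (effect default 2.0 log2).
Element signals multiply the gene signal by a fixed log-normal affinity
(log2 SD 1.0 — probe affinities span orders of magnitude), a per-array
brightness factor (log2 SD 0.1), planted attenuation fractions, and
multiplicative noise (log2 SD 0.25, consistent with replicate r² > 0.9).
The truth record keeps classes, attenuated triples and the noise-free
log2 cube for oracle comparisons.

What the generators do not emulate: linkage disequilibrium beyond
subpopulation structure, selfing pedigrees, trait distributions with
heavy tails or measurement truncation, probe-sequence-level effects
(attenuation is specified directly, not derived from 25-mer mismatches),
spatial/batch structure in arrays, and correlated noise between genes.
Passing tests therefore establish the correctness and calibration of the
algorithms under the stated generative assumptions, not the field
performance of the study design.

## Problem sizes and reproducibility

Simulation sizes in tests and in `scripts/acceptance.py` follow the study
design where it is stated (96 accessions × 10 replicates; 7 accessions ×
2 treatments × 3 replicates with ≤ 11 elements) and are otherwise chosen
to keep Monte-Carlo error well below the tolerance being asserted (e.g.
2000 SNPs for null calibration, 500 reps per power cell, 1500–2000 genes
for detection/classification rates, 60–100 clustering randomisations).
Every stochastic routine takes an explicit integer seed; the CLI and
pipeline derive stage seeds from one top-level seed and log them, and
identical configuration reproduces byte-identical outputs.
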