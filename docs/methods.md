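# Methods

`mungpop` implements the statistical chain used to reconstruct the
cultivation-range history of a predominantly selfing crop (mungbean,
*Vigna radiata*, is the motivating system) from SNP panels, geography,
climate layers and common-garden trait data.  Every stage can be driven by
the built-in synthetic-data generator, whose outputs have analytically
known expectations, so the whole chain is verifiable without any external
download.  This note records the models, the estimators, the defaults and
the design decisions.

## Synthetic data: the ground-truth models

### Allele frequencies on an admixture graph

Population history is encoded as a rooted acyclic graph
(`graphs.AdmixtureGraph`).  The ancestral allele frequency at each site is
drawn uniformly from `root_freq` (default U(0.1, 0.9)).  A drift edge with
parameter `c` in [0, 1) draws the child frequency from a Beta distribution
with mean `p` and variance `c·p(1−p)` — the Balding–Nichols model.  An
admixture node takes the linear mix `α·p_A + (1−α)·p_B`.

The Beta parametrization gives closed forms used as test oracles:

* heterozygosity decays by `(1−c)` per edge, so
  `E[p(1−p)]` at a node is `h₀·∏(1−c)` along its root path;
* `E[f2(X, Y)]` is the sum of `c·E[p(1−p) at parent]` over the edges on
  the path joining X and Y (`expected_f2`), with `expected_f3` /
  `expected_f4` derived from it.

A coalescent simulator would be more realistic but has no such closed
forms; Balding–Nichols drift is what makes every f-statistic exactly
checkable.  Frequencies that drift to 0 or 1 are retained — such sites
are monomorphic in that population and exercise the invariant-site
handling of the diversity estimators.

### Genotypes: partial selfing and distance-decaying LD

Diploid genotypes are produced by thresholding latent Gaussian AR(1)
processes (`simulate.simulate_genotypes`):

* each allele copy is `1` when its latent value falls below `Φ⁻¹(p)`, so
  the marginal allele frequency is exactly `p`;
* the latent correlation between sites `d` bp apart is `exp(−d/L)`
  (exponential covariance is Markov along the chromosome, so sequential
  generation is exact).  `L` (`ld_decay_bp`, default 50 kb) may be set per
  population, which is how scenarios encode "older groups show faster LD
  decay";
* inbreeding: at each site the second copy duplicates the first with
  probability `f`, giving genotype frequencies
  `{p²+fpq, 2pq(1−f), q²+fpq}`.  Per-site (rather than genome-wide)
  identity-by-descent makes every individual's realized inbreeding
  essentially equal to `f`, which is what a long history of partial
  selfing produces.  The default `f = 0.84` matches the study system
  (a predominantly autogamous legume);
* missing calls are inserted uniformly at random (≤10%); downstream
  filters cap missingness at 10% anyway, so biased missingness structure
  would be immaterial.

Sites are spread uniformly over 11 chromosomes of 40 Mb.  What the
generator does **not** emulate: recombination-explicit genealogies,
selection, sequencing error, and SNP ascertainment.  Passing tests
therefore demonstrate correctness of the estimators under the stated
sampling models, not robustness to those real-data complications.

### Landscapes, occurrences, traits

Climate rasters are linear spatial gradients (units per km, east or north)
plus optional Gaussian noise.  East–west gradients are linear in
along-parallel arc distance (`R·cos φ·Δλ`), which is additive along a
parallel and makes constructed-gradient tests exact; all analysis-side
distances use the great-circle haversine (R = 6371.0088 km).  Occurrences
are sampled from raster cells with probability proportional to the group's
Gaussian climate-space density.

Trait tables follow a balanced accession × batch × treatment × replicate
design with independent draws for group deviations (`v_b`), accession
deviations (`v_fam`), a polygenic value `MVN(0, v_aw·K)` for a supplied
relationship matrix `K`, batch effects, fixed treatment/interaction
shifts, and residual noise.

## Estimators

### Filtering and pruning

`filter_sites` removes sites with more than two alleles or missingness
strictly above 10% (a site at exactly the cap is kept).  `ld_prune` is the
standard SNP-count sliding window (50 SNPs, step 5): within each window,
any pair with dosage-correlation r² > 0.5 loses its later-positioned
member.  r² uses mean-imputed dosages — the common genotype-correlation
convention; a haplotype-EM r² would need phase, which the data model does
not provide.

### π, dxy and FST with invariant sites

π and dxy are ratios of sums: mismatching allele pairs over compared
allele pairs, accumulated across all sites (invariant included) with
missing alleles excluded pairwise, then divided once per window.
Averaging per-site ratios instead would weight sites equally regardless
of how many calls they carry and is biased with missing data; the ratio
of sums is the estimator popularized by pixy.  Windows are half-open
`[start, start+10 kb)` anchored at position 1.  Note that under selfing
the within-individual allele pairs are slightly less heterozygous than
between-individual pairs; π therefore carries a small downward bias of
order `f/(2n−1)`, shared by all pairwise π estimators.

Hudson's FST is the default (numerator `(p₁−p₂)² − Var(p̂₁) − Var(p̂₂)`,
denominator `p₁q₂ + p₂q₁`, aggregated ratio-of-sums; negative per-site
numerators retained).  The sampling-variance terms are estimated from the
**dosage variance** `s²/(4N)` rather than the binomial `p̂q̂/(n−1)`: under
inbreeding the allele copies within an individual are correlated and the
binomial form understates `Var(p̂)` by a factor approaching `(1+f)`,
inflating FST and f-statistics; the dosage-variance form is unbiased for
any `f` and reduces to the binomial one in expectation for outbred data.
The Weir–Cockerham (1984) θ is available behind `estimator=` and is the
default for the per-SNP values feeding the QST comparison (the common
choice in QST–FST practice).  Both are exposed because the upstream
windowed-FST tooling does not pin one down.

### LD decay

r² is computed for all intra-chromosomal SNP pairs within `max_dist_bp`,
binned by distance, and smoothed by LOESS (span 0.3; a conventional
default).  Two summaries are reported:

* `half_decay_bp`: where the smoothed curve first falls halfway from its
  maximum to its asymptote — a generic, model-free summary;
* `decay_length`: the length-scale λ of `r²(d) = a·exp(−2d/λ) + floor`
  fitted to the binned means with the floor pinned at the independence
  level `1/(n−1)` and a refit excluding the near field (`d < 0.4λ`),
  where threshold correlations saturate.  This is the estimator of the
  generator's latent correlation length; pinning the floor stops a flat
  noise tail from inflating λ, and the near-field exclusion removes the
  saturation distortion of the copula transform.  Round-trip accuracy is
  about ±10% at 8000 sites, comfortably inside the ±25% the tests assert.

### f-statistics

Per-site contributions (complete-case within the involved populations,
requiring ≥2 called diploids each):

* `f2 = (p̂_A−p̂_B)² − Var(p̂_A) − Var(p̂_B)`
* `f3(C;A,B) = (p̂_C−p̂_A)(p̂_C−p̂_B) − Var(p̂_C)`
* `f4(A,B;C,D) = (p̂_A−p̂_B)(p̂_C−p̂_D)` (products of independent
  contrasts need no bias term)

with the inbreeding-robust `Var(p̂)` described above.  Standard errors are
delete-one block jackknives over contiguous 2 Mb blocks (anchored at
position 1 per chromosome, trailing partial blocks retained), weighted by
per-block site counts using the Busing pseudovalue formula.  `|Z| > 3` is
the conventional significance call; a significantly negative f3 flags the
target as admixed, and `admixture_f3_scan` runs all source pairs.

### Structure

Genotype PCA mean-imputes missing calls, centers sites and by default
scales them by `√(p(1−p))` (Patterson normalization); signs are fixed so
each axis's largest loading is positive.  The allele-sharing distance is
`mean(|dosage_i − dosage_j|)/2` over pairwise-complete sites.
Neighbor joining follows Saitou–Nei with deterministic smallest-pair tie
breaking; a negative branch length is clamped to zero and its deficit
moved to the sister edge, preserving path lengths.  Output trees are
rooted at the midpoint of the outgroup's pendant edge.

### Geography and isolation by distance

The Mantel statistic is the Pearson correlation of lower-triangle
distances; the null permutes one matrix's rows/columns jointly.  The
p-value uses the `(1 + exceedances)/(n_perm + 1)` convention (one-sided
positive by default — the IBD hypothesis is directional); for n ≤ 6 an
exhaustive mode enumerates all permutations and is exact.  Gradient
regressions are plain OLS of raster values on great-circle km from the
unweighted coordinate centroid of the reference group.  Because distances
from a centroid fold at zero, the reference group should be compact or an
explicit `origin` supplied; both all-points and explicit-origin modes are
exposed.

### Niche analyses

Variable decorrelation scans columns in input order and drops the
later-listed member of any pair with |r| > 0.8 — deterministic and
order-stable.  Climate-space MANOVA computes Wilks' Λ = det(E)/det(E+H)
with Rao's F approximation (cross-checked against statsmodels).
Suitability surfaces use a Gaussian envelope,
`exp(−½·Mahalanobis²(cell; group mean, ridge-regularized covariance))`,
normalized to sum to one.  This is a deliberately transparent niche model
chosen for determinism and testability, not a reimplementation of
presence-background machine-learning ENMs; the surface container accepts
externally produced grids so any ENM output can be dropped into the
overlap statistics.  Schoener's D = 1 − ½·Σ|p₁−p₂| is exact on the
normalized grids.  With the envelope model only the *ordering* of
overlaps between group pairs is meaningful; printed D values from other
niche models are not comparable.

### Quantitative genetics

The rank-based inverse normal transform uses the Blom offset
`Φ⁻¹((r−3/8)/(n+¼))` with average ranks for ties.  Per-sample inbreeding
is the method-of-moments excess homozygosity
`(O_hom − E_hom)/(N − E_hom)` over polymorphic sites, with unbiased
per-site expected homozygosity `1 − 2p̂q̂·n/(n−1)`.

The drought-trial ANOVA treats treatment and group as fixed and
accessions (nested in groups) and batches as random.  For the balanced
design, expected mean squares give the error strata: group is tested
against accession-within-group; treatment and treatment×group against
treatment×accession-within-group.  Unbalanced tables fall back to the
same formulas with mean cell counts and a warning.  Tukey HSD on
accession means is provided as a post-hoc.

Variance components for QST come from the balanced expected-mean-squares
(method-of-moments) solution of the all-random model
`value = group + accession(group) + batch + residual`, one treatment at a
time; negative solutions are truncated to zero and flagged.  MoM was
chosen over REML here because it is exactly checkable by hand algebra and
the synthetic designs are balanced.  The additive within-group variance
`V_AW` is the one place REML is used: a single-random-effect mixed model
with group (and batch, when present — a pragmatic guard against
confounding batch means into the polygenic term) as fixed effects and a
polygenic effect with covariance `V_AW·K`, fitted by profiling the total
variance over the heritability ratio on the spectral decomposition of
`Z K Zᵀ`.

QST follows the two selfed-progeny formulas

    QST(1) = V_B / (V_B + V_Fam)
    QST(2) = (1+f)·V_B / ((1+f)·V_B + 2·V_AW)

where equation 1 is appropriate when replicates are selfed progeny of
each accession and equation 2 corrects for incomplete selfing through the
inbreeding coefficient `f` (panel estimate by default, overridable — e.g.
to a published value such as 0.8425).  `qst_fst_compare` places each
trait × treatment QST against the mean, 95th and 99th percentiles of the
per-SNP FST distribution computed from the phenotyped accessions only;
exceeding the upper tail is the divergent-selection flag.

## The pipeline scenarios and their diagnostics

`pipeline.run_pipeline` executes simulate → filter → diversity → f4 → IBD
→ niche from one seeded config and writes every artifact plus a
provenance sidecar (config hash, seed, version); identical configs give
byte-identical outputs.

The `east` scenario encodes a serial chain SA → SEA → (EA, CA) with 15%
gene flow from SEA into EA.  Drift parameters were chosen once so the
expected heterozygosity ratios across groups are about 1.0 : 0.7 : 0.5 :
0.3 (the qualitative π ordering of the motivating system); per-group LD
lengths increase from SA (20 kb) to CA (100 kb); the southern groups are
stepping-stone chains of demes along their transects (IBD present) while
the northern groups are recent stars (IBD absent), EA with westward-
increasing deme drift (serial-founder diversity gradient).  The CA and
western-EA transects overlap longitudinally, mirroring the documented
geography of the northern range — without this overlap the large
genetic and geographic separation of EA and CA would by itself produce a
spuriously strong pooled-north Mantel correlation.  The `radiation`
contrast scenario splits SEA, EA and CA independently from SA with equal
drift, no gene flow and star demes everywhere.

The report evaluates five diagnostics — π ordering, LD-decay ordering,
pooled-south vs pooled-north Mantel r, the f4 gene-flow test, and the
sign of the EA diversity gradient — and states each verdict strictly as
consistency with the serial-expansion pattern; it never asserts a
geographic history beyond those computed statistics.  Problem sizes
(8000 sites, 5 demes per group, 6 diploids per deme, 199 Mantel
permutations) are the package's chosen study conditions for these
qualitative diagnostics; the discriminating signals (π ratios, f4 ≈
α·c·h ≈ 0.006 with |Z| ≈ 5) are comfortably resolved at this scale and
each end-to-end run takes a few seconds.

## Numerical choices and degenerate inputs

* Mantel p can never be 0 (the +1 convention); exhaustive mode includes
  the identity permutation.
* `weighted_block_jackknife` requires ≥2 non-empty blocks; f-statistics
  with SE = 0 and a nonzero estimate are flagged degenerate rather than
  classified.
* Constant climate variables (undefined correlation) are dropped with a
  warning; singular within-group covariances raise.
* NJ on fewer than 3 taxa, PCA on zero-variance input, unreplicated
  variance-component designs, and sample pairs with no co-observed sites
  all raise `ValueError` with specific messages.
* All stochastic functions take explicit seeds; identical seeds give
  bit-identical outputs.

## Known limitations

* The drift model has no explicit time scale; branch parameters are in
  variance units, not generations, so divergence *times* are out of
  scope.
* The Gaussian-envelope niche model yields overlap orderings, not
  absolute suitability comparable to presence-background ENMs.
* π/dxy inherit the small `O(f/n)` within-individual bias under selfing
  common to pairwise estimators.
* The LD `decay_length` estimator assumes a single stationary
  exponential-like decay; mixtures of decay scales will be summarized by
  an intermediate value.
* Ancestry-coefficient matrices are consumed as input; the clustering
  that produces them is intentionally outside the package.
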