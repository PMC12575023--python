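# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would otherwise have to reverse-
engineer from the code.

## Study design and desk-side inputs

The trial feeds five diets (control plus kelp extract at 500–2000 mg/kg) to
crayfish in three cages per group and profiles six gut samples per group by
16S amplicon sequencing. The raw reads are not bundled; the desk-side
inputs are the published group summaries (mean ± SEM over three cage
replicates) for growth, hemolymph and hepatopancreas panels, and the diet
formulation table, frozen in `micronet.datasets`. Every sequencing-derived
stage runs on synthetic communities with planted truth instead.

## Dose–response and phenotype statistics

Growth indices follow the standard crustacean definitions (WGR, SGR, FCR,
HSI, CF, SR). The dose optimum is the vertex −b1/(2·b2) of an OLS quadratic
per response; a vertex is valid only when the curvature matches the
objective (concave for growth maxima, convex for the FCR minimum) and falls
inside the dose range. The reported "optimal range" is the [min, max] of
valid vertices over {WGR, SGR, FCR}. The vertex is a ratio of estimated
coefficients, so it is consistent but not exactly unbiased: at cage-level
noise sd 1.0 on the WGR scale its mean over 500 replicates sits within 0.5%
of truth, and the bias grows roughly quadratically with noise.

ANOVA from summary statistics recovers each group's variance as n·sem² and
pools it into MSW; this reproduces raw-data F exactly in the balanced case
and lets the printed tables be re-analyzed. Tukey letters use the
insert-and-absorb compact letter display with 'a' assigned to the largest
mean, matching the tables' convention. Dunn's pairwise test uses the
tie-corrected pooled-rank variance with Bonferroni adjustment by default
(the multiplicity scheme is configurable; the trial does not state one).
Orthogonal polynomial contrasts are built by Gram–Schmidt on dose powers,
which reproduces the tabulated integer coefficients for five equally spaced
levels.

Only the lower endpoint of the published optimum range is treated as
reproducible: quadratic fits of the printed (2-decimal) group means give
1507.58 (WGR), 1525.00 (SGR) and 1635.19 (FCR) mg/kg. The published upper
endpoint (1614.26) cannot be obtained from the rounded means — it was
evidently computed on unrounded replicate data — so the FCR vertex from
printed means (≈1635) is reported as-is and no test targets 1614.26.

## Differential abundance

Counts are converted to log2 relative abundance with a pseudocount of half
the smallest nonzero relative abundance (scale-aware, no magic constant).
Each OTU gets a one-way group-means model; residual variances s² with d
degrees of freedom are shrunk toward a prior estimated by matching the
moments of log s² (digamma/trigamma inversion, Newton iteration for the
trigamma inverse). The moderated t carries d0 + d degrees of freedom; when
the observed spread of log s² does not exceed pure sampling noise, d0 = ∞
and all variances collapse to s0². Flags follow the trial's rule — raw
p < 0.05 and |log2FC| ≥ 1 versus control — with Benjamini–Hochberg
available but off by default. Whether the trial modelled counts or relative
abundance is unstated; log relative abundance was chosen and is the
documented contract.

The moderated model assumes exchangeable variances. On sparse amplicon data
this is violated in both tails: very rare OTUs have zero-inflated log
profiles whose variance the prior underestimates, which is the dominant
source of residual false positives in the recovery experiments (all
remaining false discoveries in the default recovery run are OTUs averaging
under ten reads).

## Co-occurrence networks

Spearman correlations are computed on tie-corrected ranks; constant OTUs
are flagged and zeroed. The similarity threshold is selected by random-
matrix theory: for each candidate cutoff the thresholded matrix's
eigenvalues are deduplicated (isolated-node mass points removed), unfolded
with a cubic smoothing spline of the cumulative spectral function, and the
nearest-neighbour spacings are tested against the exponential law with a
χ² goodness-of-fit on √n equal-probability bins. The chosen threshold is
the smallest cutoff with Poisson-consistent spacings (p > 0.05); dense
correlated noise rejects, sparse block structure passes. Modules come from
greedy (CNM) modularity maximization on the unsigned graph — edge signs
are kept as attributes and enter only the positive/negative edge
percentages, since no signed-modularity method is specified for the
original analysis. Average path distance is computed over connected pairs
only. The random null rewires the graph with ≥10·E double-edge swaps per
replicate (degree sequence preserved exactly), re-detects modules, and
reports mean ± sd with empirical-vs-null z-scores; 100 replicates by
default. Cross-network module matching uses one-sided Fisher exact tests
of membership overlap against the shared node universe; clusters are the
connected components of the p < α similarity graph.

The trial's cutoff of 0.93 is retained as the config default for data at
its scale; the desk-scale analyses in `analysis/` use lower cutoffs (0.55
pooled, 0.85 within six-sample groups) because a 0.93 Spearman threshold on
30 or 6 samples leaves almost no edges. The RMT scan is provided to justify
a cutoff for any particular matrix rather than to hard-code one.

## Assembly ecology

The Sloan neutral model predicts occupancy 1 − BetaCDF(d/N; Nm·p, Nm·(1−p))
with detection limit d = 1 read and N the mean sample depth (both the
standard conventions; the original analysis states neither). m is fitted by
bounded scalar least squares on occupancy; R² = 1 − SSE/SST may be negative
for strongly niche-structured communities, which is exactly the diagnostic
contrast used. A Wilson 95% band around the predicted occupancy partitions
OTUs into above/within/below. Count-based detection is slightly more
permissive than the continuous stationary law the estimator inverts, so
fitted m carries a modest upward bias on realized count tables (~25% at
depth 1000); the recovery experiments therefore evaluate the mean over
seeds, which stays within ±30% of truth.

Levins breadth is B = 1/Σq² over each OTU's own across-sample proportions.
The generalist/specialist null redistributes each OTU's total reads across
samples by a multinomial proportional to sample depths — preserving the
margins the statistic is sensitive to — and classifies observed B outside
the central 1−α null band. Classification is run per treatment group (six
samples), matching the study's presentation; with n = 6 the null bands are
coarse and the per-group calls should be read qualitatively.

## MicroMEs

Differential OTUs are clustered on 1 − Spearman distance (average linkage,
configurable module count — the original modularization method and module
count are not stated, so both are parameters, with network-module reuse
available as an alternative). A MicroME is the first left singular vector
of the per-OTU z-scored samples × OTUs submatrix, scaled to zero mean and
unit variance, sign-oriented so mean kME ≥ 0; variance explained is
λ1/Σλ. Phenotype variables are clustered on 1 − |Spearman| (sign-blind) and
labelled by dominant category (growth1, growth2, …). Associations are
Spearman r/p for all MicroME × phenotype-module pairs plus dose, and a
Mantel test (Spearman statistic, Euclidean distances of eigenvector
profiles, 999 seeded permutations, one-sided). Biomarkers are module
members with kME r > 0.4, p < 0.05 and a significant Kruskal–Wallis test
across groups, mirroring the published thresholds.

## Synthetic generators: what they emulate, and what not

`simulate_otu_table` draws a log-normal base profile (σ = 1.5, reproducing
the long-tailed, sparse structure of real amplicon tables), plants
alternating-sign log2 effects on differential OTUs in all treated groups,
injects unit-variance Gaussian module factors (loading 0.85) on the log
scale before compositional closure, and realizes counts as multinomial
draws at Poisson-distributed depths (default mean 20,000). Three choices
deserve explanation:

* **Planting band.** Differential and module OTUs are drawn from the
  50th–85th abundance percentile. Below the band, planted signals fall
  under the detection floor at the default depth (truth would be
  unrecoverable at any analysis setting); above it, a single 4-fold shift
  of a dominant taxon moves the compositional denominator enough to push
  every null OTU past the fold-change threshold. The band keeps planted
  truth recoverable while leaving the closure distortion (~0.1 log2)
  realistic but sub-threshold.
* **Group-centered module factors.** Ordinary module factors are centered
  within each treatment group, so planted modules co-vary across samples
  but are, by construction, not differential; dose-linked modules
  (`dose_linked_modules`) are the explicit mechanism for
  treatment-associated modules. Without centering, a module's random
  group-mean excursions masquerade as differential signal and the
  planted-truth bookkeeping becomes ill-defined.
* **Sampling noise.** Default realization is multinomial; a Dirichlet
  concentration parameter (`dispersion`) is available for taxon-level
  overdispersion. Under strong overdispersion the raw-p/fold-change rule
  necessarily admits many false discoveries (the significance boundary
  rises to meet the fold-change cutoff), so the default keeps sampling-
  dominated noise; recovery experiments under heavy overdispersion should
  expect degraded FDR, as they would on real data.

The generators do not emulate chimeras, primer or copy-number artifacts,
taxon-specific dispersion, phylogenetic correlation, or longitudinal
structure — passing recovery tests therefore certify the estimators'
statistical machinery on an idealized table, not performance on raw reads.

`simulate_neutral_community` draws per-taxon proportions from the Sloan
stationary beta, renormalizes, and realizes a multinomial at fixed depth.
`simulate_niche_community` places taxa on a 1-D environmental gradient with
Gaussian responses sharpened by `filter_strength` (0 reduces to uniform
expectations). `simulate_phenotypes` produces cage-level quadratic dose
responses with Gaussian noise.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng(seed)`; every
permutation engine (PERMANOVA/ANOSIM/MRPP, Mantel, niche nulls, network
rewiring) takes an explicit seed and is bit-reproducible. Permutation
p-values use the add-one estimator (1 + hits)/(1 + n_perm), whose floor at
total separation is exactly 1/(n_perm + 1). PCoA reports negative
eigenvalues but excludes them from the variance denominator (the convention
behind quoted axis percentages). Quadratic fits declare "no optimum" when
|b2| < 1e-12. JSON reports embed the seed, the config echo and a config
hash; identical seed + config gives byte-identical files; non-finite values
serialize as null with a warning.

Problem sizes in the analysis drivers and tests are desk-scale by design —
30 samples × 300 OTUs (about an eighth of the trial's 2552 OTUs), 100–999
permutations, 100 random networks — chosen so the full pipeline and its
recovery experiments run in seconds while exercising every code path; the
full-scale settings are plain parameters.

## Known limitations

* The moderated model's exchangeable-variance assumption degrades on very
  rare OTUs (see above); a prevalence filter of 2 samples is applied but
  does not remove the effect.
* The RMT scan needs ≥ ~20 distinct eigenvalues after deduplication;
  very sparse thresholded matrices fall back to the scan maximum with a
  warning flag.
* Sloan m̂ inherits the count-detection bias described above; comparisons
  of R² across scenarios are unaffected.
* Generalist/specialist calls at n = 6 samples per group are coarse.
* No phylogenetic distances (UniFrac, βNTI) — no tree is in scope.
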