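# Methods

This note documents the statistical procedures, their assumptions, the
parameters that matter, and the design choices made where the problem was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

All maps live on a `ParcelAtlas`: integer parcel ids, hemisphere, one of
seven canonical intrinsic networks (VN, SMN, DAN, VAN, LiN, FPN, DMN), a
3-D centroid, and a missing flag. The human frame this emulates is the
200-parcel Schaefer atlas with 11 parcels lacking expression data;
**missing parcels are excluded from every mean, correlation and null —
never imputed**. Expression matrices are re-standardised at load time to
z-scores per gene over the non-missing parcels (sample SD, ddof = 1), so
maps are comparable regardless of upstream scaling. Alignment is by
parcel id, never by row order.

## Gene-set stage

A literature record is one reported expression change (symbol, drug,
species, tissue, direction, time from dosing in hours, study id). The
acute filter keeps unique symbols with *any* record at `time ≤ 5 h`
(inclusive: the acute set's reported maximum sits exactly on the
boundary; an `inclusive=False` switch exists). Records without a time are
excluded and counted in the log. How to reduce a gene with several
reported times to one time is not standardised anywhere; this
implementation filters per record, so a gene passes if any of its
findings is acute. Symbol matching is exact after uppercasing — no
alias or ortholog resolution, by design: reproducibility over recall.
The "−/+" direction category is kept verbatim.

## Overlap testing

`hypergeom_upper_tail(k, n, K, N)` is `scipy.stats.hypergeom.sf(k-1)`,
identical to a one-tailed (greater) Fisher exact test on the 2×2 table.
Genes of either set missing from the background are trimmed with a
warning rather than raising, reproducing the common frame in which both
sets were pre-filtered to atlas-expressed genes. The odds ratio is the
sample odds ratio, reported descriptively; inference comes from the exact
tail. The test suite checks the tail against exact integer enumeration
for every table with N ≤ 25. BH adjustment wraps
`statsmodels.multipletests(method="fdr_bh")`.

## Colocalization nulls

The observed statistic is the mean Pearson r between the query genes'
maps and a target map. Each of `n_perm` (default 5,000) permutations
draws an equally sized gene set uniformly without replacement from the
matrix *excluding the query set* and records its mean r. The p-value
uses the literal counting rule `#{null ≥ observed}/n_perm`, which can
return exactly 0; a `smoothed` option computes `(1+#)/(1+n_perm)`.

Calibration caveat: the null draws come from a finite gene pool, so the
null mean carries a finite-population correction `(1 − m/G')` relative to
the observed mean's variance. With a query of ~50 genes against a
~15,000-gene atlas this is negligible (<1%); calibration simulations
should likewise keep the universe much larger than the set (the
acceptance checks use 20-gene sets in an 800-gene universe and observe
the nominal 5% rate within Monte-Carlo error).

Distribution comparisons across receptors use a pooled-variance Student
t-test (query r's vs one seeded same-size random draw's r's — how many
random correlations enter this contrast is ambiguous in the source
analyses, so group sizes are configurable) and a one-way fixed-effects
ANOVA with Tukey–Kramer post-hocs (`scipy.stats.tukey_hsd`); an FDR
post-hoc option exists.

## Signed co-expression communities

The gene × gene matrix is the Pearson correlation of regional expression
profiles over non-missing parcels. Binarized nodal degree counts edges
with **signed** r > 0.3 (not |r|; an `absolute` flag exists) and serves
description only — community detection runs on the full weighted signed
matrix.

Signed modularity with symmetric negative-weight treatment:

    Q = Q⁺/v⁺ − Q⁻/v⁻ ,
    Q± = Σ_ij [W±_ij − γ k±_i k±_j / v±] δ(c_i, c_j) ,

with resolution γ = 0.5 by default (coarser communities than γ = 1). The
asymmetric variant (negative term weighted v⁻/(v⁺+v⁻)) is available but
non-default.

The optimiser is Louvain with three specific choices, each forced by a
correctness argument:

- **The ± sub-networks are aggregated separately across levels.**
  Aggregating net weights and re-splitting by sign would let mixed-sign
  community pairs collapse to their net weight, silently changing v± and
  the degree sequences, and with them Q.
- **Iterated refinement.** After the multi-level pass converges, the pass
  is re-run seeded with the found partition (single-node moves on the
  original graph) until Q stops improving.
- **Restarts with randomised initial partitions.** Greedy moving from
  all-singletons can be structurally unable to reach optima that require
  coordinated multi-node moves; half the restarts therefore start from a
  random partition. The best-Q partition over `n_restarts` (default 100)
  seeded restarts is kept, ties broken by fewer communities, then
  lexicographically — making the result deterministic given
  `random_state`. On random signed graphs with n ≤ 8 the search matches
  exhaustive enumeration of all set partitions (asserted in the
  acceptance suite, 100 instances).

`SignedLouvain` is a scikit-learn-style clusterer (`fit(W)`, `labels_`,
`modularity_`, `get_params`); `louvain_signed` wraps it into a
`Partition` with 1-based community ids. Cluster maps are the member
genes' average maps, named Cluster 1..k by descending size.

## Global functional connectivity

Per subject: Pearson correlation of all parcel pairs over time, then per
parcel the mean correlation with all *other* parcels (self-correlations
excluded — including the unit diagonal would only shift/rescale, but
exclusion is the standard GFC definition). No Fisher-z before averaging
by default (`fisher_z=True` exists). Group difference = parcelwise
mean(group A) − mean(group B); in the synthetic study group A is the
drug condition. The difference map is masked to the parcels with
expression data before any map comparison, keeping one analysis frame
throughout. Preprocessing/denoising of the time-series is out of scope —
inputs are taken as preprocessed.

## Variogram-matched surrogate nulls

Smooth maps correlate by geometry alone, inflating naive permutation
tests. The surrogate generator randomises a map while preserving its
variogram:

1. permute the map's values across parcels;
2. smooth the permutation with a row-normalised Gaussian distance kernel
   at each of 5 candidate scales, log-spaced across the pairwise distance
   range;
3. per scale, fit amplitude α and nugget β by least squares so that
   `α·γ_smoothed(h) + β` matches the empirical variogram (variograms of
   independent components add), then form `√α·smoothed + √β·white noise`;
4. keep the best-fitting scale (a raw permutation competes as an implicit
   candidate; if it wins, the surrogate is flagged as a fallback);
5. rescale to the source map's mean and SD.

Numerical choices: variograms use 25 uniform bins truncated at the 75th
percentile of pairwise centroid distances (long lags are pair-poor and
irrelevant to local autocorrelation); distances are Euclidean between
centroids; the smoothing kernel uses the **full neighbourhood** by
default — truncating to a small k-nearest set (e.g. k = P/10)
demonstrably under-smooths and degrades the variogram fit at P ≈ 100–200
without saving any compute, since the kernel matrices are dense either
way (`knn` remains a parameter). Negative fitted α or β are clipped to
zero.

`surrogate_p` correlates a candidate map with each surrogate of the
target. The default tail is *directed*: one-sided in the direction of the
observed r (`#{sign(r_obs)·r_surr ≥ |r_obs|}/n`). This matches the
practice of reporting one-sided surrogate p-values for negative as well
as positive observed correlations, but note it is sign-selective: under a
symmetric null its rejection rate at nominal α is ≈ 2α, exactly like a
two-sided test run at level 2α. The literal "equal or higher" rule
(`tail="greater"`) is the calibrated one-sided test and is what the
calibration simulations use. With an ensemble of raw permutations
`surrogate_p` reduces exactly to the plain permutation test (asserted as
an equivalence oracle in the tests).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies
on, at the study's stated sizes where they exist:

- **Atlas**: centroids uniform on a sphere (radius 50, arbitrary units),
  hemispheres as the two x-caps, 7 contiguous network blocks per
  hemisphere; default study frame 200 parcels with 11 missing.
- **Expression**: each gene = its cluster's network-profile map +
  kernel-smoothed noise + white noise (both noise components at sd
  `noise_sd`, default 0.3), z-scored per gene. Default profiles are
  orthogonalised *as maps* over the non-missing parcels: planted clusters
  are spatially uncorrelated, so recovery failures indicate algorithmic
  faults, not accidental profile collinearity. Correlated planted
  profiles legitimately merge at γ = 0.5 — which is informative about γ,
  not about the optimiser. Background genes (no cluster structure) fill
  out the universe; the default universe is 600 genes, scaled down from
  ~15k since resampling statistics depend on the universe only through
  its (large) ratio to the set size.
- **Gene table**: 156 entries, 56 unique acute genes; acute times from a
  normal(1.5 h, 0.5 h) truncated to [0.75, 5] h with the two window
  boundaries planted explicitly, mirroring the reported acute range;
  non-acute entries have times > 5 h or no time. 51 of the acute genes
  are in the expression universe; the HAR-like list (50 genes) shares 9
  with the query set — about twice the chance expectation, emulating the
  published ~2× enrichment at the scaled-down sizes.
- **BOLD**: two groups of multivariate-normal time-series (default 15
  subjects, 220 timepoints). Group covariance for the drug group scales
  off-diagonal entries by √((1+e_i)(1+e_j)) for an effect map e
  (diagonal restored, eigenvalues floored at 1e-8 to stay PSD), so the
  planted GFC difference follows e. In the full study, e is proportional
  (amplitude −0.3) to Cluster 1's average map, planting a real
  map-to-connectivity coupling for exactly one cluster.

Not emulated: probe-level microarray noise, donor effects, abagen's
probe-selection/normalisation pipeline, fMRI acquisition artefacts,
geodesic cortical geometry, and any spatial covariance structure specific
to real transcriptomes — the Gaussian-kernel autocorrelation is a
stand-in, not a claim about the data. Passing tests therefore validate
the *statistical machinery* (calibration, recovery, exactness), not the
biology of any particular dataset.

## Pipeline & reproducibility

`RunConfig` holds every path and constant (acute window 5 h, n_perm
5,000, GCE threshold 0.3, γ 0.5, seed); no stage hard-codes a threshold.
A single top-level seed fans out to per-stage seeds via CRC32 of
"stage:seed" (all below 2³¹), so stages can be rerun in isolation.
`run_all` executes genes → maps → overlap → coloc → network → gfc →
nulls, writes every intermediate table and a `summary.json` with floats
rounded to 12 significant decimals; reruns with the same seed are
byte-identical (asserted in the acceptance suite).

Problem sizes in the test and acceptance suites (80–200 parcels, 99–199
permutations per replicate with 1,000 replicates for calibration, 100
exhaustive-search instances) were chosen as the smallest sizes at which
each property is statistically decisive: calibration bands are ±0.02
around the nominal 0.05 (Monte-Carlo SD ≈ 0.007 at 1,000 replicates),
and recovery margins (ARI 1.0, effect-recovery r ≈ 0.98 against a 0.8
bar) are wide.

## External interfaces

- Gene table CSV: `symbol,drug,species,tissue,direction,time_hours,study_id`
  (header required; missing = empty field). Gene lists: one symbol per
  line, `#` comments.
- Expression CSV: first column `parcel_id`, remaining columns gene
  symbols; absent or empty rows are missing parcels.
- Atlas CSV: `parcel_id,hemisphere,network,x,y,z,missing`.
- Regional maps: `parcel_id,value`. BOLD: one CSV per subject, rows =
  timepoints, header = parcel ids.
- CLI subcommands: `simulate`, `genes`, `overlap`, `coloc`, `network`,
  `gfc`, `nulls`, `run-all`; exit codes 2/3/4 distinguish config, data
  and numerical errors.

## Known limitations

- Louvain optimality is guaranteed only empirically (exhaustive checks at
  n ≤ 8; restarts at realistic sizes); signed modularity landscapes can
  in principle defeat any greedy search.
- The surrogate generator matches the variogram approximately (least
  squares over candidate scales), not exactly; its calibration was
  verified at the simulated smoothness levels, and very rough or very
  long-range autocorrelation may fit less well.
- The directed surrogate tail is sign-selective (see above); use
  `tail="greater"` when strict one-sided calibration matters.
- No ortholog mapping: cross-species gene symbols are matched textually.
- Subcortical structures are out of frame; all statistics are cortical.
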