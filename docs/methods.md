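# Methods

This note records the models, defaults and numerical choices behind
`menanet`, and what the synthetic generators do and do not emulate.

## Data model and rarefaction

An `OtuTable` is an integer count matrix (samples × OTUs) with optional
per-OTU taxonomy lineages; `EnvTable` is the aligned real matrix of
environmental variables. Counts stay integers; relative abundances are a
derived view. On disk the TSV convention is OTU rows × sample columns
(first column the OTU id, optional trailing `taxonomy` column); BIOM 1.0
JSON (sparse and dense) is read with the standard library's JSON parser
because no BIOM library is declared as a dependency.

Rarefaction subsamples each sample without replacement to a common depth
using the multivariate hypergeometric distribution, so per-sample totals
equal the depth exactly and the expected count of OTU *j* is
depth·c_j/total. Samples below the depth are **dropped** with a warning
rather than padded — padding would break the exact-depth postcondition that
downstream distance computations rely on. Default depth: 1500 reads, the
depth at which the package's demo study is standardised.

Taxonomy lineages are split on `;` with Greengenes/SILVA-style rank
prefixes (`p__` etc.) stripped on parse; OTUs lacking the requested rank
pool into `unclassified`, and aggregation conserves each sample's total
exactly.

## Diversity

Shannon–Wiener is computed in nats (H = −Σ p ln p, zeros contributing 0 in
the p ln p → 0 limit). Simpson is reported as **Gini–Simpson** 1 − Σp² by
default so that larger values mean higher diversity (the direction used
when communities are described as "more diverse"); the inverse form 1/Σp²
sits behind `kind="inverse"`. The default two-group comparison is Welch's
t (unequal variances are plausible between meadow types); Student's t and
Mann–Whitney are flags.

## Ordination

CA eigen-decomposes S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}; eigenvalues are
squared singular values, total inertia is ‖S‖²_F, and site/species scores
are principal coordinates satisfying the reciprocal-averaging relation
(checked in tests to 1e-6). Axis signs are fixed by requiring the
lexicographically smallest sample id to score non-negatively, which makes
plots reproducible.

DCA detrends axes 2+ against axis 1 by mean-centering within 26
equal-width segments (the method's canonical default). Nonlinear (Hill)
rescaling is simplified to per-axis standard-deviation units and is **off**
by default; rare-species downweighting is off. Axis-1 ordering is exactly
the CA ordering.

CCA standardises the environmental variables with row-mass weights, forms
the weighted least-squares projector onto their span, and splits S into a
fitted part (constrained axes) and a residual (unconstrained axes); the two
eigenvalue sets partition the total inertia to 1e-8. An empty constraint
set therefore degenerates exactly to CA. Near-collinear designs (condition
number of the weighted Gram matrix above 1e8) raise an error naming the
variables loading on the near-null space. Percent explained is reported
against **total** inertia per axis and cumulatively; the constrained share
is also exposed (`constrained_pct`) because "cumulative contribution of all
environmental factors" can mean either. Axis significance by permutation
of environment rows is available separately (`cca_permutation_test`) and is
never used for filtering.

## Permutation tests

Bray–Curtis (default, on rarefied counts), Jaccard (presence/absence) and
Euclidean distances feed ANOSIM, Adonis/PERMANOVA and MRPP. MRPP weights
groups by w_g = n_g/N (the most common of the published options) and
reports the chance-corrected agreement A = 1 − δ/E[δ] with the expectation
taken over the sampled permutations. Permutation labels are drawn
uniformly (distinctness not enforced), p-values use the add-one estimator
p = (1 + #{at-least-as-extreme}) / (1 + N) one-sided in the statistic's
structure direction, and every test takes an explicit seed. Mantel runs in
matrix mode (simultaneous row/column permutation) or vector mode (element
permutation); the connectivity–GS linkage uses vector mode by default, as
degree and GS are per-node vectors, with matrix mode available through
`mantel` directly. The permutation kernels are vectorised over the whole
permutation batch; correctness is pinned by naive per-permutation oracles,
exhaustive enumeration at n ≤ 7, and scikit-bio cross-checks in the tests.

## RMT network construction

1. **lg matrix** — OTUs present in fewer than half of the samples (default
   `min_prevalence_fraction = 0.5`) are dropped; remaining zeros are
   replaced by 0.01 before log10.
2. **Similarity** — s = |Pearson r| across samples, signs kept separately;
   constant OTUs are dropped with a warning.
3. **Threshold scan** — for each threshold on a grid (default 0.30–0.99,
   step 0.01), entries below the threshold are zeroed and the eigenvalues
   of the thresholded matrix are computed. Degenerate eigenvalues are
   deduplicated (they carry no spacing information), the spectrum is
   unfolded, and the NNSD is chi-square-tested against the Poisson density
   e^{−d} and the GOE Wigner surmise (π/2)d·e^{−πd²/4}. The chosen
   threshold is the smallest with Poisson p > 0.05. A threshold leaving
   fewer than 20 distinct eigenvalues yields a near-diagonal matrix with no
   level correlations by construction and is treated as already
   decorrelated (accepted); this keeps the scan well defined for small or
   very clean matrices, where the classical transition test has no sample
   to work with.
4. **Unfolding** — default `cdf_spline`: a monotone piecewise-cubic (PCHIP)
   interpolant through quantile knots of the empirical cumulative spectral
   function, with the knot count capped at n/10 so the interpolant smooths
   rather than reproduces the staircase (an interpolant through every
   eigenvalue would force all spacings to 1). A degree-5 polynomial fit is
   the alternative. Spacings are rescaled to exact unit mean.
5. **Chi-square** — bins are equal-probability under the reference density
   (so expected counts are uniform and no merging is needed); df = bins − 1.
   Calibration and power (Exp(1) vs Wigner at 500 spacings) are asserted in
   the acceptance tests.

Edges are unweighted after thresholding; the correlation sign and the
similarity value ride along as edge attributes, and isolated nodes are
removed. Average path distance is the mean shortest-path length over
connected pairs only (fragmented co-occurrence graphs have no finite global
diameter); clustering is the mean local coefficient with 0 for degree < 2;
connectivity is the mean degree 2E/N.

**Module detection** is deterministic and seed-free:
Clauset–Newman–Moore greedy agglomeration followed by local refinement —
sweeps of single-node moves (to a neighbouring community or a fresh
singleton) plus a community-dissolution move that reassigns every member of
a community to its best alternative and keeps the change only if modularity
rises. The dissolution move escapes the pairwise local optima that plain
agglomeration and single-node sweeps both get stuck in; on all small graphs
in the test suite the refined partition reaches at least 95% of the
exhaustive-search optimum.

**Node roles** use the Guimerà–Amaral conventions: Zi is the z-score of the
within-module degree against the node's module (0 when the module's spread
is 0), Pi = 1 − Σ_m (k_m/k)²; cutoffs Zi ≥ 2.5 (module hub) and Pi ≥ 0.62
(connector), both exceeded → network hub.

**Gene significance** GS[i, v] is the squared Pearson correlation between a
node's log-abundance profile and an environmental variable, hence in
[0, 1] with null expectation 1/(n − 1).

Exports: edge list TSV, GraphML (for Cytoscape), node-role TSV, a network
statistics table, the threshold-scan trace, and per-variable
connectivity–GS tables.

## Synthetic data

`simulate_community` draws counts Dirichlet-multinomially per sample around
group-level mean compositions: the Dirichlet concentration (default 200)
controls overdispersion while the multinomial draw keeps depth exact. The
default design is 2 groups × 9 sites × 3 subplots (54 samples) at depth
1500, with 11 phyla whose four dominant members (Proteobacteria,
Acidobacteria, Actinobacteria, Bacteroidetes) sum to 0.81/0.79 of the two
group profiles — the "four phyla ≈ 80%" regime typical of temperate
grassland soils. `group_effect` scales *all* between-group differences
(log-linear interpolation of the phylum profiles plus OTU-level log-normal
perturbations with sd 0.3), so `group_effect = 0` makes the groups
exchangeable; that null is used to verify that every permutation test is
calibrated. Site/subplot structure is encoded in the sample ids but no
random site effect is added by default, keeping the null exchangeable.

Correlated blocks are multivariate normal in log10-abundance space
(compound-symmetric ρ within a block, or the AR(1) band ρ^|i−j| with the
`decay` flag) exponentiated and rounded to counts around 10² so the planted
correlations survive the downstream log10 transform. The RG-like/NG-like
presets use decaying bands (3 × 25 OTUs at ρ = 0.985 vs 0.90 plus 30 noise
OTUs over 80 samples): the slowly decaying band thresholds to a wide, dense
band (high degree, short paths) and the fast-decaying band to a narrow one
(low degree, long paths), reproducing the denser-network/shorter-path
contrast direction; pure compound-symmetric cliques would tie at path
length 1.

Environment linkage builds a driver variable as Σ r_i z_i plus Gaussian
noise with variance scaled so that, at `noise_sd = 1`, the population
correlation with each (near-independent) driver equals its target |r|;
`noise_sd → 0` makes the linkage deterministic (GS → 1). Non-driver
variables are group means plus noise at magnitudes realistic for meadow
topsoil chemistry (pH ≈ 6.3/7.3, SM ≈ 38/26, …).

`simulate_fastq` writes Phred+33 reads with iid bases at a target GC
fraction and iid qualities from a user profile over Phred 0–41; it exists
only to exercise the QC metrics.

What the generators do **not** emulate: phylogenetic correlation between
taxa, spatial autocorrelation between sites, compositional closure effects
beyond the multinomial, read-level errors, or chimeras. Passing tests
therefore demonstrate correctness of the computations and calibration of
the statistics under these models, not robustness to every artefact of real
amplicon data.

## Problem sizes and determinism

The test suite and acceptance script run on deliberately compact problems —
communities of 40–300 OTUs, networks of ≤ 150 nodes, 500-replicate
calibrations at 999 permutations, 10-seed recovery sweeps — chosen so the
statistical assertions (3–4 SE bands, 8/10 or 9/10 seed criteria) are
meaningful while the whole battery stays fast. Every stochastic routine
takes an explicit seed; the pipeline propagates one global seed, fixes
matplotlib's SVG hash salt, and checksums every artifact, so a rerun with
the same config and seed is byte-identical.

## Known limitations

- The QC module computes metrics from given FASTQ and tag counts; the
  raw→clean→effective tag derivation (merging, filtering) is upstream and
  intentionally out of scope.
- MRPP's A uses the sampled-permutation expectation of δ, so A (not its
  p-value) varies slightly with the permutation seed.
- DCA implements detrending-by-segments with simplified rescaling; exact
  Hill-rescaling segment surgery is not reproduced.
- The threshold scan assumes the similarity matrix is dominated by either
  noise correlations or block structure; adversarial spectra with heavy
  degeneracy between those regimes fall back to the sparsity acceptance
  rule described above.
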