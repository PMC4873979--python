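# Methods

## Scope and model

`biofilmflow` analyses stain-free flow-cytometry measurements of microbial
biofilm communities. Each event (a cell or particle) is a 12-vector of
signal-area intensities: forward scatter FS (size proxy), sideward scatter
SS (granularity proxy) and ten autofluorescence channels named by emission
wavelength (FL425–FL755 nm). The workflow is:

1. **Acquisition gating.** Every event at or above the digitizer's
   saturation limit in *any* of the 12 channels is removed. "At or above"
   because a digitizer clips at the limit value, so the limit itself marks
   clipping. The filter is idempotent.
2. **arcsinh transform.** `y = asinh(x / c)` with cofactor `c = 150`
   (configurable). Near zero the transform is linear (keeping dim debris
   and non-fluorescent particles resolvable); at high intensity it is
   logarithmic. All analysis geometry (embedding, projection, kNN graphs)
   lives in this space.
3. **Equal-size pooling.** Cross-sample comparison requires one shared map,
   so equal per-sample subsamples (without replacement, seeded) are pooled,
   hard-capped at 150,000 events — beyond that, t-SNE's crowding collapses
   distant structure. Exceeding the cap is an error, never silent
   truncation.
4. **viSNE embedding.** 2-D Barnes-Hut t-SNE (perplexity 30, 1,000
   iterations by default; both exposed). The original viSNE tooling does
   not publish its hyperparameters, so these are ordinary t-SNE defaults.
   Engines:
   - `bh`: scikit-learn Barnes-Hut t-SNE on all pooled events (PCA
     initialization, fixed seed, deterministic);
   - `landmark`: Barnes-Hut t-SNE on a seeded uniform subsample of at most
     `max_landmarks` (default 5,000) events; every remaining event is
     placed at the coordinates of its Euclidean-nearest landmark in 12-D.
     This keeps 150,000-event pools at desk runtimes and preserves
     cluster-level geometry, at the cost of within-cluster texture (many
     points share a landmark's coordinates);
   - `auto`: `bh` up to `max_landmarks`, `landmark` beyond.
   Map coordinates are engine-dependent and carry no units; every
   downstream analysis is defined so that it depends only on cluster-level
   structure, not on specific coordinates.
5. **Projection.** Held-out events (reference species, bleached controls,
   new samples) are drawn at the map coordinates of their Euclidean-nearest
   source event in 12-D arcsinh space — no interpolation, ties broken by
   lowest source index for reproducibility.
6. **Subpopulations.** Expert cluster categorization is stored as closed
   polygon gates in map coordinates (boundary counts as inside; gates may
   not overlap beyond 0.1% of either area). `auto_gates` reconstructs such
   gates from labeled points as the convex hull of each label's central
   95% (by radius around the label's map medoid), leaving the small
   uncategorized fringe manual gating also leaves. Quantification counts
   events per gate per sample; rows of the fraction table sum to 1.
7. **Map similarity (MMD).** The maximum mean discrepancy between two point
   sets, using a Gaussian RBF kernel with the median-pairwise-distance
   bandwidth computed on the union of both inputs. We report the square
   root of the biased V-statistic estimate, clamping negative radicands to
   zero. Inputs larger than 3,000 points are subsampled (seeded, with the
   per-input seed derived from the input's content so the statistic is
   exactly symmetric in its arguments). MMD is used descriptively (within-
   vs between-group means), not as a formal test.
8. **Rare clusters.** Small detached map clusters are the candidate rare
   populations (the microplastic use case). Clusters are eps-connected
   components of the map; a component is reported when it has at least
   `min_points = 20` members and at most `max_fraction = 2%` of all
   points. The connectivity radius defaults to twice the 99th percentile of
   nearest-neighbour distances among unique map positions: visually
   contiguous regions stay connected (99% of points reach a neighbour well
   within eps) while anything an expert would call detached — separated by
   several within-cluster spacings — stays separate. All three knobs are
   exposed; `min_points`/`max_fraction` are engineering defaults, not
   field-calibrated values. Sort gates for a detected cluster are central
   order-statistic intervals per channel (default coverage 99%, guaranteed
   to contain at least the requested fraction of cluster events), returned
   in raw intensity units; sorter wavelength aliases (448/576/620/695/722
   nm) map onto the analyzer panel.
9. **Detection-limit scan.** For decreasing total pooled sizes, the full
   chain (equal subsample → embed → detect) is repeated over several seeds;
   detection is declared only when some small cluster consists of ≥ 80%
   spiked events. The summary is the smallest size detected under every
   seed.
10. **Statistics.**
    - Subpopulation tables are Hellinger-transformed (`sqrt(share)` per
      row) before ordination; environmental variables are natural-log
      transformed except pH (already a log quantity — and redundancy
      analysis is invariant to the log base, an affine column rescaling).
    - Redundancy analysis: centre Y and X, regress Y on X, eigen-decompose
      the fitted values (constrained axes) and residuals (unconstrained).
      The headline number is the constrained share of total variance.
    - Significance by free row permutation of Y:
      `p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)`, 999 permutations by
      default (minimum attainable p = 0.001). Axis tests compare each
      constrained eigenvalue against its permutation distribution
      (simultaneous, not sequential); term tests are marginal (each
      variable given all others). Technical replicates should be averaged
      before RDA; the permutation scheme is unblocked.
    - Model selection: forward, backward and marginal (single-term
      screening — our operational reading of "marginal") permutation
      selection at p ≤ 0.05 with 199 permutations per step; variables
      chosen by at least two procedures survive; then the highest-VIF
      variable is dropped iteratively while any VIF > 10. An audit table
      records every vote.
    - Vector fitting projects *raw* environmental variables onto the first
      two constrained axes (least-squares direction, r², permutation p).
    - Group comparisons: one-way ANOVA per subpopulation, Tukey HSD
      pairwise, Holm step-down across each subpopulation's pairwise family
      (the family boundary is our choice). Degenerate all-equal inputs
      return F = 0, p = 1 rather than NaN.
11. **Graph clustering (comparison method).** Union-symmetrized Euclidean
    kNN graph (k = 45) in arcsinh space, modularity-maximizing (Leiden)
    partitioning run 50 times with distinct sub-seeds, best modularity
    kept. Edges are unweighted by default; Jaccard neighbourhood weighting
    is an option and is required in practice for isolating clusters smaller
    than k (a rare population of ~50 events among thousands cannot hold a
    plain-kNN community together, since most of its edges leave the
    cluster). Partitions are compared to gate labels by adjusted Rand index
    plus a per-cluster majority map.

## Synthetic data generator

There is no bundled instrument data; every analysis is exercised on a
generator that emulates the statistical structure of stream-biofilm
samples. Events are multivariate Gaussians in arcsinh space (the analysis
geometry), mapped to raw intensities by `sinh(y)·150` and clamped to the
acquisition range `[0, 2^20 − 1]`. The phenotype library is a structural
stand-in — locations are free parameters chosen for clear class geometry,
*not* calibrated to any deposited dataset:

- green algae / diatoms: strong red (chlorophyll) fluorescence, correlated
  (rho 0.97) 510/542, 575/620 and 725/755 loadings so the panel carries the
  redundant emission pairs real panels show;
- cyanobacteria: phycocyanin-range 620/660 fluorescence;
- decay series: red-channel locations decrease strictly with stage (the
  optical correlate of chlorophyll decay), other channels untouched;
- sediment: high SS, lowest fluorescence everywhere (non-organic);
- microplastic: moderate-to-high FS, very low red, elevated 448/575/620 —
  a polystyrene-bead-like signature, kept >3 sigma below saturation so
  spiked events survive acquisition gating.

Mixtures are multinomial with per-sample fraction jitter; spiking replaces
`round(f·n)` random events and records the indices. Site series renormalize
`base + z(env)·effects + noise` per site, returning the true fraction table
for parameter-recovery tests. The driver-recovery design uses 18 sites and
10 candidate variables (flow, DOC, Ca as true drivers — effect 0.05 per SD
of the variable, five times the site noise SD of 0.01 — plus seven
independent physico-chemical distractors and pH).

Not emulated: optics and electronics (pulse shapes, spillover,
compensation), doublets, acquisition-time drift, taxonomic richness beyond
the phenotype library, or any correspondence to a real instrument's channel
calibration. Passing tests therefore demonstrate the *pipeline's*
correctness and power under controlled structure, not instrument-level
realism.

## Problem sizes and numerical choices

Tests and the acceptance analysis run at desk scale by design: the
detection-limit scan uses six 25,000-event samples scanned at pooled sizes
120,000/60,000/30,000 with the landmark engine (5,000 landmarks);
driver-recovery runs use 5,000 events per site so that multinomial noise is
small against the designed site noise; the subsampling-robustness check
uses ten independent 5,000-per-sample subsamples projected onto one fixed
map. Determinism: every stochastic step takes an explicit seed; pipeline
stage seeds are derived from one master seed via a keyed hash, so stages
can re-run independently. Floating-point care: MMD radicands are clamped at
zero and argument order is canonicalized for exact symmetry;
nearest-neighbour ties resolve to the lowest index; Hellinger rejects
all-zero rows; rank-deficient constraint matrices are rejected with a
pointer to VIF screening.

## Known limitations

- The landmark engine assigns duplicated coordinates to non-landmark
  events; analyses needing within-cluster texture should use the `bh`
  engine at smaller pool sizes.
- Axis permutation tests are simultaneous rather than vegan's sequential
  conditioning; for the leading axis they coincide.
- Rare-cluster detection below `min_points` spiked events in the pool is
  impossible by construction; the scan reports this as non-detection.
- FCS support is list-mode float FCS 3.0/3.1 read plus a minimal fixture
  writer; integer-type and compensated files are out of scope.
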