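# Methods

## Targeted MWAS model

A targeted MWAS treats one metabolite's abundance profile as the outcome
and screens every LC/MS feature for linear association with it. The anchor
profile may be a feature of the same table (an *internal* MWAS) or an
external assay vector supplied as a virtual feature (a cross-platform
MWAS). For feature *i* and anchor *y*:

- Intensities are log10-transformed by default before Pearson correlation.
  LC/MS ion intensities are approximately log-normal and heavy-tailed, and
  reference tables in this field report log intensities; zeros and
  negatives become missing under the transform. The transform can be
  disabled (`log_transform=False`), and Spearman rank correlation is
  available as a robust alternative (`method="spearman"`, the default for
  networks).
- Missing data are handled by pairwise-complete deletion. A feature must
  retain at least `min_pairs` (default 10) complete pairs with the anchor;
  otherwise its coefficient is reported as undefined and it is excluded
  from multiple-testing adjustment, reducing m accordingly.
- The two-sided p-value uses t = r·sqrt(n−2)/sqrt(1−r²) on n−2 degrees of
  freedom; the same t approximation is applied to Spearman's rho, which is
  standard at the sample sizes involved (n = 50 by default). |r| = 1 maps
  to p = 0 by convention.
- FDR control is Benjamini–Hochberg step-up, performed per target (each
  anchor is analyzed as its own family), with undefined p-values excluded.

### Self-exclusion

When the anchor is a feature of the table, the scan would otherwise be
dominated by the anchor itself and its other ionic forms. The
self-exclusion window removes every feature within the ppm tolerance
(default 10 ppm) of the anchor mass or of any registered
adduct/isotopologue form of it. The registry treats the observed anchor
as [M+H]⁺ and enumerates [M+Na]⁺, [M+2Na−H]⁺, water loss, and one- and
two-¹³C isotopologues of each form, using exact monoisotopic shifts
(proton 1.0072765, Na-for-H 21.9819442, H₂O 18.0105646, ¹³C−¹²C
1.0033548 Th). The charge is assumed to be 1, which is the dominant state
for small-molecule electrospray data; multiply charged forms are out of
scope.

## Mass-domain operations

- ppm error is signed: 1e6·(observed − reference)/reference.
- Adduct transforms are exact arithmetic on the registry shifts:
  mz − Δ(from) + Δ(to); the operation is exactly invertible.
- Query-to-table matching accepts all features within the ppm window and,
  when the query carries a retention time, within an RT window (default
  30 s — narrow enough to separate an early-eluting amine from the
  late-eluting lipid region, which in the reference chromatography begins
  around 350 s).
- Cross-study overlap uses greedy one-to-one pairing by smallest |ppm|,
  optionally gated by RT. Greedy nearest-first pairing is symmetric
  and deterministic; counts always partition both lists.
- QC filtering retains features with median within-replicate-group CV
  strictly below 50%, pooled technical-replicate Pearson correlation
  strictly above 0.7, and strictly less than 30% missing cells. The
  replicate-correlation criterion pools all within-group replicate pairs
  across samples; when no group has two replicates, or the pooled values
  are constant, the criterion is skipped and flagged rather than failed.

## Association networks

Networks grow breadth-first from seed metabolites to at most depth 2.
In each expansion wave, every frontier node is correlated against all
not-yet-recruited features; p-values are BH-adjusted **within the wave**
over the tests actually performed (a pooled adjustment across waves is
available via `pooled_adjust=True`). An edge is accepted when
|r| > r_min and q < q_max. A recruitment cap (default 500 nodes) converts
an over-permissive threshold into an explicit error rather than an
attempt to invert a table-sized matrix.

### Partial correlations

Partial mode recruits nodes exactly as full mode does, then re-estimates
all pairwise coefficients on the recruited node set:

1. complete-case data over the set (optional half-minimum imputation for
   missing/zero cells, off by default);
2. Schäfer–Strimmer shrinkage toward the identity target,
   λ\* = Σ_{i≠j} Vâr(r_ij) / Σ_{i≠j} r_ij², clipped to [0,1], with
   r\*_ij = (1−λ)r_ij — this guarantees a positive-definite, invertible
   matrix (λ = 1 when all off-diagonals are exactly zero);
3. P_ij = −Ω_ij/√(Ω_ii Ω_jj) with Ω = (R\*)⁻¹ (pseudoinverse fallback for
   the unshrunk singular case).

Edge p-values in partial mode use the same t transform with
df = n − k (k recruited nodes), BH-adjusted over all recruited pairs,
and edges are re-thresholded on the partial coefficients. Partial
correlations are deliberately computed on the recruited subgraph, not the
full table: a seed-centered network asks which of the recruited
associations are direct, and inverting a 40,000² matrix is neither
feasible nor meaningful for that question.

### Stringency sweep

The sweep reports one network per threshold in an increasing list
(default 0.3/0.5/0.7). The lowest threshold is built by full BFS; each
higher-stringency network keeps only edges whose |r| exceeds that
threshold and prunes nodes no longer reachable from a seed within the
depth limit, recomputing node depths on the filtered graph. Deriving the
higher-stringency networks by filtration (rather than independent
rebuilds) makes the edge-nestedness guarantee exact: independent rebuilds
could violate nestedness through changes in the per-wave BH family when
fewer nodes are recruited. A single-threshold sweep is identical to a
plain build.

### Cross-study pattern similarity

Given correlation matrices over the same matched feature set in two
studies, each feature's off-diagonal row in study A is Pearson-correlated
with its row in B (k−1 paired coefficients); the feature is selected when
p < α (default 0.05) and the coefficient is positive. The positivity
requirement makes this a test of *similar* patterns, roughly halving the
null selection rate relative to a two-sided test.

## Synthetic data generator

The generator emulates the statistical structure of a targeted-MWAS
study, not its chromatography or spectra:

- Log10 intensities are multivariate normal. Per-feature baselines are
  N(6, 1) (log10 arbitrary-intensity units, spanning the dynamic range a
  type-3 Manhattan plot displays); within-feature variation has sd 0.4.
  Correlations are realized on the log scale, consistent with the MWAS
  default transform.
- A module of features correlated with the anchor at r_a has
  within-module correlation r_a² by default (a single-factor model:
  members are conditionally independent given the anchor); cross-module
  correlation is the product of anchor loadings. Requested blocks that
  are not positive definite raise an error naming the module.
- Companion ions copy a parent's intensity profile: scale 0.1 (an
  isotopologue or minor adduct is a fraction of the parent signal) with
  Gaussian noise at 5% of the scaled signal's sd, giving a parent–
  companion correlation near 0.99 — emulating the ¹²C/¹³C pair of a
  well-measured metabolite. The companion's m/z is the parent's plus the
  exact isotope/adduct shift.
- Missing values are inserted completely at random at a configurable
  rate (default 0).
- Default n_samples = 50 matches the cohort sizes the method was
  designed around.
- Randomly placed masses (modules and nulls) are rejection-sampled to
  stay more than 25 ppm away from the anchor's adduct/isotopologue
  forms, so the self-exclusion window removes exactly the planted
  self-features and nothing else.
- One integer seed drives a single `numpy.random.Generator`; identical
  configs give identical tables.

What the generator does **not** emulate: chromatographic peak shapes,
retention-time drift, batch effects, intensity-dependent missingness
(censoring at the detection limit), and correlated noise between
non-module features. Passing tests therefore demonstrate the statistical
operating characteristics of the pipeline under a clean factor model —
FDR control, power, parameter recovery — not robustness to instrument
artifacts.

The `choline_casestudy_fixture` packs these pieces into one table: an
anchor at m/z 104.1062 / 51 s with a ¹³C companion at +1.0033548 Th, an
8-feature late-eluting (>350 s) module at true r = 0.6 whose coordinates
reuse published phosphocholine-pathway ion masses as fixture coordinates,
and 500 nulls.

## Numerical choices and degenerate inputs

- Vectorized pairwise-complete Pearson accumulates masked sums; pairs
  with zero variance or fewer than `min_pairs` observations return NaN
  and are excluded from BH.
- Spearman over a whole table ranks each feature over its observed
  values once and then applies pairwise-complete Pearson to the ranks;
  with missing data this is an approximation to per-pair re-ranking
  (exact when data are complete), which is what makes a 40,000-feature
  scan tractable. The two-vector `correlate_profile` is exact.
- BH adjustment delegates to the standard step-up implementation and is
  verified against a brute-force step-up oracle in the tests.
- GML export writes integer node ids with label/mz/rt/is_seed/depth node
  attributes and weight/qvalue/depth edge attributes; booleans are
  encoded as 0/1 since GML has no boolean type.
- The JSON run manifest replaces a language-specific serialized workspace
  as the provenance record: it stores the tool version, all options,
  input file names with SHA-256 hashes, output names and the seed;
  equality of manifests is defined up to timestamps.
- Manhattan plots place the dashed significance line at −log10 of the
  largest raw p with q < α and omit it when nothing is significant; the
  y-axis is −log10(p) for all three types, the Manhattan-plot convention.
- Network layout is force-directed with a caller-supplied seed, so plot
  coordinates are reproducible.

## Problem sizes

The simulation-based tests use the design the screen is characterized
by: n = 50 samples, 1000 null features, 50 planted features, with 500
replicates for the false-discovery estimate and 200 for power/recovery;
these sizes give Monte-Carlo standard errors well under the margins being
tested and run in well under a minute each.

## Known limitations

- Single charge state; no isotope-pattern deconvolution; the adduct
  registry covers the positive-mode forms relevant to the shipped
  workflows and is extensible by editing `ADDUCTS`.
- No covariate adjustment (the screen is marginal correlation only).
- Per-wave BH for network edges is a pragmatic family definition; q
  values are not comparable across waves. The pooled alternative is
  provided.
- `pattern_similarity` assumes the two matrices are indexed by an
  already-matched feature set (use `overlap_features` first).
- Class labels stratify runs (one output per class); no between-class
  inference is performed.
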