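# Methods

## The model

The analysis treats the genome as the common object space of two
measurements: per-gene transcript abundance across arrays, and per-gene
predicted TF binding-site content across motifs. If a TF participates in
a treatment response, the expression of its target set should move
coherently with the treatment contrast, and that coherence should be
visible as shared structure between the two tables even when the TF's
own transcript does not change.

### Non-symmetric correspondence analysis

NSC decomposes the predictability of a frequency table's columns from
its row profiles. For a nonnegative table `F` (n × m, grand total N):

- row profiles `a_ij = f_ij / f_i·`, column masses `c_j = f_·j / N`,
- analysed table `Z_ij = m (a_ij − c_j)`,
- row weights `d_i = f_i· / N`, column metric `q_j = 1/m`,
- eigendecomposition via the SVD of `D^1/2 Z Q^1/2`; eigenvalues are
  squared singular values and sum to the total inertia
  `Σ_i d_i Σ_j q_j Z_ij²`.

The `×m` scaling of `Z` is retained so results can be validated against
the published NSC formulation; any consistent scaling would work, but
one must be fixed. Rows with zero sum are assigned the weighted mean
profile: they carry zero inertia but stay projectable. When one table's
ordination is re-expressed under another table's row weights (see
below), the centering `c` becomes the imposed-weight mean profile so
rows still average to zero under the active weights.

### Co-inertia coupling and supervision

Both tables are oriented with genes as rows — the only orientation in
which they share an object space. CIA requires a single row weighting;
the expression table is the measured dataset, so its NSC gene weights
govern and the motif ordination is recomputed under them. The coupled
axes come from the SVD of `Q_A^1/2 (Z_Aᵀ D Z_B) Q_B^1/2`; axis-k gene
scores from the two tables have weighted covariance σ_k, and the RV
coefficient divides `Σσ_k²` by the norms of the two separate
ordinations, giving 1 for a table coupled with itself and values near 0
for label-broken (row-permuted) pairs.

Supervision composes BGA with CIA by condensing the expression
ordination's array columns to q-weighted group-centroid columns before
coupling. Because NSC rows are centered, the weighted mean of the
centroid columns vanishes, so with g groups at most g − 1 coupled axes
are non-null; for the two-group contrasts used here, exactly one. This
composition — coupling against group centroids — is the largest single
interpretation fixed in this package: the supervision step is described
in the source methodology only as finding the discriminating combination
of ordination axes, and with two groups the centroid coupling yields
that unique discriminating co-inertia axis.

Motifs are ranked by *signed* loading on the surviving axis, oriented so
group 1's centroid loading is positive: each list has a group-1 pole and
a group-2 pole, matching the convention that motifs pointing in a sample
group's direction are associated with it. Ranking by absolute loading is
computable from the same output but is not the default. Ties break
lexicographically by motif id; axis signs elsewhere are fixed by making
each axis's dominant loading positive.

### Rank aggregation

Per-threshold rankings are merged by the rank product (geometric mean of
ranks, average-rank convention for ties); the permutation-based
significance component of the published rank-product method is omitted
because only the ordering is consumed downstream. The cross-comparison
consensus keeps motifs in the top `top_k` (default 10) of at least
`min_support` comparisons (default: all of them — strict unanimity);
both knobs are configurable since the original consensus rule is stated
only as consistent overlap. Reported mean ranks average over all
comparisons.

### Differential expression

Every contrast in the reference design is two-group, so the linear-model
machinery reduces to the two-sample special case: per gene,
`logFC = mean(group1) − mean(group2)` on log2 data, pooled variance
`s_g²` on `d_g = n1 + n2 − 2` df. The empirical-Bayes prior (d0, s0²) is
fitted by the method of moments on `log s²` with digamma/trigamma
corrections and a Newton-inverted trigamma, matching the standard eBayes
moments estimator (verified against the Bioconductor implementation to
ten significant digits on a frozen fixture); non-positive excess
variance yields d0 = ∞ with s0² the mean variance. The moderated t uses
the posterior variance on d0 + d_g df. Significance combines
`2^|logFC| ≥ 1.3` with BH-adjusted `p ≤ 0.05`, both boundaries
inclusive; the fold-change rule is applied two-sided since the source
states only a magnitude. The consensus gene list keeps genes significant
in the same direction in at least `min_support` comparisons (default
all); genes ever significant in both directions are excluded outright.

### Enrichment, qPCR, dose–response

Target overrepresentation uses the exact hypergeometric upper tail
`P(X ≥ a)` (one-tailed Fisher test) with the target set defined by
count > 0 at the chosen threshold table (default 0.8, the threshold used
for the projection figures); hit counts are not weighted. Raw p-values
drive the calls; a BH column is emitted for transparency only. The
background — genes with promoter information present on the platform —
is caller-supplied because it cannot be derived from the inputs.

Relative quantification averages replicate Cts within (cell line, gene,
condition) before forming ΔCt against the reference gene, with the
untreated control as calibrator and amplification efficiency fixed at 2
(`RQ = 2^−ΔΔCt`); per-replicate RQ spread is emitted alongside. The
±2-fold rule is `RQ ≥ 2` (up) or `RQ ≤ 0.5` (down). Survival is
`100 × (treated − blank)/(control − blank)` using A405 − A620 per well,
floored at 0. The IC50 comes from a least-squares 4PL fit
`y = lower + (upper − lower)/(1 + (x/ec50)^hill)` with lower ∈ [0, 49],
hill ∈ [0.05, 20] and the upper asymptote capped at the largest observed
response (survival is already normalized to untreated controls, so the
top plateau cannot meaningfully exceed what was measured; the cap also
keeps the absolute-50% crossing identified). The reported IC50 is the
concentration at 50 % absolute survival on the fitted curve, with
log-linear interpolation between the bracketing measurements as the
recorded fallback when the fit fails. The concordance statistic is the
Spearman correlation of per-line log2 RQ with IC50; the switch index is
the 1-based position of the single sign change along the
sensitivity-ordered lines, reported only when the sign sequence is
`(+…+−…−)` or `(−…−+…+)` with no zero entries.

## Synthetic data: what it emulates and what it does not

The generator reproduces the reference study conditions: a 96-array
design (two cell lines × {vehicle at 0/2/6/12/24 h, 0.1 µM drug at
2/6/12/24 h, 1 µM drug at 2/6/12 h} × 4 replicates), six two-group
comparisons whose group sizes are 8/40, 8/8, 16/32, 16/28, 8/40 and
8/36, four motif tables at PSSM thresholds 0.7/0.75/0.8/0.85, and six
phenotyped cell lines whose planted IC50s (0.036, 0.080, 0.193, 0.416,
6.08 and 7.46 µM) are the published sensitivities of the profiled
panel.

Defaults, with rationale:

| parameter | default | why |
| --- | --- | --- |
| n_genes × n_motifs | 2000 × 100 | large enough for moderation and enrichment asymptotics, seconds-scale per run |
| target_density | 0.10 | sparse incidence typical of promoter scans at a permissive cutoff |
| threshold_retention | 0.7 | binomial thinning per threshold step; cutoffs are nested by construction, so monotone thinning is the minimal faithful structure |
| n_driver_motifs / δ | 5 / 1.5 log2 units | a clear but not dominant planted effect |
| noise sd | 0.3 log2 units | replicate-level array noise |
| baseline | Normal(8, 1.5²) | log2 intensity scale of normalized arrays |
| Ct noise / replicates | 0.15 cycles / 3 | typical qPCR technical spread, triplicate assays |
| qPCR log2FC pattern | (3.0, 2.2, 1.4, 0.8, −1.2, −2.0) | graded with sensitivity, switching sign at the fifth line |
| dose grid / noise | 9 points at 0.01–100 × IC50 / 3 % | spans both plateaus; plate-reader noise |

Cell-line response profiles mirror the observed dose dependence: the
first line responds only to the high dose at 6/12 h, the second to both
doses at 6/12 h. Expression values are floored at 0.01 so the matrix
remains a valid nonnegative ordination input.

Not emulated: probe-level optical noise, cross-hybridization,
intensity-dependent (heteroscedastic) variance, correlated genes within
pathways, motif co-occurrence structure, or real promoter scanning.
Gaussian log2 noise matches the moderated-t model assumptions being
tested; passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure under the model's own
assumptions, not robustness to the full messiness of real arrays.

## Numerical choices

- Eigenvalues below 1e-12 × λ₁ count as null axes.
- NSC/CIA are deterministic; all randomness lives in the generators and
  is seeded (`numpy.random.default_rng` with per-stage child streams),
  so pipeline reruns are byte-identical.
- Quantile normalization assigns tied values the mean of the reference
  values at their tied positions; on tie-free data the transform is
  exactly idempotent and every column shares the reference multiset.
  With ties the averaging intentionally trades the exact-multiset
  property for determinism.
- Trigamma inversion by damped Newton iteration (50 iterations max,
  relative tolerance 1e-10), with asymptotic starting values at the
  extremes.
- Rank ties use the average-rank convention; all ranking tie-breaks are
  lexicographic for reproducibility.
- Degenerate inputs fail loudly: negative ordination input, all-zero
  tables, empty gene intersections, missing reference genes, survival
  never crossing 50 %, and all-tied IC50s raise typed errors that the
  CLI maps to exit codes 2 (config), 3 (data) and 4 (numerical).

## Probe handling

Gene identifiers are plain text keys. An optional many-to-one
probe-to-gene map collapses probes by maximum mean intensity —
deterministic and standard. Both probe-level and collapsed analyses are
supported because published gene counts can be stated at either level.

## Known limitations

- Only two-group supervision is implemented (every contrast in the
  reference design is two-group); multi-group BGA coupling and
  multi-factor linear models are out of scope.
- Monte-Carlo significance of the total co-inertia and rank-product
  p-values are not computed; orderings alone feed the consensus.
- The enrichment background must be supplied by the caller.
- IC50 fits report no confidence intervals; replicate-level spread is
  available only when replicate labels are provided.
- Test and acceptance problem sizes (2000 genes × 100 motifs × 96
  arrays; 20 replicate seeds for stochastic checks) are the package's
  chosen reference conditions; larger inputs run through the same code
  paths unchanged.
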