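# Methods

## Score-to-distance transform

Aligner similarity scores are unbounded above and a few extreme pairs would
otherwise dominate any least-squares embedding. The transform therefore
subtracts scores from a cap s_n chosen by nearest-rank percentile:
n = round_half_up(p/100 · (M+1)) clamped to [1, M], where M is the number of
scored pairs and p defaults to 99.95. The percentile is computed over
*observed* pairs only, each unordered pair counted once, so sparse score
sets (aligners that decline most pairs) are handled consistently.

Pairs scoring at or above the cap are *more* similar than the cap; assigning
them the cap distance would invert their ordering, so the default clamps
them to distance zero (`overflow_mode="clamp"`). A `"literal"` mode that
assigns δ = s_n instead is retained for comparison experiments. Distances
produced by the transform lie in [0, s_n] provided scores are non-negative,
which alignment scores are in practice.

Asymmetric score files (aligners are not guaranteed symmetric) are
symmetrized before the transform — by the mean of the two directions by
default, min/max optionally. Dissimilarity-type inputs (e.g. probability
scores that already behave like distances) bypass the transform entirely:
diagonal forced to zero, negative entries rejected.

## Classical MDS

The squared distances are double-centered, A_ij = −½(δ²_ij − rowmean_i −
colmean_j + grandmean), and coordinates are X_ik = √λ_k ν_ik from the
eigendecomposition of A. Determinism choices: eigenpairs sorted by
descending eigenvalue with ties kept in original order, and each
eigenvector's sign fixed so its largest-magnitude component is positive.
Columns whose eigenvalue is non-positive are set to zero rather than
shrinking the requested dimensionality — the declared r is kept, and
negative eigenvalues are recorded as a diagnostic (they measure
triangle-inequality violations in the input; exact Euclidean inputs have
none). Incomplete matrices must be imputed first (see sparse handling).

## SMACOF

Raw stress σ(X) = Σ_{i<j} w_ij (d_ij(X) − δ_ij)² is minimized by iterative
majorization. For complete, unweighted data the update is

    x_i' = (1/N) Σ_j [ x_j + δ_ij (x_i − x_j)/‖x_i − x_j‖ ],

with a zero direction term for coincident points (the standard Guttman
convention). For weighted data — in particular binary observation masks —
the update is the exact weighted Guttman transform X' = V⁺B(X)X with
V = diag(W·1) − W. A simpler per-row normalization by the number of
observed partners was considered and rejected: it is not the minimizer of
the majorizing quadratic, so it forfeits the guarantee that stress never
increases, which this package treats as a contract (and asserts per
iteration in its tests). V⁺ is computed once per fit.

Convergence: iterate until (σ_prev − σ_new)/σ_prev < tol (default 1e−5) or
max_iter (default 10 000). When the test succeeds the *previous*
configuration is returned, so an infinite tolerance returns the
initialization after zero iterations and the recorded stress always matches
the returned coordinates. A zero-stress start returns immediately.
Initialization is classical MDS by default (fast, high quality), uniform
random in [0, max δ] per axis with a recorded seed, or caller-supplied.
Random and CMDS starts converge to equivalent maps on Euclidean-realizable
inputs (Procrustes statistic < 1e−3 with matching final stress), though
random starts can land in local minima on small symmetric configurations —
another reason CMDS is the default.

## Sparse data

Two policies for unobserved pairs:

* **weights** (default for SMACOF): zero weight in the stress, so the
  embedding infers unaligned pairs transitively through shared neighbors.
  This is the interesting regime for hub-dominated sparse score sets.
* **imputation** (required for classical MDS): fill with the recorded cap
  s_n (an unaligned pair is "at least as far as the cap") or with the mean
  observed distance.

A disconnected observation graph makes weighted SMACOF ill-posed (components
float freely); generation and fitting log a warning and the connectivity
check is exposed (`synth.observed_graph_connected`).

## ROC analysis

Pairs at distance ≤ t are predicted related; the gold standard is shared
clade membership at a chosen SCOP level. Thresholds are every unique
observed distance plus one sentinel below the minimum (anchoring the (0,0)
ROC point; the maximum distance anchors (1,1)) — exhaustive, no sampling.
AUC is the trapezoidal integral, which equals the Mann–Whitney statistic
P(δ_pos < δ_neg) + ½P(δ_pos = δ_neg). The operating threshold maximizes
TCR = TPR + TNR; the comparison is done in integer arithmetic
(tp·N_neg + tn·N_pos) so exact ties are resolved reproducibly toward the
smallest threshold, and the sentinel itself is never selected. Pairs with
unobserved distances are excluded from the pair universe.

Per-clade precision/recall/F1 use the pair universe "at least one endpoint
in the clade": within-clade pairs at ≤ t are TP, beyond t FN; mixed pairs at
≤ t are FP. Conventions: precision 1 when nothing is predicted, F1 = 0 when
precision + recall = 0. Other clades' internal pairs never pollute a
clade's precision.

## Trees and tessellation

Neighbor joining is the canonical Saitou–Nei algorithm with exhaustive
Q-criterion search; ties are broken toward the lexicographically smallest
index pair, so output is deterministic even on degenerate (all-equal)
inputs. The final three-way join is kept as a trifurcating root. Negative
branch lengths are kept as computed — clustering uses original distances,
not branch lengths, so they are cosmetic; an export-side clamp is available.

Maximum-linkage tessellation descends from the root and emits a subtree's
leaves as one cluster as soon as their maximum pairwise *original* distance
is ≤ t; leaves always qualify. Raising t only merges clusters (partitions
are nested in t). Cluster labels follow depth-first discovery order.

## Partition agreement

Best-match mapping assigns every source group the target group with maximal
Jaccard J = |A∩B|/|A∪B| (ties to the lexicographically smallest target
label; a group overlapping nothing maps to J = 0 and is flagged). Reported
statistics: max/mean/population-std of the per-target degree, mean/
population-std of J, and Ratio-1 = #sources/#distinct-targets − 1, which is
0 exactly for a one-to-one correspondence. The mapping is directional and
both directions are intended to be reported; mean_degree ·
n_unique_targets = n_matched_sources holds identically.

## Power-law diagnostic

The per-entity alignment-count histogram is binned logarithmically with
geometric bin centers (20 bins by default) and a line is fitted to
log10(frequency) vs log10(center) over non-empty bins; the slope is the
reported exponent and R² the fit quality. Equal-width binning (available as
`spacing="linear"`) was rejected as the default after measurement: at a few
hundred entities the tail bins of an equal-width histogram hold 0–2
entities each, and even an ideal power-law degree sequence then caps R²
near 0.86 — Poisson noise on the log scale, not lack of power-law structure.
Logarithmic binning is the standard treatment for scale-free degree data
and restores R² > 0.9 on faithful inputs.

## Synthetic spaces

The generator emulates four statistical features of real fold space: nested
clade structure (fold centers ~ N(0, 10²·I) in r_true = 12 dimensions,
superfamily centers ~ N(fold, 3²·I), members ~ N(superfamily, 1²·I) — the
10 : 3 : 1 spread makes superfamilies separable but not trivially so after
noise); size skew (Zipf(1.5) clade sizes, truncated at 8
superfamilies/fold and 120 members/superfamily, giving ≈15 folds, ≈35
superfamilies, ≈300 members in expectation and plenty of singletons);
measurement noise (additive Gaussian per unordered pair, default sd 0.5,
clamped at zero, optionally with a fraction of pairs inflated ×2.5 to
induce triangle violations, visible as negative CMDS eigenvalues); and
scale-free sparsity (rank-based entity weights rank^(−1.2), pair retention
probability ∝ the product of endpoint weights, calibrated by bisection to
the target observed fraction — hubs are observed against most partners and
the degree histogram follows a tight power law, R² ≳ 0.94 at 400 entities
and 2% density). All randomness flows from one seed through named
substreams (hierarchy / noise / mask).

What the generator does *not* model: realistic protein geometry,
aligner-specific score distributions, asymmetric observation (mask is
symmetric), or correlation between sparsity and similarity (real sparse
aligners preferentially align *similar* pairs; the synthetic mask is
similarity-blind). Passing tests therefore demonstrate algorithmic
correctness and qualitative behavior — noise tolerance, transitive
inference, over-splitting of large clades — not quantitative performance on
any real alignment set.

## Evaluation design choices

* The end-to-end recovery check embeds the default space with SMACOF at
  r = 12, selects the superfamily threshold by TCR, tessellates, and maps
  *true clades onto clusters*: each superfamily should find a near-identical
  cluster (mean best-match J ≥ 0.9 observed ≈ 0.97). The reverse direction
  (clusters onto clades) sits near 0.8 by design: maximum-linkage splits
  large-diameter clades at a single global threshold, so noise-split remnant
  clusters drag the cluster-side mean down — the same asymmetry the
  bidirectional tables show on real data.
* The sparse-regime baseline treats unobserved pairs as never predicted
  (placed beyond every threshold) over the full annotated pair universe.
  Restricting the universe to observed pairs instead would score ≈1.0 here —
  synthetic observed distances are accurate — and would not measure what
  sparsity costs: the inability to rank the ~98% of pairs with no score.
  Against the full-universe baseline (AUC ≈ 0.5), a 12-D weighted-SMACOF map
  of a 2%-observed 400-entity space reaches AUC ≈ 0.63–0.65: transitive
  placement recovers real signal, while remaining far below the ≈1.0 of the
  fully observed map — at this scale 2% of pairs (≈1 600 constraints) is
  genuinely under-determined for 400 × 12 coordinates.
* Problem sizes in tests and the acceptance script (point sets ≤ 100,
  trees ≤ 12 leaves, spaces of ≈240–400 entities, sparse SMACOF capped at
  2 000 iterations) were chosen so the whole suite completes in well under a
  minute of compute while exercising every code path; exhaustive topology
  enumeration backs the neighbor-joining check up to 6 taxa (105
  topologies), with split-set comparison against the generating tree for 7–8
  taxa.

## Known limitations

* Weighted SMACOF computes a dense N×N pseudo-inverse once per fit — fine to
  a few thousand entities, not beyond.
* Neighbor joining is the exhaustive O(N³) algorithm; no relaxed/heuristic
  search mode.
* Classification parsing supports sccs-style dotted codes (dir.cla-like and
  two-column TSV), not CATH or sunid lineage records.
* Multi-domain chains are dropped at parse time by default; no automatic
  domain-to-chain resolution.
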