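# Methods

## Scope and model

The package delineates morphotypes of disarticulated rhombic fish scales
from inter-landmark length measurements and places them in a body-zone
(squamation) model. The statistical core is classical: hierarchical
agglomerative clustering of specimens on raw length variables, validated
and refined by multi-group linear discrimination (canonical variate
analysis), followed by per-group descriptive statistics. No Procrustes
superimposition or outline analysis is involved — the shape information
enters purely through inter-landmark lengths, which suits strongly rhombic,
nearly planar scales.

## Length variables from landmarks

The landmark scheme has 11 labeled points in crown view. The length
definitions are implemented as the simplest constructions consistent with
the anatomical definitions of the landmarks:

- `L5` (scale length) = d(LM5, LM6); `L6` (scale height) = d(LM5, LM7);
  `L8` = d(LM9, LM10); `L3` = d(LM2, LM4). These follow directly from the
  landmark definitions (LM6 and LM8 are projections of LM5 onto the
  anterior crown margin and posterior base margin).
- `L1` (peg length) is the perpendicular distance of LM1 beyond the dorsal
  crown margin (the LM4–LM5 line), measured away from the crown interior
  (represented by the centroid of LM6 and LM7) and clamped at zero.
  Whether the original measurements ran perpendicular to the margin or
  along the peg axis is not recorded anywhere; the perpendicular
  convention is the default and the mapping is configurable in principle
  (the function table is plain code).
- `L4` (longitudinal extent) is the range of the projections of LM2..LM7
  onto the anteroposterior unit axis `u = (LM5 − LM6)/‖LM5 − LM6‖`. An
  isolated scale carries no body frame, so the scale's own long axis
  stands in for the body axis.
- `L2` (keel length) is approximated by d(LM1, LM11), and `L7` (concealed
  field) has no defining landmark at all and is treated as a directly
  measured optional input. Both are removed by variable selection before
  clustering, so neither approximation reaches the analysis.

All derived lengths are invariant under rigid motions and reflections and
scale linearly with the coordinates; degenerate configurations (LM4 = LM5
or LM5 = LM6) raise geometry errors rather than returning junk.

## Variable selection

Pearson correlations are computed on the raw millimetre values — the
variables share one dimension, so standardization is deliberately omitted,
matching the clustering convention below. Variables are linked when
|r| ≥ threshold (default 0.90; the original analysis reports only that the
pruned variables were "strongly" correlated, and 0.90 reproduces the
described grouping {L2, L6, L8} and {L5, L7} while keeping the rest
independent). Connected components of the link graph form clusters —
transitive grouping, so a chain of strong pairwise correlations is one
cluster — and within each cluster the earliest variable of a preference
list is kept. The default preference (L6 before L2/L8, L5 before L7)
encodes which variable is easiest to measure on CT models. A numerical
slack of 1e-12 on the threshold comparison lets exact linear dependence
(r = 1 up to round-off) link at threshold 1.0.

## Clustering

Between-groups linkage is implemented as unweighted average linkage over
squared Euclidean point distances: the distance between two clusters is
the mean of all cross-pair squared distances. This is the standard meaning
of "between-groups linkage" in the statistical packages used for such
analyses. Implementation notes:

- Lance–Williams incremental update,
  `d(a∪b, k) = (n_a d(a,k) + n_b d(b,k)) / (n_a + n_b)`, O(n²) per merge;
  a brute-force O(n³) recomputation of all cross-pair means guards
  correctness in the tests on every random instance with n ≤ 12, and the
  merge heights are cross-checked against an independent library
  implementation at n = 30.
- Average linkage is reducible, so merge heights are monotone
  non-decreasing; the dendrogram constructor asserts this on every run
  (relative tolerance 1e-9).
- Tie-break when two candidate merges have exactly equal linkage: the pair
  with the lexicographically smallest (minimum member id, minimum member
  id) key merges first. The choice is arbitrary; determinism is the point.
- Partitions from `cut_k` are canonical: groups renumbered by descending
  size, ties by smallest member id. Row order of the input therefore does
  not affect the labels.
- `compare_k` reports group sizes, within-group dispersion, mean
  silhouette (Euclidean) and 2-D principal-component coordinates per
  candidate k. It never selects k: in this workflow k is chosen by
  comparing the candidate partitions against articulated specimens, which
  is irreducibly a user decision.

## Canonical variate analysis

With between-group scatter `B` and pooled within-group scatter `W`, the
canonical axes solve `B a = λ W a` (solved as a symmetric-definite
generalized eigenproblem), ordered by descending λ and scaled so the
pooled within-group variance along each axis is 1, i.e.
`aᵀ (W/(n−g)) a = 1`. At most min(g−1, p) positive eigenvalues exist;
the model asserts this bound on every fit.

Classification assigns each scale to the group whose mean is nearest in
Mahalanobis distance under the pooled within-group covariance with equal
priors — linear, not quadratic, discrimination, which is what
"canonical variate (discriminant) axes" implies. Ties go to the lowest
group id. Accuracy is resubstitution (the training scales are classified),
because the workflow uses CVA to test the self-consistency of cluster
labels, not to estimate out-of-sample error.

Refinement: per round, fit → classify → move every misclassified scale to
its predicted group → refit. Default one round. The history records one
accuracy per fitted model, so with one round it holds the accuracy of the
input labels and of the refined labels. A reassignment that empties a
group retires it (g decrements) with a logged warning. Single-member
groups are permitted throughout: they contribute a mean but no
within-group scatter. A singular `W` raises a singularity error advising
the optional ridge `W + λ·diag(W)` (default λ = 0).

## Per-group statistics and morphotype matching

Two conventions matter and both are forced by the reference table the
package embeds:

- **Population SD (divisor n).** The reference prints SD 0.00 for a
  single-scale morphotype, which the n−1 convention cannot produce.
- **Ratio means are means of per-scale ratios.** The reference morphotype 1
  row gives mean L6/L5 = 4.75 while mean L6 / mean L5 = 8.25/1.75 ≈ 4.71;
  only the per-scale convention reproduces the printed column.

Anonymous cluster groups are matched to named morphotypes by minimizing
total Euclidean distance between group mean vectors (L5, L6, L6/L5) and
reference means via the Hungarian algorithm, with the total cost reported
so a bad match is visible. Matching by nearest parameters, rather than by
assuming a published letter↔morphotype correspondence, is deliberate: no
such correspondence was ever published. Two reference entries carry an
alternative height/length reading from the running text (morphotype 6:
2.73 vs 2.34; morphotype 11: 1.11 vs 1.04); the table value is
authoritative and the text variant is stored alongside, not silently
"fixed".

## Squamation map

A data structure, not a drawing: 16 areas in 4 belts (3 dorsal, 5 middle,
6 ventral, 2 unpaired), each area holding its belt, assigned morphotype
(M5 maps to none — that body region is not preserved), and free-text
anatomical bounds; auxiliary elements (fin basal scales, lepidotrichia,
the lateral-line modifier applying to morphotypes 1–4, median dorsal
plates) sit outside the area grid. Belt sizes and the 16-area count are
asserted at construction.

## Synthetic data

The default generator reproduces the study conditions: 8 clusters with
sizes 23, 64, 49, 37, 27, 15, 10, 1 (226 scales; the published sizes of
the anonymous groups paired with the reference morphotypes in table order,
which places the single scale on morphotype 12 — the near-symmetric
ventral-midline scute series). Per cluster, L5 and L6 use the published
mean/SD; L1 and L3 are only published as ratios to L6, so their means are
`ratio_mean · L6_mean` with first-order SD propagation
`sd² = (ratio_mean·L6_sd)² + (L6_mean·ratio_sd)²`; L4 has no published
statistics and defaults to L5's (both measure anteroposterior extent).
Variables are independent normals per cluster — only marginal SDs are
published — truncated at 0 by clipping; a per-cluster covariance hook
exists for harder tests. Truncation bias is negligible at the published
mean/SD ratios for L5/L6 but visibly skews L1 in the low-peg morphotypes
(mean/SD ≈ 0.9 for morphotype 6); this is accepted and documented rather
than corrected.

Dependent variables are generated to carry the redundancy structure the
real variables exhibit: `L2 = 0.9·L6 + ε`, `L8 = 1.1·L6 + ε`,
`L7 = f_c·L5 + ε` with the per-morphotype concealed-field fraction `f_c`
(0.34–0.38) and measurement noise ε of SD 0.02 mm — a plausible
repeatability for sub-millimetre CT measurements, and small enough that
the generated correlations are "strong" (≥ 0.95 for L5–L7 across seeds),
as the source analysis describes for the real scales.

What the generator does **not** emulate: inter-variable correlations
within clusters (unknown without the raw table), non-Gaussian shape
variation, allometry between specimens, and measurement outliers. Passing
recovery tests therefore show that the pipeline recovers the published
cluster structure under idealized noise, not that the real scales are this
cleanly separated — the real analysis needed a CVA refinement precisely
because neighbouring morphotypes overlap.

The landmark generator inverts the length definitions: it places the
crown-corner landmarks so the forward computation returns requested
L5, L6, L1, L3 exactly (dorsal margin on the x-axis, posterior margin
vertical), fills the remaining base landmarks with template proportions,
then jitters. It exists to test the morphometry module and to fabricate
TPS fixtures; it makes no claim to anatomical realism beyond a valid
rhombic outline.

## Problem sizes and determinism

The test suite and the acceptance script run the full 226-scale analysis
(fractions of a second per run) and sweep 20 seeds for the recovery
statistics; brute-force oracle comparisons use 200 random instances of
n ≤ 12 and dense-algebra checks at n ≤ 45. All stochastic steps draw from
`numpy.random.default_rng` seeded explicitly; the analysis stages are
deterministic, so a report is bit-reproducible apart from its timestamp
field.

## Known limitations

- The landmark→length mapping for L1/L2 is a documented convention, not a
  recovered protocol; real replication should supply measured lengths
  directly via CSV.
- Replicating the original accuracies (94% → 96.04%) exactly requires the
  original 226-scale measurement table and the original software's
  linkage/tie-break details; with a table supplied, the pipeline reports
  its own accuracy history and deviations are informative rather than
  failures.
- Ridge regularization changes the discriminant geometry slightly; it is
  an escape hatch for degenerate inputs, not a tuning parameter.
- Ridge-count ranges are carried as reference metadata only; they are not
  computable from length variables.
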