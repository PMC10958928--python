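# Methods

This note documents the models implemented in `netformula`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that make runs reproducible.

## Binomial formula–target identification

A formula's *active compounds* are the union of compounds linked to its
herbs (optionally pre-filtered by drug-likeness screening). Compound–target
links carry confidence scores on the 0–1000 scale used by interaction
databases; links are kept when `score ≥ score_threshold` (default 400, the
conventional medium-confidence cutoff). Curated links without a score carry
the sentinel 9999 and pass every threshold; on duplicate (compound, target)
pairs the maximum score is kept, which is conservative toward retaining
associations.

For each target `t`, the background hit probability is estimated from the
score-filtered link table as

    p_t = (# distinct compounds linked to t) / (# distinct compounds in the table),

i.e. the chance that a randomly chosen catalogued compound hits `t`. The
table should therefore be the full background catalogue, not just the
formula's slice; the estimate sharpens with catalogue size, which is why
the synthetic fixture defaults to a 500-compound inventory. With `n` active
compounds of which `k` hit the target, the tail probability
`P(X ≥ k), X ~ Binomial(n, p_t)` is computed through the scipy survival
function (exactly 1 for `k = 0`). Targets with `P < P_sig` (default 0.05)
are ranked ascending by p-value — ties broken by larger `k`, then target id,
so output is deterministic — and scored `geneScore = −log₁₀(P)/rank`;
non-significant targets score 0 and carry rank 0. The rank denominator is
the model's own multiplicity attenuation; no additional correction is
applied. `chemScore` of a compound is the arithmetic mean of `geneScore`
over **all** its profiled targets, zeros included, so that the score is
total on the active set; compounds hitting no profiled target score 0.
The log base (10 or e) is configurable; base 10 is the default. A tail
probability that underflows to zero is clamped to the smallest positive
normal float and flagged, keeping the log finite.

## Drug-likeness screening

QED is the weighted geometric mean of eight asymmetric-double-sigmoid
desirability functions (published parameter set fitted to approved oral
drugs) of MW, ALOGP, HBA, HBD, PSA, ROTB, aromatic rings and structural
alerts, using the mean-weight scheme
`w = (0.66, 0.46, 0.05, 0.61, 0.06, 0.65, 0.48, 0.95)`. Desirabilities are
floored at 1e-6 before the logarithm so extreme descriptors cannot produce
−∞. Lipinski violations count `HBD > 5`, `HBA > 10`, `MW > 500`,
`ALOGP > 5` (boundaries pass inclusively, 0–4); Veber violations count
`ROTB > 10` and the joint failure `PSA > 140 ∧ HBD+HBA > 12` (0–2 — the
second criterion is a disjunction and fails only when both alternatives
fail). A compound passes the screen when `QED ≥ qed_min` (default 0.3, a
conventional weak drug-likeness floor; the threshold is study-specific and
user-settable) and each rule shows at most one violation. Descriptors are
taken from the input table; computing them from structures is out of scope.

## Enrichment and co-association

Enrichment is the hypergeometric upper tail on (overlap `k`, term size `K`,
query size `n`, universe size `N`), with the query silently intersected
with the universe (dropped genes counted) and only overlapping terms
(`k ≥ 1`) tested. BH-FDR is applied across the tested terms only — this
choice changes adjusted values and is therefore stated here. Rows sort by
p-value, ties by term id.

The shared-term curve compares two ranked enrichment results at depths
`n = 1..N'` with `N' = min(top_n, len(a), len(b))`: `C(n)` is the number of
term ids common to both top-n lists. Two statistics are reported:
`similarity = C(N')/N' ∈ [0, 1]` and `AUC = mean of C(n) over n`, which is
unnormalized and can exceed 1 for deeply co-enriched lists — matching the
two scales these statistics are conventionally reported on. Both are
emitted along with the full curve so alternative normalizations can be
derived downstream.

## Network proximity

The KATZ score between gene sets A and B on a PPI graph is
`|A∩B| + Σ_{l=1..3} β^l · path_l`, where `path_l` is the number of
length-`l` walks between the sets (entries of adjacency powers, implemented
as sparse matrix–vector products) and β = 0.001. Walk counting is the
construction the geometric β-weighting belongs to. Overlap enters with
weight 1 (β⁰); it is also reported separately. The distance score is the
symmetric average closest distance: each node's unweighted shortest-path
distance to the nearest member of the other set, averaged over both sets;
nodes with no finite cross-set distance are excluded from numerator and
denominator and counted.

Both tests draw `n_perm` (default 1000) uniform random node-set pairs of
the observed sizes as the null — uniform rather than degree-matched for
determinism and simplicity; degree-preserving nulls are a known refinement
this package does not implement. Empirical p-values use the add-one
estimator `(1 + exceedances)/(1 + n_perm)`, so they never reach 0 and lie
in `[1/(n_perm+1), 1]`. The KATZ test is upper-tailed (more connected than
random, null summarized by its median and mean); the distance test is
lower-tailed (closer than random) and additionally reports
`z = (observed − null mean)/null sd`, NaN when the null is degenerate. The
distance machinery precomputes a BFS distance matrix, so thousand-draw
nulls are cheap on graphs of a few thousand nodes.

The seed-expansion subnetwork is the induced subgraph on the seed genes,
optionally extended by connector nodes — non-seed nodes adjacent to at
least two seeds. The ≥2-seed rule keeps expansion conservative (a single
shared neighbor is weak evidence of pathway membership); isolated seeds are
retained so the projection is total on the seed set.

## Core-formula mining

The herb network has one node per herb and edge weight = number of
prescriptions containing both herbs. Maximal cliques of the binarized
network (edges with weight ≥ threshold) are enumerated with Bron–Kerbosch
with pivoting, implemented in-package and verified against brute-force
subset enumeration; only cliques of size ≥ 2 are considered and results are
canonically ordered.

Candidate formulas are evaluated with confidence
`|F∩R|/|F|` per prescription `R`, average confidence ᾱ over **all**
prescriptions (supporting-only averages can be derived from the emitted
counts), and support `S_α` = fraction of prescriptions with confidence
≥ α (default α = 0.9; a 1e-12 tolerance guards float rounding at exact
fractions). A formula qualifies when `size ≥ min_herbs` (default 3;
optionally exactly `desired_herbs` when `enforce_size`) and `S_α ≥ s_min`
(default 0.1; typical practice is 0.01–0.3).

**Adaptive binarization.** Every distinct edge weight is scanned as a
threshold. A qualifying formula that is a *proper subset* of a qualifying
formula found at any scanned threshold is treated as a fragment — an
over-high threshold splits a true k-herb clique into (k−1)-subcliques that
each still qualify — and is neither counted nor returned. The chosen
threshold maximizes the count of remaining (non-fragment) formulas, ties
resolved toward the larger threshold (sparser network). A naive
count-maximizing objective without fragment pruning demonstrably selects
fragmenting thresholds and returns subsets of the true formula; the pruned
objective recovers planted formulas reliably. When nothing qualifies
anywhere, the result is empty with per-threshold diagnostic counts rather
than an exception.

**Merging.** Similarity between formulas is Jaccard on herb sets.
"Together" merges each connected component of the ≥threshold similarity
graph by union in one pass; "Step" repeatedly merges the single most
similar qualifying pair (ties to the lexicographically smallest union) and
recomputes similarities until none qualify. Metrics are recomputed on the
dataset after merging; a merged formula keeps the smallest source threshold
among its parts. Recommended similarity threshold > 0.6. Both methods are
idempotent.

**Person-based statistics.** Each patient contributes the maximum
confidence over their visits; person support is the fraction of patients
reaching α. With one visit per patient this reduces to `S_α`.

## Synthetic fixtures

Generators are pure functions of a `FixtureSpec` (numpy PCG64 seeded from
the spec), producing byte-identical files under identical specs. Defaults
describe the study conditions used throughout the tests: 30 herbs, 500
compounds, 100 targets, 500 prescriptions from 250 patients (round-robin,
so patients have multiple visits), a 5-herb formula embedded intact at rate
0.6 with prescriptions padded to 8–15 herbs by uniform noise, a
compound–target background of density 0.02 with scores uniform on 150–999,
and one target enriched 10-fold among the formula's 50 designated compounds
with scores 400–999 (guaranteed to survive the default filter). At
enrichment factor 1 no extra links or biased query genes are planted, so
the planted entities are pure background — the calibration case. The
synthetic PPI is a preferential-attachment graph, connected and scale-free-
ish like real interactomes.

These fixtures reproduce the *formats* and the *signal-versus-background
structure* of real data, not its marginals: real herb usage is highly
non-uniform, real compound–target matrices are sparse with hub targets, and
real interactomes have higher clustering than preferential attachment
gives. Passing recovery tests therefore demonstrates correctness of the
algorithms under controlled signal, not performance guarantees on any
particular database.

## Numerical and reproducibility conventions

- All tail probabilities go through scipy survival functions; BH through
  statsmodels. Both are verified against exhaustive enumeration oracles in
  the test suite.
- Every ordering has a documented deterministic tie-break (p-value, then
  k, then id; QED descending then id; clique size then member list).
- All randomness flows from a single seed (`AnalysisConfig.seed` /
  `--seed`); permutation tests and generators are reproducible across runs.
- Problem sizes in the test suite and acceptance script (500-node PPI, 200
  calibration replicates × 1000 permutations, 100 recovery seeds, 500
  prescriptions) were chosen to make the statistical checks sharp at
  desk scale.

## Known limitations

- No herb-name synonym resolution beyond whitespace normalization; name
  dictionaries are data, not method.
- Gene identifiers are opaque strings; no identifier conversion.
- Permutation nulls are not degree-matched.
- The GA-based "core effective formula" stage, entropy-based herb-pair
  scoring and centrality-based core-herb ranking sometimes used alongside
  clique mining are out of scope, as are molecular docking and any web UI.
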