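# Methods

This note records the model implemented by `concordnet`, the numerical and
design choices made where the method description leaves them open, what the
synthetic cohort generator does and does not emulate, and known limitations.

## Model and pipeline

A cohort is an n × k binary table: patient i endorses symptom j (after
dichotomization of three-level severity codes — a symptom counts only when it
had at least moderate impact on functioning). Patients endorsing nothing are
removed (they form an a-priori group with no co-occurrence information);
symptoms endorsed by nobody are kept as isolate nodes so that node indices
and network renderings stay aligned with the input vocabulary.

Per patient, the concordance matrix is xxᵀ — rank-1 over {0,1}, stored by its
support set and materialized densely only on demand. Its k(k+1)/2 *unique
entries* are the diagonal followed by the strict upper triangle in row-major
order. Including the diagonal in the unique entries is a deliberate reading:
it is the only one under which two patients sharing three symptoms agree on
6 co-present entries (3 presences + 3 pairs), the method's defining worked
example. The vectorization is invertible, and rejects vectors inconsistent
with a rank-1 binary outer product.

Between-patient similarity is the Hubert–Arabie ARI of the two unique-entry
vectors, treated as two binary labelings of the L = k(k+1)/2 positions and
computed in closed form from the 2×2 contingency table. Degenerate pairs
(both vectors constant, denominator 0) score 1 when identical and 0
otherwise — the respective limits of perfect and absent agreement. Negative
values are clamped to 0 in the similarity matrix and the diagonal is set
to 1; self-loops are dropped when the matrix becomes a graph, so the
diagonal convention never influences community detection. The all-pairs
computation is a single matrix product over the 0/1 vectors; the per-pair
closed form and an independent pair-enumeration oracle (and scikit-learn's
`adjusted_rand_score`) agree with it to 1e-12 in the test suite.

Patient communities come from Pons–Latapy walktrap on the weighted similarity
graph. Walk length t = 4 (the walktrap authors' default; nothing in the
method description fixes it); the dendrogram is cut at maximum Newman
weighted modularity. Walktrap uses exact walk distributions, not sampled
walks, so detection is deterministic; the `seed` argument exists only for
interface symmetry. Isolated nodes (zero similarity to everyone) become
singleton communities. Detection is delegated to igraph's reference C
implementation behind the package's graph types; modularity is implemented
independently from the formula and cross-checked against both a literal
double-sum and igraph. On well-separated planted graphs of ≤ 8 nodes the
returned cut attains the exhaustively-searched global modularity maximum.

Each community's matrices are summed (S = Σ xxᵀ = BᵀB for the member block B)
and off-diagonals normalized by √(SᵢᵢSⱼⱼ), i.e. the Ochiai / binary cosine
coefficient of the two symptoms' patient sets — bounded in [0,1] by
Cauchy–Schwarz, 1 exactly when the symptoms co-occur in every patient who has
either. The normalized matrix's diagonal is held at 0 and raw endorsement
counts are exposed separately, so graph algorithms see no self-loops.

Centralities use edge length 1/weight (stronger co-occurrence = shorter
distance): Brandes/Freeman shortest-path betweenness (unnormalized, unordered
pairs; unreachable pairs contribute 0), strength (row sums), and
Wasserman–Faust closeness C = (r/Σd)·(r/(k−1)) with r the number of reachable
other nodes — equal to plain inverse average geodesic distance on connected
networks, 0 for isolates. The "mean of shortest paths through a symptom"
phrasing in the original description is non-standard; canonical weighted
betweenness (the convention of the qgraph/network-psychometrics toolchain it
cites) is adopted. Betweenness and closeness are delegated to networkx and
verified against an exhaustive simple-path enumeration oracle to 1e-9.

Each statistic is z-standardized by pooling all symptom values across the
compared community networks (the shared [0,1] weight scale is what makes the
pooled comparison meaningful; the plausible alternative — standardizing
within each network — would erase exactly the between-community differences
the method reports). Population SD (divide by N) is used: the compared
networks are the whole universe of interest, not a sample. A constant pooled
statistic yields all-zero z-scores with a warning. Flags are descriptive
cut-offs, not tests: bridge ⇔ z-betweenness ≥ 2; highly central ⇔
z-strength ≥ 2 and z-closeness ≥ 2. The threshold is configurable
(`bridge_threshold`), defaulting to the 2-SD rule.

Symptom clusters are walktrap on each normalized community network, with the
solution's modularity reported for cross-community comparison.

## Pipeline and I/O conventions

Input is a CSV with a patient-ID column and one column per symptom; cells in
{0,1} (presence) or {0,1,2} (severity, auto-detected and dichotomized).
Missing cells fail validation unless `--missing-as-zero` (absence of
endorsement is the conservative reading; imputation must be opt-in).
Symptom order is preserved from the file; duplicate IDs, non-numeric and
out-of-range cells are rejected with row/column context. Community
percentages are reported against the post-filter patient count. All outputs
are plain text (CSV/JSON/GraphML), written deterministically; stage timings
go to the stderr log only, so re-running a config byte-reproduces outputs.
All communities are aggregated; `--min-community-size` (default 1) only
controls which enter characterization and reporting, mirroring analyses that
focus on the few large communities.

## Synthetic cohorts: what they emulate, and a negative result

`CohortDesign` plants the two-axis heterogeneity the method is motivated by:
communities share the *same* symptom clusters and differ only in which
bridge symptom ties them together. Defaults: 2 communities × 100 patients,
k = 20 symptoms, two shared disjoint 7-symptom clusters (indices 0–6, 7–13),
one community-specific bridge each (14 and 15), 4 background symptoms;
p_cluster = 0.85, p_bridge = 0.9, p_noise = 0.05. Each patient draws one of
their community's clusters uniformly, endorses its symptoms at p_cluster,
their community's bridge at p_bridge regardless of the drawn cluster (that
is what makes it a bridge), and everything else at p_noise. The layout
values (k, cluster sizes, one bridge per community) were fixed once as a
realistic small checklist; the generator also validates the probability
ordering p_noise < p_bridge, p_cluster.

By construction the two communities have near-identical marginal symptom
prevalence (verified in the tests: max non-bridge prevalence gap < 0.05), so
no first-order method can separate them — the scenario isolates second-order
structure.

Two planted features are recovered robustly, and one is provably not:

* Given the *true* communities, the characterization arm flags exactly the
  planted bridges (recall 1.0 across seeds in the test suite): the bridge is
  the sole connector between the two cluster blocks of the aggregated
  network and dominates pooled z-betweenness.
* End-to-end, however, pairwise-similarity clustering does **not** recover
  the planted communities under this design, and the acceptance test that
  requires mean community ARI ≥ 0.8 fails (measured mean ≈ 0.0 over 20
  seeds). The reason is structural, not a tuning artifact: two
  same-community patients drawn from *different* clusters share only the
  bridge's diagonal entry (≈ 1 of ~30 endorsed unique entries; their ARI is
  near 0 and frequently clamps at 0), while two same-cluster patients from
  *different* communities share the entire cluster (≈ 28 entries, ARI
  ≈ 0.35–0.5). Any modularity-maximizing partition therefore prefers the
  symptom-cluster split over the planted-community split, and walktrap
  returns it. The failing expectation is kept as-is rather than weakened:
  it documents a real boundary of pairwise second-order clustering when
  planted clusters are fully disjoint at the patient level. Designs in which
  patients express both clusters with overlap — arguably closer to real
  symptom data — do reward the bridge signal and push community recovery up
  (ARI ≈ 0.7 in side measurements), but they are not the planted scenario
  this generator encodes.

The generator does not emulate: longitudinal drift across assessment waves,
ordinal/continuous severity, correlated (non-independent) endorsement noise,
or item-level missingness.

## Numerical choices and degenerate inputs

* ARI arithmetic is done in float64 with C(x,2) evaluated as x(x−1)/2 to
  avoid integer overflow at large L; the vectorized all-pairs path
  symmetrizes away last-bit round-off and re-pins the diagonal at 1.
* Similarity CSV round-trips use pandas' `float_precision="round_trip"`.
* Zero-total-weight graphs have modularity 0 by convention; edgeless graphs
  partition into singletons.
* Walktrap ties are resolved by igraph's deterministic merge order, so
  results are platform-independent for identical inputs.
* An all-identical cohort collapses to one community whose endorsed pairs
  all have weight 1; a single-community characterization emits the
  constant-statistic warning and zero z-scores (nothing can be 2 SD above
  the mean of a single pooled network with no variation).

## Limitations

Only dichotomous symptom indicators are supported. Similarity is O(n²) in
patients (a 531-patient cohort is seconds; tens of thousands of patients
would need blocking). No edge filtering/regularization is applied to the
normalized networks (the dense matrix is the method's object), no stability
or bootstrap analysis of centralities is provided, and the bridge/highly-
central cut-offs are descriptive conventions, not significance statements.
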