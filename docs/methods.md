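# Methods

This note documents the modelling conventions, numerical choices and design
decisions behind `hetnet`, and what the shipped experiments do and do not
demonstrate.

## Scope and containers

All computations act on finite simple undirected graphs (no loops, no
parallel edges), held as `networkx.Graph` objects with opaque node labels.
Disconnected graphs are first-class citizens — the replication principle
manufactures them deliberately — and each measure declares its own
applicability (HCS requires connectivity; the inverse-square-root measures
HE/HE′/HEp reject isolated nodes, where `k^(−1/2)` is undefined, rather than
silently dropping them).

## Measure conventions

The battery is the 12 measures HN, HS, HF, HHG, HA, HE, HAp, HEp, HAED,
HPED, HJ, HCS. Where the defining literature leaves a constant or a
summation convention open, the registry freezes one choice:

* **HF** divides the degree centralization HHG by `(n−1)(n−2)` — the maximum
  of HHG over all graphs on `n` nodes, attained by stars and wheels. No
  per-density renormalization is applied; that is the role of the separate
  HB measure, which rescales `kmax` between its minimum attainable value
  `⌈2m/n⌉` and its maximum `min(n−1, m)` at the given `(n, m)`. Both bounds
  are validated in the test suite by exhaustive enumeration of all graphs on
  up to six nodes; when the two coincide (null and complete graphs, and any
  `(n, m)` that forces the maximum degree) HB is defined as 0 and a warning
  is recorded.
* **Sums over node pairs.** "All pairs" measures (HAp, HEp) sum over
  unordered pairs `i < j`. The expected-difference measures (HHW, HPED) sum
  over ordered pairs including the zero diagonal; the two conventions differ
  only by the factor 2 that the presets' scaling constants already absorb.
* **HAED** estimates the edge-conditional degree-pair probability by the
  empirical frequency of the unordered degree pair among the `m` edges and
  uses scaling `c = 1`, giving `(1/m) Σ_pairs count(k,l)² |k−l|`. Under this
  convention the measure scales linearly with the replication factor, which
  is its documented behavioural signature.
* **HPED** (battery preset) attaches degree-frequency weights `P(kᵢ)P(kⱼ)`
  to each *node* term and scales by `1/k̄`. This literal node-sum is kept
  deliberately: it is the unique reading that scales quadratically under
  replication and that can *increase* under a transfer rewiring — the two
  behavioural signatures the compliance analysis documents. The alternative
  reading (expectation over degree *values*, i.e. the relative mean absolute
  difference) is available as the HHW preset up to its factor ½; see
  "Known limitations" for the consequence.
* **HHW** is the degree Gini coefficient: half the relative mean absolute
  difference with uniform node weights, always in [0, 1]. It is computed in
  `O(n log n)` from the sorted degree sequence via prefix sums (the naive
  double loop is kept as a test oracle).
* **HJ** follows the diversity view of heterogeneity. The printed per-node
  form `J = (1/n) Σ_{k:P(k)>0} (1−P(k))²` is exposed as `hj()`, with its
  normalization `hj_normalized()` dividing by the exact complete-diversity
  value `1 − 3/n + (n+2)/n³` by default (the asymptotic `1 − 3/n` exceeds 1
  for small n — e.g. the complete-diversity value at n = 4 — and is kept
  behind a flag). The *battery* entry uses the scale-free distribution form
  `Σ_k (1−P(k))² = n·J`: a pure functional of `P`, which is what makes the
  diversity measure invariant under replication, as its rationale demands;
  at any fixed `n` it ranks graphs identically to `J`.
* **HCS** uses the spectral radius from a dense symmetric eigensolver for
  `n ≤ 500` and Lanczos iteration (ARPACK, tolerance 1e-10) above. Both are
  established eigensolvers rather than a hand-rolled power iteration; the
  contract (largest adjacency eigenvalue within tolerance, sandwiched
  between `k̄` and `kmax` on connected graphs) is property-tested.
* **HS′** (variance normalized by its maximum at fixed `(n, m)`) computes
  its denominator by exhaustive enumeration for `n ≤ 7`. Above that it
  searches degree sequences built from a high-degree group, a low-degree
  group and one intermediate node — the structure of the extremal graphs —
  keeping the graphical ones; this search is flagged approximate in the
  result's warnings.

## Manipulations and the compliance engine

**Transfer.** A move `(pivot, u, v)` rewires the edge `(pivot, u)` to
`(pivot, v)` and is admissible when `deg(u) ≥ deg(v) + 2`, so the move
narrows the degree gap without reversing the order. Compliance demands a
*strict* decrease of the measure: a no-change outcome counts as a violation.
This strictness matters — HN is non-compliant precisely because a rewiring
whose endpoints cross the mean symmetrically leaves the absolute-deviation
sum unchanged.

**Addition** raises every degree by the same integer `c ∈ {1, 2}`, with
per-measure semantics:

* *degree shift* (HN, HS, HF, HHG, HA, HE, HAp, HEp, HPED, HJ): the edge set
  is kept and evaluators receive an explicit degree map `kᵢ + c`. For these
  measures the principle is about the degree profile, and this semantics
  makes the expected invariances exact (deviations from the mean, pairwise
  differences) while the relative measures (HE, HEp, HPED) strictly
  decrease.
* *overlay* (HAED): a true `c`-regular edge-disjoint layer is added on the
  same node set (circulant offsets first, random perfect matchings as
  fallback), because HAED's edge-conditional probabilities respond to the
  newly formed edges — which is exactly how it comes to violate the
  principle.
* *re-realization* (HCS): the shifted degree sequence `kᵢ + c` is realized
  as a fresh connected topology (Havel–Hakimi, then seeded degree-preserving
  double-edge-swap randomizations; 16 candidate realizations per case). A
  supergraph overlay cannot serve here: by Weyl's inequality a `c`-regular
  layer raises the spectral radius by at most `c` while the mean degree
  rises by exactly `c`, so HCS could never increase and the check would be
  vacuous. The addition principle itself does not constrain how the new
  edges connect; letting the topology re-form is the reading under which
  the principle probes HCS at all, and a 12-node witness shows HCS rising
  from 0.2599 to 0.2721 under `c = 1`.

**Replication** forms the disjoint union of `x ∈ {2, 3}` relabelled copies;
the distribution-level variant multiplies degree counts by a rational factor
after pre-scaling to integers. A measure that cannot evaluate the replicated
(disconnected) graph — HCS — fails with that error as its witness.

**Verdicts.** "Pass" is universal quantification over a finite battery:
the four committed witness fixtures, every connected graph on up to six
nodes (exhaustive, via the graph atlas), and 200 seeded Erdős–Rényi graphs
on 4–12 nodes. Passing certifies *no violation found on this battery*, not a
theorem; failing carries a concrete witness (graph, manipulation, before and
after values) that replays exactly. Equality and monotonicity use tolerance
1e-9 — generous against the 1e-10 eigensolver tolerance and irrelevant to
the integer-valued measures on these small graphs. The curated fixtures are
synthetic stand-ins found by randomized search (the counter-example networks
they replace exist only as figures elsewhere); each file documents the
violation it witnesses.

## Generators

* **Erdős–Rényi**: `G(n, p)` with `p = λ/(n−1)` for target mean degree λ.
* **Power law**: a static-fitness sampler — node of rank `i` gets fitness
  `i^(−1/(γ−1))`, edges draw endpoints proportionally to fitness and are
  accepted if new and non-loop, until exactly the target edge count is
  reached. The edge count is matched to the paired ER draw so that model
  comparisons hold density fixed. The realized tail exponent is checked to
  recover γ within ±0.3 on large draws.
* **Exponential**: degrees drawn from the geometric law on {1, 2, ...} with
  the requested mean (the discrete analogue of an exponential degree
  distribution), parity-fixed by decrementing one degree above 1, then
  realized by configuration-model stub matching. Loops and parallel edges
  from the matching are repaired by degree-preserving edge swaps, so the
  drawn degree sequence is realized exactly; if repair fails within budget
  the generator raises rather than silently altering degrees.
* **Completely diverse graphs** (orders 4–7): the degree values are the
  `n−1` distinct values `{1, ..., n−1}` with exactly one duplicated; the
  parity-feasible, graphical, connected-realizable candidate with the
  lexicographically smallest sorted sequence is canonical (e.g.
  `(1,2,2,3)` at `n = 4`, realized by Havel–Hakimi and connected by
  degree-preserving swaps). Densities (0.5–0.6 in this range) are reported
  alongside results, since diverse graphs are necessarily denser than the
  stars they are compared with.
* **Named families**: stars, wheels, cycles, complete and complete-bipartite
  graphs; `r`-regular graphs are circulants (offsets `1..r/2`, plus the
  antipodal offset for odd `r` on even `n`) — deterministic by construction.

All stochastic generators consume randomness through a single seeded numpy
generator; the same seed reproduces the same edge set.

## Experiments and problem sizes

The model sweep's desk scale uses `n = 10⁴` nodes and 5 replicates per cell
(the full design, `n = 10⁵` with 100 replicates per cell across mean degrees
2–50, is available via `SweepConfig(scale="full")`). Ranking assertions use
means across replicates, which are stable at desk scale. Min–max
normalization to [0, 1] is per measure across the whole experiment; a
constant column normalizes to 0 with a warning. On disconnected sweep draws
HCS is evaluated on the largest connected component, and HE/HEp on the
non-isolated nodes, each with a logged warning.

The degree-Gini experiments use `n = 10⁵`: twenty exponential
configuration-model networks (mean degrees cycling over 4, 8, 16) for the
HHW ≤ 0.5 exponential bound, and ten discrete power-law sequences
(`P(k) ∝ k^(−2.2)`, `kmin = 1`, zeta sampler) for the HHW ≥ 0.5 band of
exponents in (2, 2.5). For the geometric law with success probability `1/μ`
the asymptotic Gini is `(1 − 1/μ)/(2 − 1/μ) < 1/2`, so the bound is
approached (0.484 at μ = 16) but not crossed — the simulations probe the
bound where it is tight.

## What the synthetic data does and does not show

The generated graphs emulate the idealized study conditions: independent
edges (ER), rank-based fitness hubs (power law), and maximally uneven degree
multisets (diverse graphs). They contain no community structure, degree
correlations, clustering beyond chance, or temporal dynamics. Passing tests
therefore certify the *mathematical* behaviour of the measures on these
model classes, not their adequacy for any particular empirical network;
on real data with assortativity or modular structure the topology-aware
measures (HA, HE, HAED, HCS) can diverge from the degree-only measures in
ways these experiments do not exercise.

## Known limitations

* **The HPED convention cannot satisfy every documented expectation at
  once.** The node-sum convention adopted for the battery reproduces the
  transfer-violation and quadratic-replication signatures, but under it
  Erdős–Rényi draws *outscore* power-law draws at mean degree 10: the
  squared frequency weights `P(kᵢ)P(kⱼ)` reward the concentrated Poisson
  degree profile. The value-sum (Gini-like) reading restores the PL > ER
  ordering but provably *strictly decreases* under every admissible transfer
  (a Pigou–Dalton argument: the moved pair's term drops by 2 and each
  strictly-between value contributes another −2) and is replication
  invariant — erasing the violation signatures. The battery keeps the
  node-sum; the sweep-ordering test documents the HPED exception as an
  expected failure of the PL > ER pattern rather than hiding it.
* Compliance verdicts are battery-relative; a "pass" is falsifiable by
  enlarging the battery (the engine's monotonicity — enlarging can only
  flip pass to fail — is itself tested).
* The HS′ denominator above `n = 7` and the diverse-graph canon are
  search-based, not certified extremal.
* Degree-correlated rewiring, community-structured models, directed and
  weighted graphs are out of scope.
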