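# hetnet

**Graph and degree heterogeneity measures for simple undirected networks —
with the machinery to stress-test them.**

Network scientists describe degree-regular graphs as *homogeneous* and
hub-dominated (power-law) graphs as *heterogeneous*, but the literature
quantifies "heterogeneity" with more than a dozen non-equivalent indices.
Depending on the index chosen, the same pair of networks can rank in either
order. `hetnet` is for researchers in epidemiology, systems biology, ecology
and network science who need to *choose* a heterogeneity measure deliberately:
it implements the common measures under one framework, exposes the generic
classes they instantiate, and ships the experimental machinery to probe how
each measure behaves on random-graph models, extreme topologies, and
controlled network manipulations.

## The measure battery

All measures act on a simple undirected graph `G = (V, E)` with `n` nodes,
`m` edges, degrees `k_i`, mean degree `k̄`, maximum degree `kmax`, degree
distribution `P(k) = n_k / n` and adjacency spectral radius `ℵ₁`.

**Global dispersion aggregation** — `c · Σᵢ g(kᵢ − h(K))`:

| name | formula | notes |
|------|---------|-------|
| HHG | `Σᵢ (kmax − kᵢ)` | degree centralization |
| HF  | `HHG / ((n−1)(n−2))` | Freeman-normalized; = 1 exactly on stars |
| HS  | `n⁻¹ Σᵢ (kᵢ − k̄)²` | degree variance |
| HN  | `Σᵢ |kᵢ − k̄|` | absolute deviations |

**Adjacent pairwise dispersion** — `c · Σ_{{i,j}∈E} g(f(kᵢ) − f(kⱼ))`:
HA (Albertson irregularity, `Σ |kᵢ − kⱼ|` over edges) and HE (Estrada
heterogeneity with `f(k) = k^(−1/2)`, satisfying the Randić-index identity
`HE = n − 2R₋₁/₂`).

**Pairwise dispersion** — the same sums over all node pairs `i < j`:
HAp and HEp.

**Expected difference (Gini-type)** — HAED (expected degree difference across
a random *edge*, empirical edge-pair frequencies) and HPED (expected degree
difference across node pairs); HHW is the degree Gini coefficient
`(2k̄)⁻¹ · E|K − K′|` with uniform node weights, and the battery HPED uses
degree-frequency weights `P(kᵢ)P(kⱼ)` per node term with `c = 1/k̄`.

**Special measures** — HCS (Collatz–Sinogowitz spectral irregularity
`ℵ₁ − k̄`, connected graphs only) and HJ (degree diversity built from
`(1 − P(k))²` terms, maximal on "completely diverse" graphs where all but
one degree value is unique).

Every battery measure returns exactly 0 on regular graphs.

Beyond single values, the package answers behavioural questions through three
manipulation principles: does a measure *strictly decrease* when an edge is
rewired from a higher-degree to a lower-degree node (**transfer**)? Does it
avoid increasing when all degrees grow by the same constant (**addition**)?
Is it invariant under disjoint replication of the network (**replication**)?
The compliance engine answers with concrete counter-example witnesses.

## Worked example

```python
>>> import networkx as nx
>>> from hetnet import evaluate, BATTERY
>>> d4 = nx.Graph([(1, 2), (2, 3), (3, 4), (2, 4)])   # degrees (1, 3, 2, 2)
>>> for name in ("HS", "HN", "HA", "HE", "HAED", "HPED", "HCS"):
...     print(name, round(evaluate(name, d4).value, 4))
HS 0.5
HN 2.0
HA 4.0
HE 0.2123
HAED 1.5
HPED 0.625
HCS 0.1701
```

`HS = 0.5` is the variance of the degrees around their mean 2; `HA = 4` sums
the absolute degree differences across the four edges; `HE ≈ 0.2123` equals
`4 − 2R₋₁/₂` with Randić index `R₋₁/₂ ≈ 1.8938`; `HCS ≈ 0.1701` is the gap
between the spectral radius (≈ 2.1701) and the mean degree. Because this
little graph is *completely diverse* (degree multiset {1, 2, 2, 3} repeats
only one value), the normalized diversity measure is maximal:

```python
>>> from hetnet.measures import hj_normalized
>>> hj_normalized(d4)
1.0
```

Compliance checking, with a witness for a violation:

```python
>>> from hetnet.principles import check_transfer, default_battery
>>> verdict = check_transfer("HN", default_battery())
>>> verdict.passed, verdict.witness.before, verdict.witness.after
(False, 10.333333333333334, 10.333333333333334)
```

(HN fails the transfer principle: a rewiring that crosses the mean leaves the
absolute-deviation sum unchanged instead of strictly decreasing it.)

The same functionality is available from the shell:

```bash
hetnet gen --family powerlaw --n 10000 --gamma 2.2 --match-er-lambda 10 \
           --seed 7 --out g.edgelist
hetnet measure --graph g.edgelist --measures HS,HA,HE,HJ --out results.csv
hetnet principles --measures all --out matrix.json
hetnet sweep --scale desk --out sweep.csv
hetnet compare-extremes --out heatmap.csv
hetnet zero-suite
```

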