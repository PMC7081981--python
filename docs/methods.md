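# Methods

## Model

The pipeline treats one sample's transcriptome as a scalar field on a
protein-protein interaction network and extracts the proteins that are
both energetically and topologically load-bearing.

1. **Concentration.** Transcript abundance is used as a surrogate for
   protein concentration. Within each sample, values over the
   network-mapped genes are min-max rescaled to `c_i ∈ [0, 1]`. The
   rescaling is per sample across genes — each patient's landscape is
   computable alone, which is the point of a personalized analysis — with
   a `per_gene` (across-cohort) switch available for sensitivity checks.

2. **Gibbs free energy.** Each node gets
   `G_i = c_i ln(c_i / Σ_{j∈N(i)∪{i}} c_j)`, the sum running over the
   closed neighborhood (neighbors of `i` **plus `i` itself** — easy to get
   wrong, and the reason self-loops are dropped at parse time: a loop
   would count `i` twice). The natural logarithm is used, matching the
   standard statistical-thermodynamic form. Since
   `0 ≤ c_i ≤ Σ`, the log argument never exceeds 1 and `G_i ≤ 0`: every
   expressed protein sits in an energy well whose depth grows with its own
   concentration and with the total concentration of its neighborhood (a
   degree-entropy-like term — hub proteins with many expressed partners
   acquire deep wells).

3. **Filtration.** Nodes are sorted by energy ascending and the first `k`
   induce the sample's Gibbs-homology network (default `k = 32`). The
   threshold is a node *count*, not an energy value. The induced subgraph
   may be disconnected; `connected_only` optionally keeps the largest
   component (which can then hold fewer than k nodes).

4. **Betti centrality.** "Rings" are formalized as the first Betti number
   of the graph — the cycle rank `B(G) = |E| − |V| + C(G)` with `C` the
   component count; no clique-complex filling is performed (see
   Limitations). The centrality of `v` is `B(G) − B(G − {v})`, the rings
   destroyed by deleting `v` with its incident edges; it obeys the exact
   identity `B(v) = deg(v) − 1 + C(G) − C(G−v)`, which the tests use as an
   independent oracle. All nodes attaining the maximal value are reported
   as equivalent; ties are never broken.

5. **Cohort aggregation.** The Pareto table counts, per protein, the
   samples in which it belongs to the maximal-centrality set — the full
   equivalence set per patient, so the Pareto total exceeds the sample
   count exactly when ties occur. The presence table counts membership in
   the threshold-k node set. A disease gene list can be intersected with
   either the union of all captured nodes (default) or only the
   top-centrality proteins.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 32 | filtration threshold: nodes retained per sample |
| `dialect` | `plain2col` | edge-list format (`biogrid_tab` selects the two official-symbol columns by header) |
| `rescale` | `per_sample` | min-max scope (`per_gene` for sensitivity analysis) |
| `collapse` | `mean` | duplicate-probe collapse (`max` available) |
| `connected_only` | off | keep only the largest component of the induced subgraph |

All quantities are dimensionless; no temperature or physical units are
attached to `G_i`.

## Numerical conventions

- **Boundary cases of `G_i`:** `c_i = 0` gives `G_i = 0` (the `x ln x`
  limit), and an all-zero closed neighborhood gives `G_i = 0` (0/0 guard).
- **Constant sample:** a sample whose retained genes are all equal rescales
  to all-0.5 rather than dividing by zero; the landscape stays
  non-degenerate and the choice is covered by tests.
- **Ordering ties:** the energy sort is made fully deterministic by the
  key `(energy asc, degree desc, symbol asc)`. Degree-descending favors
  high-connectivity hubs, consistent with the role the degree-entropy term
  gives them; the final lexicographic key makes reruns byte-identical.
- **Intersection mapping:** genes absent from the network are dropped
  before rescaling (restrict, then rescale); network nodes without
  expression are removed from the working graph. Both counts are logged.
  Restricting first means the unit interval is spanned by the genes that
  actually sit on the network.
- **Input hygiene:** symbols are uppercased; self-loops and duplicate or
  reversed-duplicate edges collapse silently (counts logged); duplicate
  expression rows collapse by mean (or max); negative and non-numeric
  expression values are rejected with the offending row/column named.

## Synthetic data

The generator emulates the shape of a whole-blood expression cohort over
a curated interactome at desk scale: a degree-biased (preferential)
attachment network whose heavy-tailed degree distribution echoes real
interactome hubs with hundreds of partners; positive, heavy-tailed
(lognormal by default, optionally uniform) background expression;
X-prefixed decoy genes absent from the network so the intersection
mapping is exercised; and 291 samples by default, the size of the SLE
cohort that motivated the method, over 3000 nodes.

Its planted structure is a high-concentration clique because the energy
functional makes the analytics predictable: a clique of size m expressed
near the per-sample maximum gives each member
`G ≈ 1 · ln(1/m)` (for m = 10, about −2.30), far below the diffuse
background, so the k = m filtration should retrieve the clique and the
maximal-centrality set should fall inside it. One global seed threads
through network construction, planted-member selection and expression
draws; every stochastic claim in the tests states its seed.

What the generator does **not** emulate: platform-specific microarray
noise, batch effects, correlated co-expression modules beyond the planted
clique, or biologically structured network topology. Passing tests
therefore demonstrate the machinery is correct and the recovery guarantee
holds under the stated generative model — not that the pipeline's protein
rankings on any real cohort are biologically meaningful.

## Problem sizes

The verification suite uses random graphs up to 60 nodes (where the
closed-form centrality identity is checked exhaustively per node),
planted-recovery instances of 200 background nodes over seeds 0–9, and an
end-to-end determinism run of 20 samples over 300 nodes. The acceptance
script additionally runs a full 291-sample cohort over a 3000-node
network — the package's chosen desk-scale stand-in for a cohort-scale
analysis.

## Design choices where the design was open

- **Threshold semantics:** "threshold 32" is read as a node count, the
  only interpretation under which every sample yields a comparable-size
  subnetwork.
- **Disconnected subnetworks are kept by default**; connectivity is
  opt-in, since nothing in the method requires the k lowest-energy nodes
  to be mutually reachable.
- **Restrict-then-rescale** (rather than rescale-then-restrict) for the
  network/expression intersection, as argued above.
- **Pareto counts use full equivalence sets**, never an arbitrary winner.
- The `aggregate` and `overlap` CLI subcommands work from the `run.json`
  manifest a `run` leaves behind, so aggregation does not recompute
  energies.

## Limitations

- Cycle rank counts independent rings of the *graph*; a clique-complex
  (simplicial) homology would fill triangles and count differently. The
  ring notion here is deliberately the graph-theoretic one.
- Betti centrality is computed by node deletion per node, O(V·(V+E)) per
  subnetwork — trivial at k = 32 but not intended for whole-interactome
  centrality screens.
- Gene identity is the uppercased official symbol; no identifier mapping,
  isoform handling, or organism resolution is bundled.
- No expression preprocessing (background correction, quantile
  normalization) is performed; feed the pipeline whatever normalization
  your platform requires, as long as values are non-negative.
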