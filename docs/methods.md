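# Methods

## Model

`mpick` casts OTU inference as community detection. Reads are vertices of
an undirected weighted graph; an edge joins two reads exactly when their
pairwise distance d is strictly below the neighborhood radius ε, with
similarity weight w = 1 − d (so w ∈ (1 − ε, 1]). The quality of a partition
is the weighted modularity

    Q = (1/2m) Σ_ij [ w_ij − k_i k_j / 2m ] δ(C_i, C_j),

where m is the total edge weight, k_i the weighted degree, and the sum runs
over ordered vertex pairs with w_ii = 0. The null term k_i k_j / 2m is the
edge weight expected between i and j in a degree-preserving random graph;
Q therefore measures excess within-cluster weight over chance. Q ≤ 1, the
single-cluster partition scores exactly 0, and partitions of a homogeneous
graph score near 0. Internally Q is evaluated through the per-community
identity Q = Σ_c [S_in(c)/2m − (S_tot(c)/2m)²] (S_in twice the
intra-community weight, S_tot the summed degrees), which is O(edges); unit
tests pin its equality with the literal double loop to 1e-12.

The assumption that makes this model appropriate for amplicon data is
separability: within a taxon, neighbor distances are smaller than ε, so a
taxon forms a densely connected region, while between-taxon distances
exceed ε and contribute no edges. OTUs are then regions of homogeneous edge
density and need not be spherical in sequence space.

## Pipeline and stopping rule

1. Build the ε-graph from all pairwise distances (pairs with d ≥ ε may be
   absent from the input matrix entirely — sparse input is sufficient for
   any ε at or below the cut-off used to produce it).
2. Isolated vertices immediately become singleton OTUs: every input read
   appears in the output.
3. Each connected component is optimized independently. If the optimizer
   returns a single cluster, or the optimized partition's Q on that
   sub-graph is below δ (strict), the component is accepted as an OTU.
   Otherwise each sub-cluster, re-split into connected components (the
   optimizer can emit internally disconnected clusters, and components are
   independent under Q), is recursed with the same rule, each time
   measuring Q on the sub-graph's own edges and degrees.

The recursion serves two purposes: it counteracts the resolution limit of
a single global maximization (communities below a scale set by total graph
weight are invisible to one pass), and its δ test supplies the termination
criterion — the maximum modularity attainable on a graph is a homogeneity
score, near zero for graphs without community structure.

A depth cap of 50 exists purely as a safety valve and warns if reached.

## Optimizer

The classic two-phase greedy scheme: start from singletons; sweep vertices
in a seeded shuffled order, moving each to the neighboring community with
the largest modularity gain; when a full pass makes no move, aggregate
communities into super-vertices (intra-community weight becomes a
self-loop counting twice in the degree) and repeat. Determinism contract:
the sweep order is drawn from `numpy` Generator seeded with the run seed
(default 42), a move must improve Q by more than 1e-12, and ties between
candidate communities go to the smallest community id. The result is a
local maximum — no single-vertex move improves Q — and on well-separated
toy graphs (disjoint cliques joined by at most one edge) the suite checks
it attains the global maximum found by exhaustive enumeration of all set
partitions (provided for graphs of ≤ 12 vertices as a test oracle).

## Distances

Sequence mode is a Needleman–Wunsch global alignment with match +1,
mismatch −1, linear gap −2, and free terminal gaps; the distance is
(mismatched columns + internal gap columns) / (alignment columns excluding
terminal-gap columns), a fraction in [0, 1]. Ambiguity codes (N, R, Y, …)
never match anything, including themselves. Among co-optimal alignments
the traceback prefers diagonal, then vertical, then horizontal steps;
because that preference is not transpose-symmetric, each pair is aligned
in a canonical order (lexicographically smaller residue string first),
making d(a, b) = d(b, a) exact. The kernel is numba-compiled; all-pairs
distances for 1,100 reads of length 250 take on the order of a minute.

Two properties of the free-terminal-gap convention are worth knowing.
First, a sequence scores 0 against any of its prefixes (the overhang is
terminal). Second, for highly dissimilar pairs the best-scoring alignment
can be a short overlap, giving a distance far below the per-site
divergence; for same-length amplicon reads at realistic divergences the
near-diagonal alignment dominates and the distance behaves like a per-site
difference fraction. The convention is a documented stand-in for the
unpublished scoring of the alignment tools used historically for this
task; no bit-compatibility is claimed.

Point mode uses the Euclidean metric in any dimension. Because w = 1 − d
turns negative for d > 1, similarity weighting requires ε ≤ 1; a binary
weight mode (w = 1 on retained edges) is provided for larger radii.

## Parameters

- **ε (default 0.04, dimensionless distance fraction)** — should exceed
  the largest within-taxon neighbor distance but stay below between-taxon
  distances. 0.04 suits species-level 16S OTUs.
- **δ (default 0.1, dimensionless modularity)** — the homogeneity
  threshold; smaller values split more aggressively (below ~0.03 spurious
  small OTUs appear), larger values merge (above ~0.4 species begin to
  fuse). The `--sweep` CLI option maps the (ε, δ) sensitivity grid against
  ground-truth labels.
- **seed (default 42)** — affects only the optimizer's sweep order.
- **precluster level (optional, e.g. 0.01)** — greedy incremental
  preclustering processed in decreasing read-length order (ties by id);
  each read joins the first representative closer than the level, members
  inherit their representative's OTU. Reduces the quadratic alignment cost
  on large datasets.

## Synthetic data

`gen_taxa_sequences` draws one root sequence, derives one ancestor per
taxon by mutating the root (redrawing until every ancestor pair differs at
≥ min-divergence · length sites, default 0.10 · 250), then emits each read
as its ancestor with i.i.d. substitutions at the within-taxon rate
(default 0.01/site; per-taxon rates allowed). Defaults: 11 taxa × 100
reads — a desk-scale stand-in for the published simulated benchmark of
22,000 reads from 11 taxa, sized down so the full all-pairs alignment runs
in about a minute. What it does *not* emulate: indels, chimeras,
quality-dependent errors, unequal read lengths, and intra-taxon population
structure. Passing tests therefore demonstrate correct recovery under
clean separability, not robustness to real sequencing artifacts.

One quantitative consequence of the read model: a read with ~10 or more
substitutions (probability ≈ 5·10⁻⁴ per read at rate 0.01 and length 250)
is ≥ 0.04 away from every clean neighbor, becomes isolated in the ε-graph,
and — by the completeness rule — a singleton OTU. With 1,100 reads roughly
half of all seeds contain such an outlier, so exact recovery of the taxon
count holds for most but not all seeds, while NMI stays ≥ 0.998 in the
exceptions.

`gen_gaussian_points` samples a three-component 2-D Gaussian mixture
(x-means −0.5, 1, 3; per-component sd 0.2, 0.4, 0.6 on both axes; sizes
150/100/250 — unequal by design). The components overlap in their tails.
Recursive modularity clustering of such geometric clouds at ε = 0.6
over-splits them: a dense geometric random graph has internal maximum
modularity well above 0.1 even when the cloud is a single Gaussian, so the
sub-graph-frame δ test keeps splitting. Exact recovery of the three
components at this sample size is additionally precluded by the overlap
itself — essentially every draw contains boundary points whose ε-neighbors
are dominated by the adjacent component. The point mode is therefore a
qualitative illustration of the graph machinery; the acceptance check that
demands exact three-way recovery at ε = 0.6 documents this limitation by
failing, and the amplicon regime (near-complete within-taxon sub-graphs,
empty between-taxon cut) is the one the method is built for.

## Numerical choices and degenerate inputs

- Strict inequalities: d < ε for edge retention, Q < δ for stopping.
- Move acceptance tolerance 1e-12; brute-force ties resolved toward fewer
  clusters, then lexicographic block order.
- Edgeless graphs: modularity and the optimizer reject them; the driver
  never calls the optimizer on them (isolated vertices and edgeless
  components are handled upstream).
- NMI degeneracies: two zero-entropy labelings (both single-cluster, hence
  identical) score 1; exactly one zero-entropy side scores 0. Natural
  logarithms; arithmetic-mean normalization 2I/(H(X)+H(Y)), cross-checked
  against scikit-learn in the suite.
- OTU tables are byte-deterministic: OTUs numbered by decreasing size with
  ties broken by smallest member id; writers are atomic (temp file +
  rename), so failures leave no partial outputs.
- The replicate summary reports the sample standard deviation (n − 1); a
  single replicate reports 0 with a warning.

## Known limitations

- No automatic selection of ε or δ; defaults target species-level 16S.
- The alignment convention's short-overlap behavior on wildly dissimilar
  sequences (above).
- Geometric point clouds with smooth density gradients are over-split, as
  documented above.
- No chimera handling, taxonomy assignment, or indel-aware read
  simulation.
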