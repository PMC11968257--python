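# Methods

## The model

A *pathway space* is an undirected, unweighted gene-interaction graph
together with a fixed 2D embedding. The graph carries the biology (hop
counts between genes approximate functional distance through shared
pathways); the embedding carries only the visualization. The two are kept
strictly separate: the distance statistic and its null model depend on graph
topology alone, while the density landscapes depend on the layout alone.
Layouts are consumed as input (they normally ship with the reference graph)
and are normalized on load by an aspect-preserving affine map into the unit
square, which makes all projection radii scale-free; the package never
computes a layout for real data, though the synthetic generator embeds its
graphs with a seeded force-directed method for self-contained testing.

Graph hygiene at load: self-loops and duplicate edges are dropped with a
logged count (hop counts and degree-based hub ranking are otherwise
ambiguous), gene symbols are matched case-sensitively with no alias
resolution, and duplicate vertex names are fatal.

## The distance statistic and its null

For lists $L_1, L_2$, the directed statistic is the mean over $v \in L_1$
of the minimum hop count to any $w \in L_2$ ("average path distance to
first nearest neighbors"). The default direction is `from_to`
($L_1 \to L_2$); a `symmetric` variant averages the two directed values.
The packaged toy fixture was deliberately constructed so that both
directions give the same worked value (1.25), making the headline check
insensitive to the convention. Conventions for edge cases:

- a gene present in both lists contributes 0 (it is its own first nearest
  neighbor); consequently $\bar d = 0$ iff $L_1 \subseteq L_2$;
- genes whose minimum is infinite (separate connected component) are
  excluded from the average with a logged count; the statistic errors only
  if *every* term is infinite. Reference interactomes are effectively
  connected, but permutation replicates on sparse synthetic graphs must not
  return infinities;
- `k` is fixed at 1 neighbor.

The permutation null redraws both lists independently and uniformly without
replacement from all vertices — no degree matching (a degree-preserving
null is a natural extension hook, not the default). One seeded
`numpy` generator drives the whole loop, so the null sample is bitwise
reproducible from `(seed, nperm, sizes)`. The p-value uses the add-one
estimator $(1 + b)/(n_{\text{perm}} + 1)$, which is never 0 and bounded
below by $1/(n_{\text{perm}}+1)$; rejection is left-tail (small distance =
proximity). The z-score uses the null sample's mean and ddof-1 standard
deviation and is reported as NaN when the null is degenerate (zero spread);
the p-value remains valid there. Z-scores are the recommended scale when
comparing list pairs of different sizes, since larger lists are
mechanically closer in hop distance.

All-pairs hop distances are computed by per-source BFS (scipy's unweighted
shortest-path machinery) into a dense matrix; `shortest_paths_from`
computes selected rows only, for graphs where the dense $n \times n$ matrix
is unwanted. Distance matrices round-trip through named TSV so
user-supplied distances from other algorithms can be tested unchanged.

## Projection and silhouette

Per-vertex signal (1 on the list of interest, 0 elsewhere, assigned with
reset-on-write semantics so successive lists never accumulate) is
rasterized on an $R \times R$ grid over the unit square. Pixel $(i, j)$ has
center $((j+0.5)/R, (i+0.5)/R)$, row-major, origin at lower-left. Each
vertex spreads its signal with a kernel in the scaled distance
$u = \lVert p - xy(v) \rVert / (r_p \sqrt 2)$, where $r_p$ is the
projection radius as a fraction of the unit-square diagonal:
linear $K(u) = \max(0, 1-u)$ (default) or Gaussian $e^{-u^2/2}$ truncated
at $u = 3$. Contributions aggregate per pixel by elementwise max (default;
a dense cluster saturates rather than dominating the color scale) or by
capped sum; the grid is rescaled to $[0,1]$ by its maximum, so the result
is invariant to positive rescaling of the signal. The silhouette step masks
pixels farther than $r_s \sqrt 2$ (silhouette radius $r_s$, same diagonal
units) from every vertex, computed with a KD-tree; masked pixels are NaN.

Defaults: resolution 400, linear kernel, $r_p = 0.05$, $r_s = 0.03$, max
aggregation. These are visualization choices made for legibility on
interactome-scale layouts (about 13k vertices in the unit square); the
quantitative pipeline is entirely independent of them. Kernels decay with
*Euclidean layout* distance, not graph-geodesic distance — a possible
extension, but the landscape is by construction a picture of the layout.

## Synthetic data

The synthetic module defines the conditions under which the statistical
claims are tested, all as pure functions of their seeds:

- `toy_fig1`: an 11-vertex schematic with two 4-gene lists whose per-gene
  nearest-neighbor minima are (1, 1, 1, 2) in both directions, hence mean
  1.25. The encoding is data, verified by tests (including against a
  Floyd–Warshall oracle), not trusted.
- `random_space(n, m, seed)`: Barabási–Albert preferential attachment —
  connected, heavy-tailed degree distribution, the standard minimal model
  of interactome-like topology — with synthetic symbols `G0001…` (fixed
  zero-padding for deterministic tie-breaks) and a seeded spring layout.
  It does not mimic Pathway Commons' exact degree law, clustering, or
  pathway annotation structure, so passing tests demonstrate statistical
  correctness of the machinery, not biological calibration on real
  interactomes.
- `sample_lists`: `uniform` draws are the null model's own notion of a
  random list; `neighborhood` draws truncate a BFS ball around a center
  (random, or fixed via `center`) with seed-shuffled within-level order, so
  two draws around one center overlap without coinciding — the planted
  proximity used in power tests.

Test problem sizes: calibration uses a 200-vertex space, 500 repetitions of
20-vs-20 uniform lists at nperm = 199 (empirical type-I error within three
binomial standard errors of alpha = 0.05); power uses 100 seeds of
15-gene lists at nperm = 99. These sizes give stable verdicts in seconds;
the defaults for real analyses remain nperm = 10000.

## Design choices where the design was open

- **Direction default** `from_to`, matching the asymmetric from/to
  signature of `path_distance_test`; the symmetric variant is one flag
  away, and the toy fixture pins the worked value under both.
- **Hub ties** broken lexicographically by gene symbol — determinism over
  any claim about which tied hub matters more.
- **Overlap test** delegates to the exact hypergeometric survival function
  (strictly-greater tail, matching one-sided `phyper(..., lower.tail =
  FALSE)` semantics).
- **Rejection threshold** for plots is the type-7 (linear-interpolation)
  empirical quantile of the null — the common default across statistical
  environments, chosen for cross-implementation determinism.
- **Null KDE** in the distance plot uses Silverman's bandwidth over a
  histogram; purely cosmetic.
- **Empty intersections** of a gene list with the graph are errors rather
  than silently empty lists, because every downstream statistic is
  undefined on them.

## Limitations

- One list pair per test; all-pairs comparison across many lists is left to
  the caller (loop the CLI, or reuse one `DistanceMatrix`).
- Unweighted edges only; confidence- or weight-aware distances are out of
  scope.
- The uniform null ignores degree and spatial structure of the observed
  lists; for graphs very unlike a pruned interactome, the null's stability
  should be checked before trusting small p-values.
- Landscape pixel values are package-specific (kernel and radii choices);
  only the qualitative reading — high density where list genes concentrate
  — is claimed.
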