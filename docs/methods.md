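# Methods

## The in-memory model

Everything is a view of one structure: a `SetCollection` holds an ordered
tuple of set names and a map element → membership subset.  The derived
`RegionPartition` assigns each element to the exclusive region of its full
membership signature; regions are disjoint, counts conserve the element
total, and at most 2ⁿ−1 signatures exist.  Inclusive intersection sizes
are superset sums of exclusive counts.  Partitions can also be built
count-only from signature/count tables: exclusive tables verbatim,
inclusive tables via Möbius inversion N_S = Σ_{T⊇S} (−1)^{|T|−|S|} I_T.
Signatures missing from an inclusive table are treated as zero, and any
negative recovered region raises a semantics error naming the signature —
a consistency check, not a formatting one.  Count-table semantics default
to **exclusive** (the disjoint Venn-cell reading): when a table states a
single number per intersection *part*, the cell reading is the one that
makes all parts sum to the element total; an `inclusive` switch is
provided and documented wherever counts enter.

Signatures are canonicalized by sorting names in collection order and
joining with `&` (no spaces on output; input tolerates them).  Names are
case-sensitive and trimmed at both ends — biological IDs distinguish case,
and trimming guards against invisible whitespace without silently merging
distinct IDs.  Header handling is an explicit flag everywhere, never
sniffed.

## Synthetic collections

`generate_collection(n_sets, n_elements, core_fraction, unique_fraction,
seed)` emulates the membership structure typical of multi-condition
comparisons: a fraction of elements present in *every* set (the shared
core that flower plots foreground), a fraction of set-specific singletons,
and the remainder assigned a uniformly random non-empty subset.  Defaults
are core 0.25, unique 0.35, 200 elements: a visible core plus plenty of
singleton and mid-degree structure, so every region class is exercised.
What it deliberately does not emulate: correlated set sizes, nested
condition designs, or heavy-tailed abundance-driven membership.  Tests
passing on these collections certify the combinatorics and geometry, not
robustness to any particular biological sampling design — the calculus
itself is exact and distribution-free, so this limitation mostly concerns
how representative the rendered examples look.

## Euler layout

Radii: rᵢ = √(|Sᵢ|·a₀/π) with a₀ chosen so the largest circle has radius
exactly 1 (the proportionality constant is arbitrary; normalizing the
largest radius fixes the scale).  Two sets are exact: the lens area of two
circles has the standard two-segment closed form, is monotone
non-increasing in center distance on [|r₁−r₂|, r₁+r₂], and is inverted by
bisection to tolerance 10⁻¹² (200-iteration cap).  Zero overlap adds a
0.1·r_min separation margin so disjointness is visible; full containment
pulls the small circle 0.05·r_min inside.

Three sets: pairwise distances are solved as above and give a triangle
initialization (law of cosines, clamped when the triangle inequality
fails); centers are then refined by Nelder–Mead over (x₂, x₃, y₃) with
circle 1 pinned at the origin and circle 2 on the x-axis, minimizing
stress = Σ_regions (achieved − target)², targets being region counts × a₀.
Achieved areas come from a Halton quasi-random sampling oracle (scrambled,
seed-determined; 20 000 points inside the optimizer, 200 000 for the
reported final areas — quasi-random error decays ~(log N)²/N, comfortably
inside the 0.5 % contract at 2·10⁵).  The recorded stress history is the
best-so-far value per iteration, hence non-increasing by construction;
layouts are bit-reproducible for a fixed seed.  Area specifications no
disk arrangement can realize (they exist for three sets) are drawn at the
stress minimum with a warning — practitioners expect a best-effort diagram,
not an error.

## Venn templates

Templates are shape lists with vectorized point-membership tests; all
region geometry (cell existence, label anchors) comes from grid sampling
the canvas, default 500×500.  Label anchors are cell centroids, snapped to
the cell's deepest sampled pixel (Euclidean distance transform) when the
centroid of a non-convex cell falls outside it.  A cell with no sampled
pixel raises a resolution error.

Classic mode: two unit circles at distance 1; three at pairwise distance
1; four and five use the well-known congruent-ellipse arrangements
(four ellipses at ±40°, five in 72°-step rotations), constants frozen
after grid verification that all 15/31 cells exist with comfortable
margins.  For six sets no arrangement of convex shapes can realize all 63
cells: two convex boundaries built from k line segments cross at most 2k
times (6 for triangle pairs), so a sixth convex curve crosses the other
five at most ~30 times, while it must enter all 32 faces of the five-set
diagram.  The six-triangle layouts circulating in web tools realize only
35 regions.  Classic-6 therefore uses a circle-based weave: two large
circles (radius 40) whose near-straight arcs split the plane like the two
Edwards half-planes, a central unit circle, and three serpentine curves
r = 1 + a·cos(fθ) with (f, a) = (2, 0.40), (4, 0.20), (8, 0.10) — grid
verified to realize all 63 cells, smallest cell ≈ 94 pixels at 500×500.

Edwards mode is the textbook construction for every n: upper and right
half-planes (clipped to the canvas for rendering), the unit circle, then
the same serpentine family.  The doubling frequency guarantees every sign
pattern of (cos 2θ, cos 4θ, cos 8θ) occurs inside each quadrant, which is
what makes all cells non-empty for any amplitudes in (0, 1); the chosen
amplitudes keep cells fat enough for coarse grids.

Scene labels are *exactly* the partition's exclusive counts (zeros shown);
the scene layer never recomputes set logic, which is what makes the
classic/Edwards label multisets provably identical.

## UpSet, flower, network

UpSet columns are the exclusive regions, sorted count-descending with ties
broken degree-ascending then lexicographically (common UpSet practice;
a `degree` sort is available).  Keeping empty intersections enumerates all
2ⁿ−1 signatures and is capped at n = 12; without it, columns are bounded
by the element count and 40 sets are supported.  Bars are linear in
counts; each column draws one filled dot per member set joined by k−1
segments.

Flower plots use `flower_decomposition`: core = |∩ all sets|, unique(i) =
exclusive singleton count, residual(i) = |Sᵢ| − core (so residual + core
conserves the set size).  Petal k sits at angle 2πk/n on a unit orbit;
petal semi-axes and label sizes scale as 1/√n, which keeps tip labels
non-overlapping up to at least 70 petals (asserted geometrically in the
tests).  Tip labels rotate with the petal axis and flip upright on the
left half.

The network is the bipartite membership graph: element degree equals
membership multiplicity, so degree-n nodes are the core and degree-1 nodes
the set-specific elements; `flower_like` filtering keeps exactly those two
classes.  Layout is seeded Fruchterman–Reingold per connected component
with deterministic left-to-right component packing and tie-nudging of
coincident coordinates — the browser-style physics this replaces is
interactive cosmetics, so only determinism and same-membership clustering
are contracted.  Exports are GraphML and a JSON node/link document, both
carrying node type, color and coordinates.

## Overlap significance

The overlap statistic is the one-sided hypergeometric enrichment test
(Fisher's exact upper tail), the field-standard test for gene-list
overlap: p = P(X ≥ k), X ~ Hypergeom(N, |A|, |B|), evaluated via scipy's
survival function (log-space internally, safe at genome scale), plus the
null expectation |A||B|/N.  The universe N is a required explicit input:
inferring it from the observed union would systematically inflate
significance.  The method name is embedded in the output metadata.

## Numerical and interface choices

* CSV output is strict RFC 4180 (comma, CRLF, UTF-8), one column per
  non-empty region, columns ordered degree-then-set-order, elements
  lexicographic.  Run metadata (tool version, seed, input SHA-256 digest)
  lives in the JSON summary and the SVG `<metadata>` element; CSVs stay
  comment-free by design.
* SVG maps the scene bounding box onto a 600-unit viewBox with the y-axis
  flipped (SVG y points down); identical inputs and flags produce
  byte-identical artifacts.
* Color lists shorter than the set count are stretched by linear RGB
  interpolation at evenly spaced positions, rounding half up per channel,
  endpoints preserved; a single color repeats.  RGB is used because no
  perceptual space is implied by the interpolation contract.
* Exit codes: 0 success, 2 input format/semantics error, 3 capacity
  error (set counts outside a diagram's range), 64 usage error.

## Problem sizes

The default test suite verifies the region calculus against a brute-force
set-algebra oracle on 1000 seeded random collections (≤ 6 sets, ≤ 500
elements), Möbius round-trips on 300 tables, all ten templates at the full
500×500 grid, and hypergeometric tails against direct pmf enumeration for
universes up to 200.  `scripts/acceptance.py` re-runs the same checks at
200/100/20-trial scale plus the worked-case pipelines; both finish in well
under a minute on a single CPU.

## Known limitations

Euler layouts are circles-only and 2–3 sets; 3-set stress minimization is
local (triangle init is good in practice but global optimality is not
claimed).  Venn templates are fixed arrangements — region *positions* do
not adapt to counts.  Label collision avoidance is geometric scaling, not
constraint solving.  The worked-case scenarios whose element-level source
tables are not bundled are exercised through the count-matrix dialect or
synthesized memberships instead (marked as such in the tests); the
underlying set calculus is covered exhaustively by the brute-force
suites.
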