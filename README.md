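# vennkit

Offline set-relationship visualization for omics-scale list comparisons.

Comparing lists — differential metabolites across tissues, ChIP-seq target
genes across regulators, OTUs/ASVs across microbiome samples — is a set
problem: which elements are unique to one condition, which are shared by a
pair, which form the common core?  `vennkit` parses set-membership data in
the standard text dialects, computes the exact exclusive-region partition
for any number of sets, and renders it as classic or Edwards Venn diagrams
(2–6 sets), area-proportional Euler diagrams (2–3 sets), UpSet plots (3–40
sets), flower plots (3 to ~70 sets) and bipartite set–element networks —
all as renderer-agnostic scenes exportable to SVG, with per-region element
lists as CSV and a hypergeometric overlap-significance test.

## The core calculus

For sets S₁…Sₙ over element universe E, each element e belongs to exactly
one **exclusive region**, labelled by its membership signature
sig(e) = {i : e ∈ Sᵢ}, written `A&B&…` in set order.  There are 2ⁿ−1
possible regions, they are pairwise disjoint, and their counts sum to |E|.
**Inclusive** intersection sizes follow by summation over superset
signatures, |∩ₛSᵢ| = Σ_{T⊇S} N_T, and conversely count tables given
inclusively are converted to region counts by Möbius inversion
(inclusion–exclusion) over the subset lattice, with negative recovered
counts flagged as inconsistent input.

On top of the calculus:

* **Euler layout** — circle areas ∝ set sizes, overlap areas ∝ shared
  counts.  The two-circle lens area has a closed form; the center distance
  realizing a target overlap is solved by bisection (the lens area is
  monotone in distance), so 2-set layouts are exact.  Three-set layouts
  minimize the stress Σ(achieved − target)² over center positions with a
  deterministic Nelder–Mead search; achieved areas come from a seeded
  Halton-sampling oracle.
* **Venn templates** — fixed shape arrangements realizing all 2ⁿ−1 region
  cells, verified by grid sampling: circles (2–3), congruent ellipses
  (4–5), a circle-based weave (6), and the Edwards construction
  (half-planes + circle + serpentine curves) for every n up to 6.
* **Overlap significance** — one-sided hypergeometric (Fisher's exact
  upper tail): p = P(X ≥ k) for X ~ Hypergeom(N, |A|, |B|), with the null
  expectation |A||B|/N.

## Worked example

A three-tissue metabolite comparison in the two-column dialect
(TAB-separated, element then set, header line):

```text
id	set
m01	FS1
m02	FS1
m03	FS1
m01	FS2
m03	FS2
m04	FS2
m01	FS3
m05	FS3
```

```bash
vennkit calc -i demo.tsv --header -o demo
```

writes `demo.json`:

```json
{
  "tool": "vennkit",
  "version": "0.1.0",
  "seed": 0,
  "input_digest": "7fe6c71e69a98f37",
  "set_names": ["FS1", "FS2", "FS3"],
  "region_counts": {"FS1&FS2&FS3": 1, "FS1": 1, "FS1&FS2": 1, "FS2": 1, "FS3": 1},
  "exclusive": {"FS1": 1, "FS2": 1, "FS3": 1, "FS1&FS2": 1, "FS1&FS3": 0,
                "FS2&FS3": 0, "FS1&FS2&FS3": 1},
  "inclusive": {"FS1": 3, "FS2": 3, "FS3": 2, "FS1&FS2": 2, "FS1&FS3": 1,
                "FS2&FS3": 1, "FS1&FS2&FS3": 1}
}
```

Reading: m01 sits in all three tissues (the `FS1&FS2&FS3` core), m03 is
shared by FS1 and FS2 only, and each tissue keeps one unique metabolite.
Exclusive counts are the disjoint Venn-cell counts; inclusive counts are
the familiar intersection sizes (|FS1∩FS2| = 2 because m01 and m03 are in
both).  `demo.csv` lists the member elements per region, one column per
signature:

```text
FS1,FS2,FS3,FS1&FS2,FS1&FS2&FS3
m02,m04,m05,m03,m01
```

`vennkit venn --mode edwards`, `vennkit euler`, `vennkit upset`,
`vennkit flower` and `vennkit network` render the same partition as SVG;
`vennkit estimate` tests an overlap:

```bash
vennkit estimate --size-a 5 --size-b 5 --overlap 5 --universe 10 -o est
```

```json
{"method": "hypergeometric-upper-tail", "p_value": 0.003968253968253969,
 "expected_overlap": 2.5}
```

— two 5-element sets drawn from a 10-element universe coincide completely
with probability 1/C(10,5) = 1/252 ≈ 0.00397.

Count-matrix input (signature TAB count, `--dialect counts`) is accepted
everywhere a partition suffices, with `--semantics inclusive` triggering
the Möbius inversion.

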