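# Methods

## The segmentation model

`segont` performs seeded binary segmentation by interactive graph cuts.
The user (or a script) marks some pixels as foreground and some as
background; every other pixel is free.  A labeling `A` assigns each pixel
`p` a label `A_p ∈ {fg, bg}` and is scored by the energy

```
E(A) = λ · Σ_p R_p(A_p)  +  Σ_{(p,q) ∈ N} w_pq · [A_p ≠ A_q]
```

* **Regional term.** `R_p(fg) = −ln h_fg(I_p)` and `R_p(bg) = −ln h_bg(I_p)`,
  where `h_fg`, `h_bg` are intensity histograms built from the seed pixels
  of each class.  Grayscale images use `hist_bins` bins on [0, 1]; RGB
  images use joint bins (`hist_bins³` cells).  Histograms are floored by
  mixing with the uniform distribution at total weight
  `epsilon_prob · n_cells`, which keeps every cell ≥ `epsilon_prob` while
  the distribution still sums to 1 exactly (a plain max-then-renormalize
  would leave floored cells slightly below the floor).

* **Boundary term.** For neighbors `p, q` at Euclidean pixel distance
  `dist`, `w_pq = exp(−‖I_p − I_q‖² / 2σ²) / dist`.  Equal neighbors at unit
  distance get weight 1; the weight decays with contrast on the scale σ and
  with distance (diagonal neighbors are discounted by 1/√2).  RGB contrast
  is the Euclidean distance in RGB space.

* **Hard constraints.** Seeded pixels are pinned: the energy is minimized
  only over labelings that agree with every seed.

The minimizer is found exactly as a minimum s-t cut on a pixel graph:
n-links between neighbors carry `w_pq`, t-links carry the regional costs,
and each seeded pixel's own-terminal t-link gets capacity
`K = 1 + max_p Σ_q w_pq`, which no minimum cut can afford to sever — so the
hard constraints are satisfied by construction, not by post-processing.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `lambda_regional` | 1.0 | weight of the regional term; 0 = purely contrast-driven |
| `sigma` | 0.1 | boundary contrast scale, in [0, 1] intensity units |
| `hist_bins` | 16 (gray) / 8 (RGB, joint) | histogram resolution per channel |
| `neighborhood` | 8 | 4- or 8-connectivity of the pixel lattice |
| `epsilon_prob` | 1e-4 | histogram floor; keeps `−ln` finite |

These are common practice for this family of energies; all are exposed in
`EnergyParams`, in the CLI flags, and in the key=value config file.  σ can
optionally be estimated from the image as the root-mean-square neighbor
contrast (`estimate_sigma`, CLI `--auto-sigma`); the fixed default is used
otherwise, because reproducibility is preferred over adaptivity.

### Numerical choices

The max-flow problem is solved with networkx's shortest-augmenting-path
algorithm on **integer** capacities: float capacities are scaled by 2⁴⁴ and
rounded.  Exact integer arithmetic matters here — with float capacities,
saturated edges retain residuals of order 1e-16, and the reachability pass
that extracts the cut partition can then walk through them and return an
arbitrarily bad (even constraint-violating) labeling.  The quantization
error is ~3e-14 per edge, orders of magnitude below any energy difference
the tests resolve; the brute-force comparison tolerance is 1e-8.  The graph
is built in a fixed order and the solver is deterministic, so identical
inputs always produce identical masks.  Ties between distinct minimum cuts
are resolved arbitrarily but deterministically; tests therefore compare
energies, not pixel sets, wherever ties are possible.

Degenerate inputs: a seed class with no pixels is an error naming the
missing class; a scribble that relabels a pixel with the opposite class is
an error identifying the pixel (seeds merge monotonically; clearing is
explicit).  Coordinates are 0-based (row, col) everywhere inside the
library; conversion happens only at I/O boundaries (SVG uses x=col, y=row).

## Segment layers and boundaries

Forming a segment freezes the current mask as an immutable layer with the
next consecutive id and a preset color — a fixed 12-color
maximally-distinct cycle indexed by `(id − 1) mod 12`, making color a pure
function of the id.  Deleting a layer renumbers the remainder consecutively
and re-derives their colors.  One ontology term per segment (last write
wins), one taxon per document.  Overlapping layers are allowed and stored
verbatim.

Boundaries are traced as crack-edge loops on the pixel-corner grid
(foreground kept to the right of the travel direction; at corners where two
loops touch diagonally the tracer takes the sharpest right turn, keeping
them separate).  Holes become additional loops.  Filling uses even-odd
parity of vertical edges per pixel row, which inverts the tracing exactly —
`fill(trace(mask)) == mask` for every mask, which is asserted
property-style in the tests and again on archive validation.

## Persistence

See `FORMAT.md` for the byte-level archive specification.  Design points:
the original image bytes are stored verbatim (decoding is lossy for JPEG;
re-encoding would break round-trips); masks are stored redundantly (1-bit
PNG + row-major RLE text + boundary polygons in XML) and all three must
agree; entry order and timestamps are fixed so identical documents produce
byte-identical archives.  No wall-clock data is written anywhere — this is
what makes serialization reproducible.  The reader rejects unknown newer
format versions explicitly.

## Ontology and taxon providers

Term lookup and autocomplete run against a small provider interface.  Two
implementations ship: an OBO flat-file reader (obonet-backed; obsolete
terms excluded) and a recorded-JSON provider that mimics a lightweight term
web service.  The provider contract is tested identically against both.
The autocomplete ranking — case-insensitive prefix match on name or
synonym, ordered by (name length, name), exact name match first — is this
package's own choice.  Taxon lookup is a case-insensitive substring search
over a plain-text name list.  No code path performs network I/O; live
service adapters would slot into the same interfaces but are deliberately
not shipped (the historical name-resolution services this workflow used are
no longer reliable).

The packaged mini Plant Ontology subset (24 terms: the floral organs
perianth, tepal, anther, stamen, carpel, plant ovary, style, etc., plus
vegetative anatomy) is a synthetic fixture with paraphrased definitions,
not an official ontology release; real OBO files load through the same
reader.

## Synthetic scenes and what the tests show

The fixture generator renders organic shapes — ellipses, lobed blobs
(sinusoidally perturbed radii), curvilinear bands (thickened polylines) —
over a uniform background, records ground truth, then adds clipped Gaussian
pixel noise.  Scenes are pure functions of their seeds.  Scribbles are
sampled inside the eroded target region and outside its dilation, so they
are label-correct by construction, emulating a careful human mark-up.

The canonical recovery conditions are a region/background intensity gap of
0.8 with noise sd 0.02 on 64×64 canvases; the recovery criterion is a
median Jaccard ≥ 0.95 over 20 seeded scenes, and the scripted five-organ
replay runs on a 72×72 five-region scene.  Brute-force optimality checks
enumerate all labelings on images ≤ 4×4 (100 random instances with random
parameters).  These sizes keep the full suite around a minute; the method
itself has no size-specific logic.

What passing these tests does **not** show: performance on real
photographs, where foreground/background intensity distributions overlap,
illumination varies, and boundaries are soft.  The synthetic scenes have
piecewise-constant albedo and i.i.d. noise — the regime where a
histogram+contrast energy is near-ideal.  Real-image quality depends on
seed placement and parameter tuning in exactly the ways the interactive
workflow is designed to absorb.

## Known limitations

* Binary labels only; multiple structures are layered as successive binary
  segmentations (by design, matching the original workflow).
* The shortest-augmenting-path solver is pure Python; large images (beyond
  a few hundred pixels on a side) get slow.  The architecture isolates the
  solver behind one function if a faster backend is ever wanted.
* No undo/redo; deletion renumbers ids, so external references to segment
  ids are stable only within one editing pass.
* The archive schema is this package's own; reading archives written by
  other tools is out of scope.
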