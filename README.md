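# epitile

Linear-epitope mapping for tiled peptide-microarray serology of homologous
allergen families.

## The problem

High-content peptide microarrays print **every possible linear k-mer**
(by default every 16-mer, adjacent peptides overlapping by 15 residues) of a
panel of allergen isoforms — for example the 21 catalogued fish
β-parvalbumin isoallergens/isoforms — and measure serum IgG/IgG4/IgE
binding to each spot across subjects and longitudinal samplings.  Turning
that readout into biology requires several deconvolution steps that this
package implements as a tested, reusable pipeline:

* **Tiling and indexing** — exhaustive offset-1 tiling of each complete
  isoform, with identical peptides from different isoforms collapsed into a
  unique-peptide index that remembers every occurrence, and peptide starts
  mapped into master-alignment coordinates so homologous peptides share a
  position number.
* **Reactive-peptide calling** — per-sample robust z-scores
  `z = (log2 I − median) / (1.4826·MAD)`; a peptide is *reactive* at
  `z ≥ 3` and *confirmed* only when corroborated the way true antibody
  binding behaves on a tiled array: the same peptide reactive at a second
  timepoint, an overlapping peptide reactive in the same sample, or a
  homologous peptide (same aligned start, different isoform) reactive in
  the same sample.  An isolated bright spot is flagged as an artifact
  candidate.
* **Minimal-epitope deconvolution** — a contiguous run of *n* reactive tile
  starts narrows the epitope to the residues covered by **all** tiles of
  the run: length `k − (n − 1)`.  A single reactive tile leaves the full
  16-mer as the minimal epitope.
* **Residue attribution** — peptides of different isoforms at one aligned
  start differ only at the family's variable columns; partitioning
  isoforms by residue and contrasting mean log2 signal ranks candidate key
  residues for epitope recognition.
* **Longitudinal analysis** — within- vs between-subject profile
  correlations, and detection of *induced* reactivities: windows below
  `z = 1` at every earlier sampling that reach `z ≥ 3` later with a
  ≥ 2 log2-unit rise.
* **Profile similarity** — sample-level PCA over the unique-peptide set,
  allergen-level PCA over a fixed alignment window, and
  samples-only hierarchical clustering (euclidean/complete) for heatmaps.
* **Synthetic serology generator** — a fully seeded simulator of the whole
  study (mutated isoform family, per-subject epitope repertoires,
  key-residue-gated cross-reactivity, induction events, log-normal array
  noise) with planted ground truth and recovery scoring, so every stage is
  testable end to end.

A Kolaskar–Tongaonkar antigenic-propensity module is included for
sequence-based prediction of candidate linear B-cell epitopes.

## Worked example

```python
from epitile import (simulate_cohort, robust_z, call_reactive, call_segments,
                     stability_correlation, detect_induced)

panel, alignment, tiles, truth, matrix = simulate_cohort(seed=11, n_subjects=4)
z = robust_z(matrix)
calls = call_reactive(z, tiles, z_cut=3.0)
segments = call_segments(calls, tiles, panel)
print(f"{len(tiles)} tiles, {matrix.log2.shape[1]} unique peptides, "
      f"{matrix.log2.shape[0]} samples")
print(f"{len(calls)} reactive calls, {int(calls.confirmed.sum())} confirmed")

seg = segments[0]
print(f"example segment: {seg.allergen_id} subject {seg.subject} "
      f"tiles {seg.starts_local[0]}-{seg.starts_local[-1]} "
      f"minimal epitope {seg.minimal_epitope} at {seg.minimal_span_local}")

summary = stability_correlation(matrix)
print(f"mean within-subject r = {summary.mean_within:.2f}, "
      f"between-subject r = {summary.mean_between:.2f}")

induced = detect_induced(z, matrix.log2, tiles, calls=calls)
ev = induced.iloc[0]
print(f"{len(induced)} induced events, e.g. {ev.subject} window {ev.window} "
      f"first seen at timepoint {ev.induced_timepoint}")
```

prints

```
1786 tiles, 1116 unique peptides, 16 samples
3192 reactive calls, 3191 confirmed
example segment: syn 1.0001 subject D01 tiles 47-54 minimal epitope FNTVVYDSL at (54, 62)
mean within-subject r = 0.76, between-subject r = 0.07
53 induced events, e.g. D01 window [14, 36] first seen at timepoint 3
```

Reading this: 19 simulated ~109-residue isoforms tile into 1786 peptides
(1116 unique across the family); subject D01's run of 8 overlapping
reactive tiles (starts 47–54) pins one epitope down to the 9-residue
minimal epitope `FNTVVYDSL` (residues 54–62); repertoires are far more
similar within a subject over time (r ≈ 0.76) than between subjects
(r ≈ 0.07); and one planted specificity is correctly reported as induced
at the third sampling.  Induced events are reported per isoform, so one
cross-reactive induction appears once per isoform carrying the window.

A `epitile` console command exposes the same pipeline as subcommands
(`simulate`, `tile`, `call`, `epitopes`, `residue-assoc`, `longitudinal`,
`profiles`, `evaluate`); run `epitile --help`.

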