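# Methods

This note documents the models, conventions and numerical choices behind
`epitile`, and what the synthetic benchmarks do and do not establish.

## Tiling model and coordinates

A panel is tiled exhaustively: every complete isoform of length L yields
L − k + 1 peptides of length k (defaults k = 16, offset 1), adjacent
peptides sharing k − 1 residues.  Allergen-local positions are 1-based and
inclusive: a tile starting at s covers residues [s, s + k − 1].  Records
flagged incomplete (undefined residues in the source database) are carried
in the panel but never tiled — a partial sequence cannot be tiled
faithfully, and silently tiling the defined prefix would misnumber every
downstream coordinate.

Whether a stored sequence begins with the initiator methionine is a
per-record metadata flag, not string surgery: the stored sequence is
exactly what is tiled.  Isoforms lacking the initiator Met begin their
alignment row with a gap, so alignment-coordinate numbering stays
consistent across the family.

The master alignment is an *input* (gapped FASTA), not computed:
published family numberings are curated objects, and the pipeline's job is
to consume one consistently.  `local_to_aligned`/`aligned_to_local` are
exact inverses on non-gap columns.  Column diversity is computed among
non-gap entries only; a column is "diverse" when the most prominent
residue falls strictly below the threshold (default 0.5), ties broken
alphabetically.

## Reactivity calling

Raw fluorescence is floored at 1 unit (log-domain safety; negligible at
array scale) and log2-transformed.  Within each sample
(subject × timepoint × isotype) the robust z-score is

    z = (log2 I − median) / (1.4826 · MAD)

which cancels scanner gain and per-sample background; the 1.4826 factor
makes the scaled MAD estimate the s.d. of a normal background.  A zero MAD
is refused (degenerate input) rather than patched.

No universal numeric threshold for "reactive" exists for this platform, so
the cut-off is expressed on the robust z scale with `z_cut = 3.0` by
default, and every threshold is a config parameter.  Confirmation encodes
how genuine antibody binding manifests on an offset-1 tiled array of a
homologous family:

* `consecutive_sample` — the same peptide reactive in ≥ 2 samplings of the
  same subject and isotype.  "Consecutive" is interpreted loosely (any two
  timepoints) by default; a strict-adjacency flag is available.
* `overlapping_peptide` — a second reactive peptide in the same sample
  whose tile overlaps by ≥ `overlap_min` residues (default 8, half a tile)
  on the same isoform.
* `homologous_peptide` — a *different* reactive peptide at the same aligned
  start on another isoform in the same sample.  A peptide shared verbatim
  by two isoforms is one physical spot and is not counted as independent
  support.

Reactive peptides with no support are reported as artifact candidates, the
single-spot situation that longitudinal and cross-isoform context is
designed to filter.

## Minimal epitopes

For a contiguous run of n reactive starts, the minimal epitope is the
intersection of covered positions, [last_start, first_start + k − 1],
hence length k − (n − 1); the union (span) is reported alongside.
Intersection is the standard deconvolution convention for offset-1 tiling:
every reactive tile must contain the epitope, so the epitope lies in their
common residues.  Runs longer than k admit no common residue and are split
into maximal sub-runs.  A gap-tolerance option (default 0) lets a run
absorb single failed spots.

## Residue attribution

For the tiles of all isoforms at one aligned start, isoforms with
identical peptides collapse into one representative.  For each in-window
alignment column with at least two residue classes of ≥ `min_class`
(default 2) isoforms each, the effect of residue *a* is
mean(log2 signal | a) − mean(log2 signal | not a).  Columns are ranked by
|effect| and flagged at ≥ `effect_cut` (default 2 log2 units).  With at
most ~19 isoforms the class sizes are tiny, so this is deliberately a
ranking by effect size, not a formal test with p-values.

## Induced reactivities

An induction event requires true baseline silence — every earlier observed
timepoint below `z_low = 1.0` — followed by a sampling at `z ≥ z_cut` with
a log2 rise ≥ `fold_min = 2.0` over the mean baseline.  A rise from an
already-elevated baseline is deliberately not an induction.  Missing
samplings are simply not observed (never imputed).  By default the induced
call must also be *confirmed* (support tags are carried onto the event),
which is what keeps cohort-level false events near zero.  Induced peptides
are expanded to their isoform occurrences and merged into aligned-start
windows (merge gap k − 1: overlapping tiles), one event row per isoform
carrying the window.

## Profile similarity

Stability is summarised as Pearson r between log2 profiles over shared
measured peptides, pairs split within/between subject, isotypes never
mixed.  PCA is an SVD of the column-centered matrix; explained fractions
are normalised squared singular values, and signs are fixed (largest
loading per component positive) so results are deterministic.  The
allergen-level view uses tiles starting in a fixed alignment window
(default columns 9–95) as features; columns with any missing cell (gap
isoforms) are dropped entirely — the simplest rule that keeps every
isoform comparable over identical features.  Heatmap preparation clusters
rows (samples) only, with pheatmap-style defaults (euclidean distance,
complete linkage); peptide columns stay in linear tiling order so epitope
positions remain readable.

## Antigenic-propensity prediction

The Kolaskar–Tongaonkar per-residue propensity scale is embedded verbatim
from the original publication (see `antigenicity.py`).  Windowed means
(default window 7) are defined only for residues with a full centered
window.  The segment threshold follows the common web-tool convention —
the mean of the defined windowed values for the protein at hand — with the
run-length filter defaulting to 6 residues; the original method's window,
threshold and minimum length are not uniquely fixed in the literature, so
all three are exposed as parameters.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the structure of a longitudinal tiled-array serology
study at its default scale: a family of 19 isoforms of a 109-residue
protein derived from one random base sequence by independent per-site
substitution (rate 0.05); 15 subjects, each with 3 epitope windows of
width 9, sampled at 4 timepoints; effect sizes of 3 log2 units over
additive N(0, 0.5) log2 noise (i.e. multiplicative log-normal array
noise) on a baseline of log2 intensity 7; a quarter of epitopes induced at
a random sampling ≥ 2; and ~30 % of epitopes gated by a key residue —
only isoforms carrying the family-consensus residue at one variable
in-window column present the epitope, the mechanism behind
isoform-differential recognition.  Epitope windows within a subject are
separated so no tile spans two windows.  Everything is driven by
`numpy.random.default_rng` with explicit seeds; reruns are byte-identical.

Deliberate simplifications: families are gap-free (aligned = local
coordinates; the demo panel, not the generator, exercises gap handling);
effects are log-additive with a single affinity per epitope rather than a
binding isotherm; noise is i.i.d. (no spatial array artifacts, no
print-batch effects); isotype layers share windows and differ only by a
multiplier; no missing samplings by default (the API accepts an explicit
missing set).  Passing the recovery benchmarks therefore shows the
*deconvolution logic* is correct at realistic signal-to-noise, not that
the thresholds are optimal for any particular scanner or cohort.

A known edge case, visible in the benchmarks at roughly one event per
cohort: a non-carrier isoform's peptide lying at a genuine epitope
position can cross the reactivity cut by noise and then inherits
`homologous_peptide` confirmation from its genuinely reactive homologs; if
its own baseline happened to be quiet it is reported as an induced event.
This is the expected price of the homology-support rule, which otherwise
provides most of the artifact suppression.

## Problem sizes

Tests and the acceptance script run the generator at the default study
scale above (60 samples × ~1100 unique peptides; a few seconds end to
end), with smaller seeded instances (6–8 isoforms, 48–80 residues) for
unit-level oracle comparisons and brute-force cross-checks.

## Demonstration panel

`epitile.demo` ships a 21-record panel using the real catalogue's isoform
names, species and completeness flags, but **synthetic stand-in
sequences**: a designed 109-residue base with hand-placed variants that
reproduce the family's qualitative landmarks (a shared D-helix 16-mer at
aligned start 59 with variable column 71, a loop 9-mer unique to one cod
isoform, a missing initiator Met in Gad c 1.0101, truncated/incomplete
rainbow-trout records).  It exists so coordinate arithmetic, uniqueness
queries and gap handling can be tested against a fixed, human-readable
family; it carries no measured sequence or intensity data.
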