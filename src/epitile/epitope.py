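"""Epitope deconvolution from runs of reactive tiles.

On an offset-1 tiled array an antibody binding a short linear epitope
lights up every peptide that contains the whole epitope, i.e. a contiguous
run of tile start positions.  The *minimal epitope* of such a run is the
stretch of residues covered by **all** reactive tiles: for a contiguous run
of n starts with tile length k its length is k − (n − 1), so a single
reactive tile leaves the full k-mer as the minimal epitope while a long run
narrows it down to a few residues.

The same tiling, read across homologous isoforms, attributes binding
differences to individual residues: peptides of different isoforms that
start at the same alignment position differ only at the family's variable
columns, so partitioning isoforms by the residue at a column and comparing
mean signals ranks candidate key residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import GAP, MasterAlignment
from .panel import AllergenPanel


class EpitopeError(ValueError):
    pass


@dataclass
class EpitopeSegment:
    """A maximal run of reactive tiles on one allergen in one sample."""

    allergen_id: str
    subject: str
    timepoint: int
    isotype: str
    starts_local: list[int]
    starts_aligned: list[int]
    span_local: tuple[int, int]  # union of covered residues
    minimal_span_local: tuple[int, int]  # intersection of covered residues
    minimal_epitope: str

    def to_dict(self) -> dict:
        return {
            "allergen_id": self.allergen_id,
            "subject": self.subject,
            "timepoint": self.timepoint,
            "isotype": self.isotype,
            "starts_local": self.starts_local,
            "starts_aligned": self.starts_aligned,
            "span_local": list(self.span_local),
            "minimal_span_local": list(self.minimal_span_local),
            "minimal_epitope": self.minimal_epitope,
        }


def minimal_epitope(
    starts: list[int], sequence: str, k: int
) -> tuple[str, tuple[int, int]]:
    """Residue stretch shared by all tiles of one contiguous run.

    ``starts`` are 1-based local tile starts forming a contiguous run
    (consecutive integers); the minimal epitope spans
    ``[max(starts), min(starts) + k - 1]`` and has length k − (n − 1).
    """
    if not starts:
        raise EpitopeError("empty run")
    ordered = sorted(set(starts))
    if ordered != list(range(ordered[0], ordered[-1] + 1)):
        raise EpitopeError(
            f"run {ordered} is not contiguous; split it before deconvolution"
        )
    lo, hi = ordered[-1], ordered[0] + k - 1
    if hi < lo:
        raise EpitopeError(
            f"run of {len(ordered)} starts exceeds tile length {k}: "
            "no residue is covered by every tile"
        )
    return sequence[lo - 1 : hi], (lo, hi)


def _runs(sorted_starts: list[int], gap_tol: int = 0) -> list[list[int]]:
    runs: list[list[int]] = []
    for s in sorted_starts:
        if runs and s - runs[-1][-1] <= 1 + gap_tol:
            runs[-1].append(s)
        else:
            runs.append([s])
    return runs


def call_segments(
    calls: pd.DataFrame,
    tiles: pd.DataFrame,
    panel: AllergenPanel,
    gap_tol: int = 0,
    confirmed_only: bool = True,
) -> list[EpitopeSegment]:
    """Group confirmed reactive tiles into epitope segments per allergen/sample.

    Each segment is a maximal run of consecutive reactive start positions
    (``gap_tol`` > 0 lets a run absorb isolated failed spots).  Runs longer
    than the tile length have no common residue; they are split into
    maximal sub-runs that still admit a minimal epitope.
    """
    if calls.empty:
        return []
    use = calls[calls["confirmed"]] if confirmed_only else calls
    occ: dict[str, list[tuple[str, int, int]]] = {}
    for row in tiles.itertuples(index=False):
        occ.setdefault(row.sequence, []).append(
            (row.allergen_id, int(row.start_local), int(row.start_aligned))
        )
    k = len(tiles["sequence"].iloc[0])
    # (subject, timepoint, isotype, allergen) -> {start_local: start_aligned}
    grouped: dict[tuple, dict[int, int]] = {}
    for row in use.itertuples(index=False):
        for allergen, s_local, s_aligned in occ.get(row.peptide, []):
            key = (row.subject, int(row.timepoint), row.isotype, allergen)
            grouped.setdefault(key, {})[s_local] = s_aligned
    segments: list[EpitopeSegment] = []
    for (subject, timepoint, isotype, allergen), start_map in sorted(
        grouped.items()
    ):
        sequence = panel[allergen].sequence
        for run in _runs(sorted(start_map), gap_tol=gap_tol):
            # fill gap-tolerated holes so the run is contiguous for the
            # intersection arithmetic
            full = list(range(run[0], run[-1] + 1))
            if len(full) > k:
                # no residue common to all tiles: emit maximal sub-runs
                sub_runs = [full[i : i + k] for i in range(0, len(full), k)]
            else:
                sub_runs = [full]
            for sub in sub_runs:
                epi, (lo, hi) = minimal_epitope(sub, sequence, k)
                segments.append(
                    EpitopeSegment(
                        allergen_id=allergen,
                        subject=subject,
                        timepoint=timepoint,
                        isotype=isotype,
                        starts_local=sub,
                        starts_aligned=[
                            start_map.get(s, -1) for s in sub
                        ],
                        span_local=(sub[0], sub[-1] + k - 1),
                        minimal_span_local=(lo, hi),
                        minimal_epitope=epi,
                    )
                )
    return segments


@dataclass
class HomologGroup:
    """Tiles of all isoforms starting at one alignment position.

    Isoforms whose tiles are identical collapse into one representative
    (they are the same array spot); ``members`` lists the isoforms behind
    each representative sequence.
    """

    aligned_start: int
    k: int
    members: dict[str, list[str]] = field(default_factory=dict)  # seq -> allergens

    @property
    def representatives(self) -> list[str]:
        return list(self.members)


def group_homologs(
    tiles: pd.DataFrame, aligned_start: int
) -> HomologGroup:
    """Group the tiles of every allergen at one aligned start position.

    Allergens with no tile at that aligned start (gap region) are absent
    from the group.
    """
    sub = tiles[tiles["start_aligned"] == aligned_start]
    k = len(tiles["sequence"].iloc[0]) if len(tiles) else 0
    group = HomologGroup(aligned_start=aligned_start, k=k)
    for row in sub.itertuples(index=False):
        group.members.setdefault(row.sequence, []).append(row.allergen_id)
    return group


def residue_association(
    group: HomologGroup,
    signals: dict[str, float],
    alignment: MasterAlignment,
    min_class: int = 2,
    effect_cut: float = 2.0,
) -> pd.DataFrame:
    """Rank in-window alignment columns by their association with signal.

    ``signals`` maps allergen id to the log2 signal of that allergen's tile
    at the group's aligned start (one sample).  For every alignment column
    in the tile window where at least two residue classes each hold
    ``min_class`` or more allergens, the effect of residue *a* is
    mean(signal | residue a) − mean(signal | other residues).  Columns are
    returned ranked by |effect|, flagged when |effect| ≥ ``effect_cut``
    (log2 units).  With a handful of isoforms per class this is a ranking
    aid, not a formal test.
    """
    allergens = [
        a
        for members in group.members.values()
        for a in members
        if a in signals
    ]
    if len({seq for seq, mem in group.members.items() if any(a in signals for a in mem)}) < 3:
        raise EpitopeError(
            "residue association needs >= 3 distinct tile representatives "
            "with signal"
        )
    records = []
    columns = range(group.aligned_start, group.aligned_start + group.k)
    for col in columns:
        residue_of: dict[str, str] = {}
        for a in allergens:
            r = alignment.residue_at(a, col)
            if r != GAP:
                residue_of[a] = r
        classes = sorted(set(residue_of.values()))
        if len(classes) < 2:
            continue
        for res in classes:
            inside = [signals[a] for a in residue_of if residue_of[a] == res]
            outside = [signals[a] for a in residue_of if residue_of[a] != res]
            if len(inside) < min_class or len(outside) < min_class:
                continue
            effect = float(np.mean(inside) - np.mean(outside))
            records.append(
                {
                    "column": col,
                    "residue": res,
                    "effect": effect,
                    "n_high": len(inside),
                    "n_low": len(outside),
                    "flagged": abs(effect) >= effect_cut,
                }
            )
    out = pd.DataFrame(
        records,
        columns=["column", "residue", "effect", "n_high", "n_low", "flagged"],
    )
    if not out.empty:
        out = out.reindex(
            out["effect"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class IsoallergenContrast:
    allergen_a: str
    allergen_b: str
    subject: str
    timepoint: int
    isotype: str
    aligned_start: int
    signal_difference: float  # z(a) − z(b)
    discriminating: bool


def isoallergen_contrasts(
    calls: pd.DataFrame,
    z: pd.DataFrame,
    tiles: pd.DataFrame,
    pair: tuple[str, str],
) -> pd.DataFrame:
    """Positions where one isoform of a pair is reactive and the other is not.

    For every sample and every aligned start where both pair members carry a
    tile, reports the z difference; the position is *discriminating* when
    exactly one member's tile is a reactive call there.  Swapping the pair
    negates the differences (antisymmetry).
    """
    a_id, b_id = pair
    for member in pair:
        if not (tiles["allergen_id"] == member).any():
            raise EpitopeError(f"pair member {member!r} has no tiles")
    tile_at = {
        (row.allergen_id, row.start_aligned): row.sequence
        for row in tiles[tiles["allergen_id"].isin(pair)].itertuples(index=False)
    }
    starts = sorted(
        {s for (aid, s) in tile_at if aid == a_id}
        & {s for (aid, s) in tile_at if aid == b_id}
    )
    reactive_set = {
        (row.subject, int(row.timepoint), row.isotype, row.peptide)
        for row in calls.itertuples(index=False)
        if row.reactive
    }
    records = []
    for sample in z.index:
        subject, timepoint, isotype = sample
        for s in starts:
            pep_a, pep_b = tile_at[(a_id, s)], tile_at[(b_id, s)]
            za = z.loc[sample].get(pep_a, np.nan)
            zb = z.loc[sample].get(pep_b, np.nan)
            if pd.isna(za) or pd.isna(zb):
                continue
            ra = (subject, int(timepoint), isotype, pep_a) in reactive_set
            rb = (subject, int(timepoint), isotype, pep_b) in reactive_set
            if not (ra or rb):
                continue
            records.append(
                {
                    "allergen_a": a_id,
                    "allergen_b": b_id,
                    "subject": subject,
                    "timepoint": int(timepoint),
                    "isotype": isotype,
                    "aligned_start": s,
                    "signal_difference": float(za - zb),
                    "discriminating": ra != rb,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "allergen_a", "allergen_b", "subject", "timepoint", "isotype",
            "aligned_start", "signal_difference", "discriminating",
        ],
    )


def unique_kmer_index(panel: AllergenPanel, k: int) -> dict[str, list[str]]:
    """Map every k-mer of every complete allergen to its carrier set.

    Supports "uniquely found in" queries: a k-mer whose carrier list has
    length one occurs in exactly one isoform of the panel.
    """
    carriers: dict[str, set[str]] = {}
    for rec in panel.complete_records:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            carriers.setdefault(seq[i : i + k], set()).add(rec.allergen_id)
    return {kmer: sorted(ids) for kmer, ids in carriers.items()}
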