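"""Intensity ingestion, robust normalisation and reactive-peptide calling.

Samples are keyed by (subject, timepoint, isotype).  Raw fluorescence
intensities are floored and log2-transformed; a robust per-sample z-score
(median / scaled MAD) puts samples with different scanner gains on one
scale.  A peptide is *reactive* when its z-score passes a cut-off, and
*confirmed* when the signal is corroborated the way a genuine antibody
reactivity is expected to be on a tiled array:

* the same peptide is reactive in multiple samples of the same subject and
  isotype (``consecutive_sample``),
* a second reactive peptide in the same sample overlaps it substantially on
  the same allergen (``overlapping_peptide``), or
* a homologous peptide — same alignment start, different allergen — is
  reactive in the same sample (``homologous_peptide``).

A reactive peptide with no such support is flagged as an artifact
candidate: an isolated bright spot is more plausibly a local surface defect
than an antibody.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PeptideIndex

ISOTYPES = ("IgG", "IgG4", "IgE")
SAMPLE_LEVELS = ["subject", "timepoint", "isotype"]
MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma for normals

TAG_CONSECUTIVE = "consecutive_sample"
TAG_OVERLAP = "overlapping_peptide"
TAG_HOMOLOG = "homologous_peptide"


class ReactivityError(ValueError):
    pass


@dataclass
class ReactivityMatrix:
    """Samples × unique peptides, raw and log2 fluorescence layers.

    Rows are a (subject, timepoint, isotype) MultiIndex; columns are unique
    peptide sequences.  Missing sample/peptide combinations are NaN, never
    zero.  ``quarantined`` holds input rows whose peptide was not in the
    design index.
    """

    raw: pd.DataFrame
    log2: pd.DataFrame
    quarantined: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def samples(self) -> pd.MultiIndex:
        return self.raw.index

    @property
    def peptides(self) -> pd.Index:
        return self.raw.columns

    def subset(self, isotype: str) -> "ReactivityMatrix":
        mask = self.raw.index.get_level_values("isotype") == isotype
        return ReactivityMatrix(
            self.raw.loc[mask], self.log2.loc[mask], self.quarantined
        )


def matrix_from_log2(log2: pd.DataFrame) -> ReactivityMatrix:
    """Build a matrix directly from a log2 layer (raw = 2**log2)."""
    log2 = log2.copy()
    log2.index = log2.index.set_names(SAMPLE_LEVELS)
    return ReactivityMatrix(raw=2.0 ** log2, log2=log2)


def read_intensity_table(
    tsv_path: str | Path,
    index: PeptideIndex | None = None,
    floor: float = 1.0,
) -> ReactivityMatrix:
    """Read a long-format intensity TSV into a ReactivityMatrix.

    Required columns: ``subject, timepoint, isotype, peptide, intensity``.
    Peptides are matched by sequence against the design index; unmatched
    rows are quarantined with a warning rather than silently dropped.
    Intensities at or below zero are raised to ``floor`` before log2 (log
    domain safety; negligible at array scale), negative intensities are a
    hard error.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"subject": str, "isotype": str})
    required = {"subject", "timepoint", "isotype", "peptide", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ReactivityError(f"intensity table lacks columns {sorted(missing)}")
    if (df["intensity"] < 0).any():
        bad = df.loc[df["intensity"] < 0].head()
        raise ReactivityError(f"negative intensities in table, e.g.\n{bad}")
    dup = df.duplicated(subset=["subject", "timepoint", "isotype", "peptide"])
    if dup.any():
        listed = df.loc[dup, ["subject", "timepoint", "isotype", "peptide"]]
        raise ReactivityError(
            f"duplicate (sample, peptide) rows:\n{listed.to_string(index=False)}"
        )
    quarantined = df.iloc[0:0]
    if index is not None:
        known = df["peptide"].isin(index.occurrences)
        if not known.all():
            quarantined = df.loc[~known]
            warnings.warn(
                f"{len(quarantined)} intensity rows reference peptides absent "
                "from the design index; quarantined",
                stacklevel=2,
            )
            df = df.loc[known]
    if df.empty:
        raise ReactivityError("no resolvable intensity rows")
    df = df.assign(intensity=df["intensity"].clip(lower=floor))
    wide = df.pivot_table(
        index=SAMPLE_LEVELS, columns="peptide", values="intensity", aggfunc="first"
    )
    wide.columns.name = None
    return ReactivityMatrix(raw=wide, log2=np.log2(wide), quarantined=quarantined)


def robust_z(matrix: ReactivityMatrix | pd.DataFrame, min_peptides: int = 8) -> pd.DataFrame:
    """Per-sample robust z-scores of the log2 layer.

    z = (log2 I − median_sample) / (1.4826 × MAD_sample), computed within
    each sample row so scanner gain and per-sample background cancel.
    """
    log2 = matrix.log2 if isinstance(matrix, ReactivityMatrix) else matrix
    counts = log2.notna().sum(axis=1)
    if (counts < min_peptides).any():
        bad = counts[counts < min_peptides]
        raise ReactivityError(
            f"samples with fewer than {min_peptides} peptides: {list(bad.index)}"
        )
    med = log2.median(axis=1)
    mad = log2.sub(med, axis=0).abs().median(axis=1)
    if (mad == 0).any():
        bad = mad[mad == 0]
        raise ReactivityError(
            "zero MAD in samples "
            f"{list(bad.index)}; intensities are degenerate — apply a "
            "pseudo-count/floor or check the input"
        )
    return log2.sub(med, axis=0).div(MAD_SCALE * mad, axis=0)


def _occurrences_by_peptide(tiles: pd.DataFrame) -> dict[str, list[tuple[str, int, int]]]:
    occ: dict[str, list[tuple[str, int, int]]] = {}
    for row in tiles.itertuples(index=False):
        occ.setdefault(row.sequence, []).append(
            (row.allergen_id, int(row.start_local), int(row.start_aligned))
        )
    return occ


def call_reactive(
    z: pd.DataFrame,
    tiles: pd.DataFrame,
    z_cut: float = 3.0,
    overlap_min: int = 8,
    min_timepoints: int = 2,
    require_adjacent: bool = False,
) -> pd.DataFrame:
    """Call reactive peptides and confirm them by corroborating evidence.

    Returns a long DataFrame of the reactive peptides only, with columns
    ``subject, timepoint, isotype, peptide, z, reactive, confirmed,
    support, artifact_candidate``.  ``support`` is a comma-joined sorted
    set of the evidence tags; it is empty exactly when the call is an
    unconfirmed isolated signal (artifact candidate).

    ``require_adjacent`` restricts the multi-sample criterion to adjacent
    observed timepoints of the subject rather than any two.
    """
    occ = _occurrences_by_peptide(tiles)
    k = len(next(iter(occ))) if occ else 0
    records: list[dict] = []
    reactive_mask = z.ge(z_cut)

    # peptide -> reactive timepoints per (subject, isotype), for the
    # multi-sample criterion
    reactive_long = reactive_mask.stack()
    reactive_long = reactive_long[reactive_long]
    by_subject: dict[tuple[str, str], dict[str, set[int]]] = {}
    observed_tp: dict[tuple[str, str], set[int]] = {}
    for (subject, timepoint, isotype) in z.index:
        observed_tp.setdefault((subject, isotype), set()).add(int(timepoint))
    for (subject, timepoint, isotype, peptide) in reactive_long.index:
        by_subject.setdefault((subject, isotype), {}).setdefault(
            peptide, set()
        ).add(int(timepoint))

    def multi_sample_support(subject, isotype, peptide) -> bool:
        tps = by_subject.get((subject, isotype), {}).get(peptide, set())
        if len(tps) < min_timepoints:
            return False
        if not require_adjacent:
            return True
        ordered = sorted(observed_tp[(subject, isotype)])
        hits = sorted(tps)
        return any(
            ordered.index(b) - ordered.index(a) == 1
            for a, b in zip(hits, hits[1:])
        )

    for sample in z.index:
        subject, timepoint, isotype = sample
        row = z.loc[sample]
        reactive_peps = list(row.index[reactive_mask.loc[sample].fillna(False)])
        if not reactive_peps:
            continue
        # occurrence lookup for this sample's reactive set
        starts_by_allergen: dict[str, dict[str, set[int]]] = {}
        aligned_allergens: dict[int, set[str]] = {}
        for pep in reactive_peps:
            for allergen, s_local, s_aligned in occ.get(pep, []):
                starts_by_allergen.setdefault(allergen, {}).setdefault(
                    pep, set()
                ).add(s_local)
                aligned_allergens.setdefault(s_aligned, set()).add(allergen)
        for pep in reactive_peps:
            tags = set()
            if multi_sample_support(subject, isotype, pep):
                tags.add(TAG_CONSECUTIVE)
            for allergen, s_local, s_aligned in occ.get(pep, []):
                # overlapping distinct peptide on the same allergen
                others = starts_by_allergen.get(allergen, {})
                for other_pep, other_starts in others.items():
                    if other_pep == pep:
                        continue
                    if any(
                        0 < abs(s_local - o) <= k - overlap_min
                        for o in other_starts
                    ):
                        tags.add(TAG_OVERLAP)
                        break
                # homologous peptide: same aligned start, another allergen
                carriers = aligned_allergens.get(s_aligned, set())
                if carriers - {allergen}:
                    # a different reactive peptide must carry that start
                    for other_pep, occs in (
                        (p, occ.get(p, [])) for p in reactive_peps if p != pep
                    ):
                        if any(
                            oa != allergen and osa == s_aligned
                            for oa, _, osa in occs
                        ):
                            tags.add(TAG_HOMOLOG)
                            break
            records.append(
                {
                    "subject": subject,
                    "timepoint": int(timepoint),
                    "isotype": isotype,
                    "peptide": pep,
                    "z": float(row[pep]),
                    "reactive": True,
                    "confirmed": bool(tags),
                    "support": ",".join(sorted(tags)),
                    "artifact_candidate": not tags,
                }
            )
    columns = [
        "subject", "timepoint", "isotype", "peptide", "z",
        "reactive", "confirmed", "support", "artifact_candidate",
    ]
    return pd.DataFrame(records, columns=columns)


def project_positions(
    values: pd.Series,
    tiles: pd.DataFrame,
    allergen_id: str,
    aggregate: str = "max",
) -> pd.Series:
    """Project per-peptide signal onto allergen residues.

    Each residue receives the aggregate (``max`` or ``mean``) of the signals
    of all tiles covering it; residues covered by no tile (or only by tiles
    with no measured signal) are NaN.  ``values`` is indexed by peptide
    sequence (e.g. one row of a z matrix or log2 matrix).
    """
    sub = tiles[tiles["allergen_id"] == allergen_id]
    if sub.empty:
        raise ReactivityError(f"no tiles for allergen {allergen_id!r}")
    if aggregate not in {"max", "mean"}:
        raise ReactivityError(f"unknown aggregate {aggregate!r}")
    k = len(sub["sequence"].iloc[0])
    length = int(sub["start_local"].max()) + k - 1
    buckets: list[list[float]] = [[] for _ in range(length + 1)]
    for row in sub.itertuples(index=False):
        v = values.get(row.sequence, np.nan)
        if pd.isna(v):
            continue
        for pos in range(row.start_local, row.start_local + k):
            buckets[pos].append(float(v))
    agg = np.max if aggregate == "max" else np.mean
    out = pd.Series(
        [agg(b) if b else np.nan for b in buckets[1:]],
        index=pd.RangeIndex(1, length + 1, name="position"),
        name=allergen_id,
    )
    return out
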