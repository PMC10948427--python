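"""Allergen panel I/O and exhaustive overlapping-peptide tiling.

A *panel* is the set of allergen isoforms printed on the array: named
sequences (e.g. ``Gad m 1.0201``) plus per-record metadata.  Each complete
record is decomposed into every k-mer subsequence at a fixed offset
(offset-1 tiling: adjacent peptides share k-1 residues), and identical
peptides arising from different isoforms are collapsed into a unique-peptide
index that remembers every occurrence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alignment import MasterAlignment

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

TILE_COLUMNS = ["allergen_id", "start_local", "start_aligned", "sequence"]


class PanelError(ValueError):
    """Raised for malformed panels or invalid tiling requests."""


@dataclass(frozen=True)
class AllergenRecord:
    """One allergen isoform as represented on the array.

    ``complete`` is False for records whose database entry left residues
    undefined; such records are carried in the panel for bookkeeping but are
    never tiled.  ``includes_initial_met`` records whether the stored
    sequence begins with the initiator methionine — the stored sequence is
    exactly what gets tiled, the flag is descriptive only.
    """

    allergen_id: str
    species: str
    sequence: str
    complete: bool = True
    includes_initial_met: bool = True

    def __post_init__(self) -> None:
        bad = [
            (i + 1, c)
            for i, c in enumerate(self.sequence)
            if c not in AMINO_ACIDS
        ]
        if bad:
            pos, char = bad[0]
            raise PanelError(
                f"record {self.allergen_id!r}: non-amino-acid character "
                f"{char!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideTile:
    """A k-mer peptide cut from one allergen.

    ``start_local`` is the 1-based index of the first tile residue on the
    allergen sequence; the tile covers residues
    ``[start_local, start_local + k - 1]`` inclusive.  ``start_aligned`` is
    the master-alignment column of the first residue (equal to
    ``start_local`` when no alignment is supplied / the family is gap-free).
    """

    allergen_id: str
    start_local: int
    start_aligned: int
    sequence: str

    @property
    def k(self) -> int:
        return len(self.sequence)

    @property
    def end_local(self) -> int:
        return self.start_local + self.k - 1


@dataclass
class AllergenPanel:
    """Ordered collection of allergen records with unique ids."""

    records: list[AllergenRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.allergen_id in seen:
                raise PanelError(f"duplicate allergen id {rec.allergen_id!r}")
            seen.add(rec.allergen_id)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, allergen_id: str) -> AllergenRecord:
        for rec in self.records:
            if rec.allergen_id == allergen_id:
                return rec
        raise KeyError(allergen_id)

    @property
    def complete_records(self) -> list[AllergenRecord]:
        return [r for r in self.records if r.complete]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.allergen_id}\n{rec.sequence}\n")

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "allergen_id": [r.allergen_id for r in self.records],
                "species": [r.species for r in self.records],
                "complete": [r.complete for r in self.records],
                "includes_initial_met": [
                    r.includes_initial_met for r in self.records
                ],
            }
        )

    def to_metadata_tsv(self, path: str | Path) -> None:
        self.metadata_frame().to_csv(path, sep="\t", index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise PanelError(f"unparseable boolean {value!r} in panel metadata")


def read_panel(fasta_path: str | Path, metadata_path: str | Path) -> AllergenPanel:
    """Read a panel from a FASTA file plus a TSV metadata sidecar.

    The metadata TSV must have columns ``allergen_id``, ``species``,
    ``complete``, ``includes_initial_met``.  Records are returned in FASTA
    file order; incomplete records are retained but flagged.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"allergen_id", "species", "complete", "includes_initial_met"}
    missing = required - set(meta.columns)
    if missing:
        raise PanelError(f"panel metadata lacks columns {sorted(missing)}")
    if meta["allergen_id"].duplicated().any():
        dups = meta.loc[meta["allergen_id"].duplicated(), "allergen_id"]
        raise PanelError(f"duplicate allergen ids in metadata: {list(dups)}")
    meta_by_id = meta.set_index("allergen_id")

    records = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        rid = seq_rec.description  # allergen names contain spaces
        if rid in seen:
            raise PanelError(f"duplicate allergen id {rid!r} in FASTA")
        seen.add(rid)
        if rid not in meta_by_id.index:
            raise PanelError(f"record {rid!r} missing from panel metadata")
        row = meta_by_id.loc[rid]
        records.append(
            AllergenRecord(
                allergen_id=rid,
                species=str(row["species"]),
                sequence=str(seq_rec.seq).upper(),
                complete=_parse_bool(row["complete"]),
                includes_initial_met=_parse_bool(row["includes_initial_met"]),
            )
        )
    return AllergenPanel(records)


def tile_allergen(
    record: AllergenRecord,
    k: int = 16,
    offset: int = 1,
    alignment: MasterAlignment | None = None,
) -> list[PeptideTile]:
    """Cut one complete allergen into overlapping k-mer tiles.

    Tiles start at local positions 1, 1+offset, ... while they still fit.
    With offset 1 this is the exhaustive tiling: ``len - k + 1`` peptides,
    adjacent ones overlapping by ``k - 1`` residues.  Incomplete records are
    refused: partially defined sequences cannot be tiled faithfully.
    """
    if not record.complete:
        raise PanelError(
            f"record {record.allergen_id!r} is incomplete and cannot be tiled"
        )
    if k < 1 or offset < 1:
        raise PanelError("tile length and offset must be >= 1")
    if len(record) < k:
        raise PanelError(
            f"record {record.allergen_id!r} shorter ({len(record)}) than "
            f"tile length {k}"
        )
    tiles = []
    for start in range(1, len(record) - k + 2, offset):
        if alignment is not None:
            aligned = alignment.local_to_aligned(record.allergen_id, start)
        else:
            aligned = start
        tiles.append(
            PeptideTile(
                allergen_id=record.allergen_id,
                start_local=start,
                start_aligned=aligned,
                sequence=record.sequence[start - 1 : start - 1 + k],
            )
        )
    return tiles


def tile_panel(
    panel: AllergenPanel,
    k: int = 16,
    offset: int = 1,
    alignment: MasterAlignment | None = None,
) -> pd.DataFrame:
    """Tile every complete record of a panel into one table.

    Returns a DataFrame with columns ``allergen_id, start_local,
    start_aligned, sequence`` — the tile-table interchange format used by
    the rest of the pipeline.
    """
    rows = []
    for rec in panel.complete_records:
        rows.extend(tile_allergen(rec, k=k, offset=offset, alignment=alignment))
    return pd.DataFrame(
        {
            "allergen_id": [t.allergen_id for t in rows],
            "start_local": [t.start_local for t in rows],
            "start_aligned": [t.start_aligned for t in rows],
            "sequence": [t.sequence for t in rows],
        }
    )


@dataclass
class PeptideIndex:
    """Unique-peptide index over all tiles of a panel.

    ``occurrences`` maps each distinct peptide sequence to the list of
    ``(allergen_id, start_local, start_aligned)`` positions where it is cut
    from the panel; identical peptides from different isoforms collapse into
    a single entry.
    """

    k: int
    occurrences: dict[str, list[tuple[str, int, int]]] = field(
        default_factory=dict
    )

    @property
    def unique_sequences(self) -> set[str]:
        return set(self.occurrences)

    @property
    def n_unique(self) -> int:
        return len(self.occurrences)

    @property
    def total_tiles(self) -> int:
        return sum(len(v) for v in self.occurrences.values())

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.occurrences


def build_peptide_index(
    tiles: pd.DataFrame | list[PeptideTile],
) -> PeptideIndex:
    """Collapse a tile table into a unique-peptide index.

    All tiles must share one k; mixing tile lengths is a hard error because
    a unique-peptide count is only meaningful within one design.
    """
    if isinstance(tiles, pd.DataFrame):
        it = tiles.itertuples(index=False)
        rows = [(r.allergen_id, r.start_local, r.start_aligned, r.sequence) for r in it]
    else:
        rows = [
            (t.allergen_id, t.start_local, t.start_aligned, t.sequence)
            for t in tiles
        ]
    if not rows:
        raise PanelError("cannot index an empty tile set")
    ks = {len(seq) for *_, seq in rows}
    if len(ks) != 1:
        raise PanelError(f"mixed tile lengths in index: {sorted(ks)}")
    index = PeptideIndex(k=ks.pop())
    for allergen_id, start_local, start_aligned, seq in rows:
        index.occurrences.setdefault(seq, []).append(
            (allergen_id, int(start_local), int(start_aligned))
        )
    return index
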