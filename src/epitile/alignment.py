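"""Master-alignment coordinate mapping and per-column diversity.

The family alignment is an *input* (gapped FASTA): peptide start positions
reported by the pipeline are numbered in master-alignment columns so that
homologous peptides of different isoforms share a coordinate, and column
diversity flags the positions where the family disagrees.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass
class MasterAlignment:
    """Gapped rows keyed by allergen id, all of equal length.

    Columns are 1-based; ungapping a row must reproduce the panel sequence
    for that allergen exactly (checked by callers that hold both).
    """

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment rows: lengths {sorted(lengths)}")
        self.column_count = lengths.pop()
        # per-row maps between local residue index and alignment column
        self._local_to_col: dict[str, np.ndarray] = {}
        self._col_to_local: dict[str, np.ndarray] = {}
        for rid, row in self.rows.items():
            cols = np.flatnonzero(np.frombuffer(row.encode(), dtype="S1") != GAP.encode())
            self._local_to_col[rid] = cols + 1
            c2l = np.zeros(self.column_count, dtype=int)  # 0 = gap
            c2l[cols] = np.arange(1, len(cols) + 1)
            self._col_to_local[rid] = c2l

    def __contains__(self, allergen_id: str) -> bool:
        return allergen_id in self.rows

    def ungapped(self, allergen_id: str) -> str:
        return self.rows[allergen_id].replace(GAP, "")

    def ungapped_length(self, allergen_id: str) -> int:
        return len(self._local_to_col[allergen_id])

    def local_to_aligned(self, allergen_id: str, local_pos: int) -> int:
        """1-based alignment column of the ``local_pos``-th residue."""
        if allergen_id not in self.rows:
            raise AlignmentError(f"allergen {allergen_id!r} not in alignment")
        n = self.ungapped_length(allergen_id)
        if not 1 <= local_pos <= n:
            raise AlignmentError(
                f"local position {local_pos} out of range 1..{n} for "
                f"{allergen_id!r}"
            )
        return int(self._local_to_col[allergen_id][local_pos - 1])

    def aligned_to_local(self, allergen_id: str, column: int) -> int:
        """Inverse of :meth:`local_to_aligned`; errors on a gap column."""
        if allergen_id not in self.rows:
            raise AlignmentError(f"allergen {allergen_id!r} not in alignment")
        if not 1 <= column <= self.column_count:
            raise AlignmentError(
                f"column {column} out of range 1..{self.column_count}"
            )
        local = int(self._col_to_local[allergen_id][column - 1])
        if local == 0:
            raise AlignmentError(
                f"{allergen_id!r} has a gap at alignment column {column}"
            )
        return local

    def residue_at(self, allergen_id: str, column: int) -> str:
        """Residue (or gap) of one row at a 1-based column."""
        return self.rows[allergen_id][column - 1]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, row in self.rows.items():
                fh.write(f">{rid}\n{row}\n")


def read_alignment(path: str | Path) -> MasterAlignment:
    """Read a master alignment from gapped FASTA (row order preserved)."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.description  # allergen names contain spaces
        if rid in rows:
            raise AlignmentError(f"duplicate alignment row {rid!r}")
        rows[rid] = str(rec.seq).upper()
    return MasterAlignment(rows)


@dataclass(frozen=True)
class ColumnDiversity:
    column: int
    consensus_residue: str
    consensus_frequency: float
    diverse: bool


def column_diversity_profile(
    alignment: MasterAlignment, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-column consensus residue, its frequency, and a diversity flag.

    Frequencies are computed among non-gap entries only; a column is flagged
    diverse when the most prominent residue has frequency strictly below
    ``threshold`` (default: below one half).  Consensus ties break
    alphabetically.  All-gap columns yield a NaN frequency and are never
    flagged.
    """
    if len(alignment.rows) < 2:
        raise AlignmentError("diversity profile needs at least 2 rows")
    records = []
    rows = list(alignment.rows.values())
    for col in range(1, alignment.column_count + 1):
        residues = [r[col - 1] for r in rows if r[col - 1] != GAP]
        if not residues:
            records.append((col, GAP, float("nan"), False))
            continue
        counts = Counter(residues)
        consensus = min(counts, key=lambda a: (-counts[a], a))
        freq = counts[consensus] / len(residues)
        records.append((col, consensus, freq, freq < threshold))
    return pd.DataFrame(
        records,
        columns=["column", "consensus_residue", "consensus_frequency", "diverse"],
    )
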