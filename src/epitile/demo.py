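"""Synthetic demonstration panel shaped like the fish β-parvalbumin family.

The 21 isoallergen/isoform names and species follow the WHO/IUIS allergen
nomenclature catalogue for fish β-parvalbumins (the two rainbow-trout
records have undefined residues in the database and are flagged
incomplete).  The *sequences are synthetic stand-ins*: the real database
sequences are not redistributed here.  A designed 109-residue base
sequence is varied per isoform so that the family reproduces the
qualitative features the pipeline must handle, e.g.:

* a shared dominant helix epitope ``FIEEDELKLFLQNFSA`` starting at
  alignment position 59, with variation at column 71 (N in most isoforms,
  D in a few, and an isoleucine–alanine motif at 70–71 in Gad c 1.0101);
* a loop 9-mer ``LAAKSPADI`` found uniquely in Gad m 1.0201, with the
  near-identical ``LAAKTPEDI`` in Thu a 1.0101 and a single-residue
  variant in Gad m 1.0202;
* Gad c 1.0101 lacking the initiator methionine (its alignment row starts
  with a gap), so local and aligned coordinates differ by one.

All tests that quote a named allergen use this panel; nothing here is a
measured sequence.
"""

from __future__ import annotations

from .alignment import MasterAlignment
from .panel import AllergenPanel, AllergenRecord

BASE = (
    "MAFAGILADADIAAAL"  # 1-16
    "EACKAADSFD"        # 17-26
    "HKAFFAKVGLTS"      # 27-38
    "LAAKTPADA"         # 39-47  (BC loop / C-helix N-terminus)
    "KKAFEIIDQDK"       # 48-58  (C-helix C-terminus / CD loop)
    "FIEEDELKLFLQNFSA"  # 59-74  (D helix and flanks)
    "GDSD"              # 75-78
    "ETKVFLKAGDSDGDGK"  # 79-94  (E helix / EF loop)
    "IGVDEWAALVKKVGL"   # 95-109
)

# isoform -> (species, {aligned position: residue}, complete, has initial Met)
_VARIANTS: dict[str, tuple[str, dict[int, str], bool, bool]] = {
    "Clu h 1.0101": ("Clupea harengus", {10: "S", 101: "S"}, True, True),
    "Clu h 1.0201": ("Clupea harengus", {10: "S", 33: "R"}, True, True),
    "Clu h 1.0301": ("Clupea harengus", {5: "A", 71: "D"}, True, True),
    "Cyp c 1.0101": ("Cyprinus carpio", {24: "T"}, True, True),
    "Cyp c 1.0201": ("Cyprinus carpio", {24: "T", 71: "D"}, True, True),
    "Gad c 1.0101": (
        "Gadus callarias",
        {
            27: "F", 28: "D", 29: "E", 30: "D", 31: "G", 32: "F", 33: "Y",
            34: "A", 35: "K",          # B-helix motif FDEDGFYAK
            51: "I", 52: "A", 53: "D", 54: "E", 55: "D", 56: "K",  # IADEDK
            70: "I", 71: "A",          # isoleucine-alanine motif at 70-71
            103: "F", 104: "Y",        # distinctive C-terminus
        },
        True,
        False,  # stored sequence starts at the alanine after the Met
    ),
    "Gad m 1.0101": ("Gadus morhua", {37: "S"}, True, True),
    "Gad m 1.0102": ("Gadus morhua", {18: "S", 37: "S"}, True, True),
    "Gad m 1.0201": (
        "Gadus morhua", {43: "S", 47: "I", 102: "S"}, True, True
    ),  # 39-47 becomes LAAKSPADI, unique in the panel
    "Gad m 1.0202": (
        "Gadus morhua", {43: "S", 44: "L", 47: "I", 102: "S"}, True, True
    ),  # LAAKSLADI: one residue away from the Gad m 1.0201 epitope
    "Lat c 1.0101": ("Lates calcarifer", {63: "N"}, True, True),
    "Lat c 1.0201": ("Lates calcarifer", {6: "V", 63: "N"}, True, True),
    "Lep w 1.0101": ("Lepidorhombus whiffiagonis", {22: "S"}, True, True),
    "Onc m 1.0101": ("Oncorhynchus mykiss", {14: "S"}, False, True),
    "Onc m 1.0201": ("Oncorhynchus mykiss", {14: "S", 35: "A"}, False, True),
    "Sal s 1.0101": ("Salmo salar", {12: "V"}, True, True),
    "Sar sa 1.0101": ("Sardinops sagax", {86: "S"}, True, True),
    "Seb m 1.0101": ("Sebastes marinus", {58: "R"}, True, True),
    "Seb m 1.0201": ("Sebastes marinus", {58: "R", 71: "D"}, True, True),
    "Thu a 1.0101": (
        "Thunnus albacares", {45: "E", 47: "I"}, True, True
    ),  # 39-47 becomes LAAKTPEDI; D-helix peptide identical to base
    "Xip g 1.0101": ("Xiphias gladius", {30: "Y"}, True, True),
}

_INCOMPLETE_LENGTH = 60  # residues defined for the incomplete records


def demo_panel() -> tuple[AllergenPanel, MasterAlignment]:
    """Build the synthetic demonstration panel and its master alignment.

    21 records, 19 complete; the alignment is 109 columns, gap-free except
    for the missing initiator methionine of Gad c 1.0101 and the undefined
    tails of the two incomplete records.
    """
    records = []
    rows: dict[str, str] = {}
    for allergen_id, (species, subs, complete, has_met) in _VARIANTS.items():
        seq = list(BASE)
        for pos, res in subs.items():
            seq[pos - 1] = res
        full = "".join(seq)
        if not complete:
            stored = full[:_INCOMPLETE_LENGTH]
            row = stored + "-" * (len(BASE) - _INCOMPLETE_LENGTH)
        elif not has_met:
            stored = full[1:]
            row = "-" + stored
        else:
            stored = full
            row = full
        records.append(
            AllergenRecord(
                allergen_id=allergen_id,
                species=species,
                sequence=stored,
                complete=complete,
                includes_initial_met=has_met,
            )
        )
        rows[allergen_id] = row
    return AllergenPanel(records), MasterAlignment(rows)
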