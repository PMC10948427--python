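import numpy as np
import pandas as pd
import pytest

from epitile.alignment import MasterAlignment
from epitile.epitope import (
    EpitopeError,
    call_segments,
    group_homologs,
    isoallergen_contrasts,
    minimal_epitope,
    residue_association,
    unique_kmer_index,
)
from epitile.panel import AllergenPanel, AllergenRecord, tile_panel

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_minimal(starts, k):
    """Oracle: intersection of the residue sets covered by each tile."""
    covered = [set(range(s, s + k)) for s in starts]
    common = set.intersection(*covered)
    return (min(common), max(common)) if common else None


class TestMinimalEpitope:
    def test_single_tile_returns_whole_peptide(self):
        seq = (AA * 6)[:109]
        epi, span = minimal_epitope([40], seq, 16)
        assert epi == seq[39:55] and span == (40, 55)
        assert len(epi) == 16

    @pytest.mark.parametrize("n", range(1, 17))
    def test_length_formula_matches_bruteforce(self, n):
        seq = (AA * 6)[:109]
        starts = list(range(20, 20 + n))
        epi, (lo, hi) = minimal_epitope(starts, seq, 16)
        assert len(epi) == 16 - (n - 1)
        assert (lo, hi) == brute_force_minimal(starts, 16)
        assert epi == seq[lo - 1 : hi]

    def test_eleven_tile_run_narrows_to_six_residues(self):
        seq = (AA * 6)[:109]
        epi, _ = minimal_epitope(list(range(40, 51)), seq, 16)
        assert len(epi) == 6

    def test_two_tile_gap_seven_gives_nine_residues(self):
        seq = (AA * 6)[:109]
        starts = [30, 37]
        with pytest.raises(EpitopeError):
            minimal_epitope(starts, seq, 16)  # not contiguous as a run
        # as endpoints of a contiguous run the overlap is 9 residues
        epi, span = minimal_epitope(list(range(30, 38)), seq, 16)
        assert len(epi) == 9
        assert span == brute_force_minimal(starts, 16)

    def test_extreme_shift_leaves_single_residue(self):
        seq = (AA * 6)[:109]
        epi, _ = minimal_epitope(list(range(10, 26)), seq, 16)
        assert len(epi) == 1

    def test_non_contiguous_run_rejected(self):
        with pytest.raises(EpitopeError, match="contiguous"):
            minimal_epitope([10, 12], "A" * 40, 16)


def _family_panel(n=4, length=60, seed=0, edits=None):
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(AA), length))
    records = []
    for i in range(n):
        seq = list(base)
        for pos, res in (edits or {}).get(i, {}).items():
            seq[pos - 1] = res
        records.append(AllergenRecord(f"iso{i}", "sp", "".join(seq)))
    panel = AllergenPanel(records)
    aln = MasterAlignment({r.allergen_id: r.sequence for r in records})
    return panel, aln, tile_panel(panel, alignment=aln)


def _calls_for(tiles, hits, subject="s1", timepoint=1, isotype="IgG"):
    rows = []
    for allergen, start in hits:
        pep = tiles[
            (tiles.allergen_id == allergen) & (tiles.start_local == start)
        ]["sequence"].iloc[0]
        rows.append(
            {
                "subject": subject,
                "timepoint": timepoint,
                "isotype": isotype,
                "peptide": pep,
                "z": 5.0,
                "reactive": True,
                "confirmed": True,
                "support": "overlapping_peptide",
                "artifact_candidate": False,
            }
        )
    return pd.DataFrame(rows).drop_duplicates(subset="peptide")


class TestCallSegments:
    def test_single_start_full_16mer(self):
        panel, _, tiles = _family_panel(n=2, edits={1: {5: "W"}})
        calls = _calls_for(tiles, [("iso0", 20)])
        segs = [
            s for s in call_segments(calls, tiles, panel)
            if s.allergen_id == "iso0"
        ]
        assert len(segs) == 1
        seg = segs[0]
        assert seg.minimal_epitope == panel["iso0"].sequence[19:35]
        assert seg.minimal_span_local == (20, 35)

    def test_two_runs_give_two_segments(self):
        panel, _, tiles = _family_panel(n=2, length=90, edits={1: {5: "W"}})
        starts = [("iso0", s) for s in range(20, 28)] + [
            ("iso0", s) for s in range(50, 53)
        ]
        calls = _calls_for(tiles, starts)
        segs = [
            s for s in call_segments(calls, tiles, panel)
            if s.allergen_id == "iso0"
        ]
        assert len(segs) == 2
        assert sorted(len(s.minimal_epitope) for s in segs) == [9, 14]

    def test_runs_partition_reactive_starts(self):
        panel, _, tiles = _family_panel(n=2, length=90, edits={1: {5: "W"}})
        wanted = set(range(10, 15)) | {30} | set(range(55, 60))
        calls = _calls_for(tiles, [("iso0", s) for s in sorted(wanted)])
        segs = [
            s for s in call_segments(calls, tiles, panel)
            if s.allergen_id == "iso0"
        ]
        seen = [s for seg in segs for s in seg.starts_local]
        assert sorted(seen) == sorted(wanted)  # no orphan, no double

    def test_gap_tolerance_absorbs_failed_spot(self):
        panel, _, tiles = _family_panel(n=2, length=90, edits={1: {5: "W"}})
        starts = [10, 11, 13, 14]  # spot at 12 failed
        calls = _calls_for(tiles, [("iso0", s) for s in starts])
        strict = [
            s for s in call_segments(calls, tiles, panel, gap_tol=0)
            if s.allergen_id == "iso0"
        ]
        loose = [
            s for s in call_segments(calls, tiles, panel, gap_tol=1)
            if s.allergen_id == "iso0"
        ]
        assert len(strict) == 2 and len(loose) == 1
        assert loose[0].starts_local == list(range(10, 15))


class TestGroupHomologs:
    def test_identical_family_one_representative(self):
        _, _, tiles = _family_panel(n=4)
        group = group_homologs(tiles, aligned_start=10)
        assert len(group.members) == 1
        assert sorted(next(iter(group.members.values()))) == [
            "iso0", "iso1", "iso2", "iso3",
        ]

    def test_in_window_substitution_splits_representatives(self):
        _, _, tiles = _family_panel(n=2, edits={1: {15: "W"}})
        assert len(group_homologs(tiles, aligned_start=10).members) == 2
        assert len(group_homologs(tiles, aligned_start=40).members) == 1

    def test_matches_bruteforce_substring_grouping(self, small_cohort):
        panel, _, tiles, _, _ = small_cohort
        for start in (5, 20, 40):
            group = group_homologs(tiles, aligned_start=start)
            brute = {}
            for rec in panel.complete_records:
                sub = rec.sequence[start - 1 : start + 15]
                brute.setdefault(sub, set()).add(rec.allergen_id)
            assert {
                seq: set(m) for seq, m in group.members.items()
            } == brute


class TestResidueAssociation:
    def _planted(self, signal_residue="N", column=25):
        edits = {
            0: {column: "N"}, 1: {column: "N"}, 2: {column: "N"},
            3: {column: "D"}, 4: {column: "D"}, 5: {column: "S", 40: "W"},
        }
        panel, aln, tiles = _family_panel(n=6, seed=2, edits=edits)
        group = group_homologs(tiles, aligned_start=column - 5)
        signals = {
            rec.allergen_id: (
                10.0 if rec.sequence[column - 1] == signal_residue else 7.0
            )
            for rec in panel.complete_records
        }
        return group, signals, aln, column

    def test_planted_key_residue_is_top_flagged_column(self):
        group, signals, aln, column = self._planted()
        assoc = residue_association(group, signals, aln)
        top = assoc.iloc[0]
        assert top.column == column and top.flagged
        assert top.residue == "N" and top.effect == pytest.approx(3.0)

    def test_constant_signal_flags_nothing(self):
        group, signals, aln, _ = self._planted()
        flat = {a: 8.0 for a in signals}
        assoc = residue_association(group, flat, aln)
        assert not assoc["flagged"].any()

    def test_relabeling_invariance(self):
        group, signals, aln, _ = self._planted()
        a1 = residue_association(group, signals, aln)
        # permuting allergen labels together with their signals changes
        # nothing observable
        mapping = dict(zip(sorted(signals), reversed(sorted(signals))))
        group2 = type(group)(
            aligned_start=group.aligned_start,
            k=group.k,
            members={
                seq: [mapping[a] for a in mem]
                for seq, mem in group.members.items()
            },
        )
        signals2 = {mapping[a]: v for a, v in signals.items()}
        a2 = residue_association(group2, signals2, _RelabeledAln(aln, mapping))
        pd.testing.assert_frame_equal(a1, a2)

    def test_too_few_representatives_rejected(self):
        _, _, tiles = _family_panel(n=3)
        group = group_homologs(tiles, aligned_start=10)  # identical family
        with pytest.raises(EpitopeError):
            residue_association(group, {"iso0": 1.0, "iso1": 1.0, "iso2": 1.0},
                                None)


class _RelabeledAln:
    def __init__(self, aln, mapping):
        self._aln = aln
        self._inverse = {v: k for k, v in mapping.items()}

    def residue_at(self, allergen_id, column):
        return self._aln.residue_at(self._inverse[allergen_id], column)


class TestIsoallergenContrasts:
    def _pair_setup(self, edits):
        panel, aln, tiles = _family_panel(n=2, length=70, seed=4, edits=edits)
        peptides = sorted(tiles["sequence"].unique())
        idx = pd.MultiIndex.from_tuples(
            [("s1", 1, "IgG")], names=["subject", "timepoint", "isotype"]
        )
        z = pd.DataFrame(0.0, index=idx, columns=peptides)
        return panel, tiles, z

    def test_identical_isoforms_never_discriminate(self):
        panel, tiles, z = self._pair_setup(edits=None)
        # light up one shared peptide: both isoforms carry it
        pep = tiles["sequence"].iloc[10]
        z.loc[:, pep] = 5.0
        from epitile.reactivity import call_reactive

        calls = call_reactive(z, tiles)
        out = isoallergen_contrasts(calls, z, tiles, ("iso0", "iso1"))
        assert not out["discriminating"].any()

    def test_planted_private_epitope_found_at_its_window(self):
        # C-terminal substitutions make iso1 peptides differ at starts 40+
        edits = {1: {55: "W", 60: "Y"}}
        panel, tiles, z = self._pair_setup(edits=edits)
        hot = tiles[
            (tiles.allergen_id == "iso1") & (tiles.start_local.isin([44, 46]))
        ]["sequence"]
        for pep in hot:
            z.loc[:, pep] = 5.0
        from epitile.reactivity import call_reactive

        calls = call_reactive(z, tiles)
        out = isoallergen_contrasts(calls, z, tiles, ("iso0", "iso1"))
        disc = out[out["discriminating"]]
        assert sorted(disc["aligned_start"]) == [44, 46]
        assert (disc["signal_difference"] < 0).all()  # iso1 brighter

    def test_antisymmetric_under_pair_swap(self):
        edits = {1: {55: "W"}}
        panel, tiles, z = self._pair_setup(edits=edits)
        pep = tiles[
            (tiles.allergen_id == "iso1") & (tiles.start_local == 45)
        ]["sequence"].iloc[0]
        z.loc[:, pep] = 5.0
        from epitile.reactivity import call_reactive

        calls = call_reactive(z, tiles)
        ab = isoallergen_contrasts(calls, z, tiles, ("iso0", "iso1"))
        ba = isoallergen_contrasts(calls, z, tiles, ("iso1", "iso0"))
        merged = ab.merge(
            ba, on=["subject", "timepoint", "isotype", "aligned_start"]
        )
        assert np.allclose(
            merged["signal_difference_x"], -merged["signal_difference_y"]
        )
        assert (merged["discriminating_x"] == merged["discriminating_y"]).all()

    def test_missing_pair_member_rejected(self):
        panel, tiles, z = self._pair_setup(edits=None)
        with pytest.raises(EpitopeError):
            isoallergen_contrasts(pd.DataFrame(), z, tiles, ("iso0", "nope"))


class TestUniqueKmerIndex:
    def test_demo_loop_epitope_unique_to_one_isoform(self, demo):
        panel, _ = demo
        index = unique_kmer_index(panel, k=9)
        assert index["LAAKSPADI"] == ["Gad m 1.0201"]

    def test_shared_kmer_carried_by_whole_panel(self):
        panel, _, _ = _family_panel(n=5)
        index = unique_kmer_index(panel, k=8)
        seq = panel["iso0"].sequence
        assert index[seq[:8]] == [f"iso{i}" for i in range(5)]

    def test_matches_bruteforce_substring_scan(self, demo):
        panel, _ = demo
        index = unique_kmer_index(panel, k=9)
        for kmer, carriers in list(index.items())[::37]:
            brute = sorted(
                r.allergen_id
                for r in panel.complete_records
                if kmer in r.sequence
            )
            assert carriers == brute

    def test_incomplete_records_excluded(self, demo):
        panel, _ = demo
        index = unique_kmer_index(panel, k=9)
        assert not any(
            "Onc m" in a for carriers in index.values() for a in carriers
        )
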