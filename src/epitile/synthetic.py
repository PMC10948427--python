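"""Synthetic serology generator with planted ground truth.

Emulates the structure of a tiled peptide-microarray study of a small
homologous allergen family: ~19 isoforms of a ~109-residue protein derived
from one base sequence by independent point substitutions; per-subject
stable epitope repertoires over 4 samplings with occasional induction
events; key-residue-dependent cross-reactivity (an epitope is carried only
by isoforms holding a required residue at one alignment column); and
multiplicative log-normal array noise (additive Gaussian noise on the log2
scale).

The effect model is log-additive: the log2 intensity of peptide p in
sample s is a baseline plus the summed affinities (log2 units) of the
subject's epitopes active at that timepoint whose window is fully
contained in an occurrence of p on a carrier isoform, plus N(0, noise_sd).

Every planted quantity is recorded in a :class:`SyntheticTruth` that
serialises losslessly to JSON, so pipeline outputs can be scored against
the truth (:func:`evaluate_recovery`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import MasterAlignment
from .epitope import group_homologs, residue_association
from .panel import AllergenPanel, AllergenRecord, tile_panel
from .reactivity import ReactivityMatrix, matrix_from_log2

AA = "ACDEFGHIKLMNPQRSTVWY"

# Study-scale defaults: family of 19 complete ~109-residue isoforms,
# 15 subjects sampled at 4 timepoints, epitope effects of 3 log2 units
# over a 0.5-sd log2 noise floor.
DEFAULT_N_ALLERGENS = 19
DEFAULT_LENGTH = 109
DEFAULT_SUBSTITUTION_RATE = 0.05
DEFAULT_N_SUBJECTS = 15
DEFAULT_TIMEPOINTS = (1, 2, 3, 4)
DEFAULT_EPITOPES_PER_SUBJECT = 3
DEFAULT_WINDOW_WIDTH = 9
DEFAULT_AFFINITY = 3.0
DEFAULT_NOISE_SD = 0.5
DEFAULT_BASELINE_LOG2 = 7.0
DEFAULT_INDUCTION_FRACTION = 0.25
DEFAULT_KEY_RESIDUE_FRACTION = 0.3
# isotype multipliers on the planted affinity: IgG carries the response,
# IgG4 a weaker parallel one, IgE essentially none (atopic, not
# food-allergic donors)
DEFAULT_ISOTYPE_MULTIPLIERS = {"IgG": 1.0, "IgG4": 0.6, "IgE": 0.0}


class SyntheticError(ValueError):
    pass


@dataclass
class PlantedEpitope:
    """One planted linear epitope of one subject."""

    subject: str
    window: tuple[int, int]  # aligned residue span, inclusive
    carriers: tuple[str, ...]  # isoforms that present the epitope
    key_column: int | None  # alignment column gating cross-reactivity
    required_residue: str | None
    affinity: float  # log2 units (IgG scale; multiplied per isotype)
    induction_timepoint: int | None  # None = present from baseline

    def active_at(self, timepoint: int) -> bool:
        return (
            self.induction_timepoint is None
            or timepoint >= self.induction_timepoint
        )


@dataclass
class SyntheticTruth:
    base_sequence: str
    mutations: dict[str, list[tuple[int, str, str]]]  # id -> (pos, old, new)
    epitopes: list[PlantedEpitope]
    timepoints: tuple[int, ...]
    isotype_multipliers: dict[str, float]
    noise_sd: float
    baseline_log2: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["mutations"] = {
            k: [tuple(m) for m in v] for k, v in d["mutations"].items()
        }
        d["epitopes"] = [
            PlantedEpitope(
                subject=e["subject"],
                window=tuple(e["window"]),
                carriers=tuple(e["carriers"]),
                key_column=e["key_column"],
                required_residue=e["required_residue"],
                affinity=e["affinity"],
                induction_timepoint=e["induction_timepoint"],
            )
            for e in d["epitopes"]
        ]
        d["timepoints"] = tuple(d["timepoints"])
        return cls(**d)


def generate_panel(
    n_allergens: int = DEFAULT_N_ALLERGENS,
    length: int = DEFAULT_LENGTH,
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE,
    seed: int = 0,
) -> tuple[AllergenPanel, MasterAlignment, SyntheticTruth]:
    """Generate a gap-free homologous family by per-site substitution.

    A random base sequence is mutated independently per isoform at the
    given per-site rate; the alignment is the trivial identity mapping
    (all rows gap-free), so local and aligned coordinates coincide.  All
    substitutions are recorded in the returned truth.
    """
    if n_allergens < 2:
        raise SyntheticError("need at least 2 allergens")
    if length < 32:
        raise SyntheticError("family length must be >= 32")
    if not 0 <= substitution_rate <= 0.3:
        raise SyntheticError(
            f"substitution rate {substitution_rate} outside [0, 0.3]"
        )
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(AA), size=length))
    records = []
    mutations: dict[str, list[tuple[int, str, str]]] = {}
    for i in range(n_allergens):
        aid = f"syn 1.{i + 1:04d}"
        seq = list(base)
        muts = []
        hit = rng.random(length) < substitution_rate
        for pos in np.flatnonzero(hit):
            old = seq[pos]
            new = rng.choice([a for a in AA if a != old])
            seq[pos] = new
            muts.append((int(pos) + 1, old, new))
        records.append(
            AllergenRecord(
                allergen_id=aid,
                species=f"Synthecus fictus {i + 1}",
                sequence="".join(seq),
            )
        )
        mutations[aid] = muts
    panel = AllergenPanel(records)
    alignment = MasterAlignment({r.allergen_id: r.sequence for r in records})
    truth = SyntheticTruth(
        base_sequence=base,
        mutations=mutations,
        epitopes=[],
        timepoints=DEFAULT_TIMEPOINTS,
        isotype_multipliers=dict(DEFAULT_ISOTYPE_MULTIPLIERS),
        noise_sd=DEFAULT_NOISE_SD,
        baseline_log2=DEFAULT_BASELINE_LOG2,
    )
    return panel, alignment, truth


def _eligible_key_columns(
    panel: AllergenPanel, min_class: int = 2
) -> dict[int, tuple[str, tuple[str, ...]]]:
    """Columns where consensus and non-consensus classes both have >= min_class.

    Returns column -> (consensus residue, carrier isoforms).  Only such
    columns can gate a key-residue epitope that a mean-difference
    attribution can recover.
    """
    out = {}
    records = panel.complete_records
    length = len(records[0].sequence)
    for col in range(1, length + 1):
        residues = {}
        for rec in records:
            residues.setdefault(rec.sequence[col - 1], []).append(
                rec.allergen_id
            )
        consensus = max(residues, key=lambda a: (len(residues[a]), a))
        n_cons = len(residues[consensus])
        if n_cons >= min_class and len(records) - n_cons >= min_class:
            out[col] = (consensus, tuple(residues[consensus]))
    return out


def simulate_subjects(
    panel: AllergenPanel,
    n_subjects: int = DEFAULT_N_SUBJECTS,
    epitopes_per_subject: int = DEFAULT_EPITOPES_PER_SUBJECT,
    induction_fraction: float = DEFAULT_INDUCTION_FRACTION,
    key_residue_fraction: float = DEFAULT_KEY_RESIDUE_FRACTION,
    window_width: int = DEFAULT_WINDOW_WIDTH,
    affinity: float = DEFAULT_AFFINITY,
    tile_k: int = 16,
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS,
    seed: int = 0,
) -> list[PlantedEpitope]:
    """Draw per-subject epitope repertoires with known truth.

    Windows are drawn without replacement per subject, interior to the
    sequence and mutually separated so that no tile spans two windows.  A
    ``key_residue_fraction`` of epitopes is gated by a family-variable
    column inside the window (carriers = isoforms with the consensus
    residue there); the rest are carried by the whole family.  An
    ``induction_fraction`` of epitopes switches on at a random timepoint
    >= the second sampling; the rest are present from baseline.
    """
    if n_subjects < 1 or epitopes_per_subject < 1:
        raise SyntheticError("subject and epitope counts must be positive")
    if window_width > tile_k:
        raise SyntheticError("window wider than a tile cannot be planted")
    rng = np.random.default_rng(seed)
    records = panel.complete_records
    length = len(records[0].sequence)
    all_ids = tuple(r.allergen_id for r in records)
    key_columns = _eligible_key_columns(panel)
    lo, hi = tile_k - window_width + 1, length - tile_k + 1
    n_slots = (hi - lo) // (tile_k + window_width)
    if epitopes_per_subject > n_slots:
        raise SyntheticError(
            f"{epitopes_per_subject} epitopes per subject exceed the "
            f"{n_slots} non-overlapping interior windows available"
        )
    sep = tile_k + window_width  # no tile may span two windows
    epitopes: list[PlantedEpitope] = []
    for i in range(n_subjects):
        subject = f"D{i + 1:02d}"
        placed = None
        # sequential placement can reach an infeasible corner; retry the
        # whole subject with fresh draws rather than giving up
        for _attempt in range(200):
            starts: list[int] = []
            chosen: list[tuple[int, int | None]] = []
            want_key = rng.random(epitopes_per_subject) < key_residue_fraction
            ok = True
            for j in range(epitopes_per_subject):
                feasible = [
                    a
                    for a in range(lo, hi + 1)
                    if all(abs(a - s) >= sep for s in starts)
                ]
                if not feasible:
                    ok = False
                    break
                key_candidates = [
                    (a, col)
                    for col in sorted(key_columns)
                    for a in range(col - window_width + 1, col + 1)
                    if lo <= a <= hi
                    and all(abs(a - s) >= sep for s in starts)
                ]
                if want_key[j] and key_candidates:
                    a, col = key_candidates[
                        int(rng.integers(len(key_candidates)))
                    ]
                else:
                    a, col = int(feasible[int(rng.integers(len(feasible)))]), None
                starts.append(a)
                chosen.append((a, col))
            if ok:
                placed = chosen
                break
        if placed is None:
            raise SyntheticError(
                "could not place windows; reduce epitopes_per_subject"
            )
        for a, col in placed:
            if col is not None:
                required, carriers = key_columns[col]
            else:
                required, carriers = None, all_ids
            induced = None
            if rng.random() < induction_fraction and len(timepoints) > 1:
                induced = int(rng.choice(timepoints[1:]))
            epitopes.append(
                PlantedEpitope(
                    subject=subject,
                    window=(a, a + window_width - 1),
                    carriers=carriers,
                    key_column=col,
                    required_residue=required,
                    affinity=float(affinity),
                    induction_timepoint=induced,
                )
            )
    return epitopes


def elevated_peptides(
    epitope: PlantedEpitope, tiles: pd.DataFrame
) -> set[str]:
    """Unique peptides whose occurrence on a carrier contains the window."""
    a, b = epitope.window
    k = len(tiles["sequence"].iloc[0])
    sub = tiles[
        tiles["allergen_id"].isin(epitope.carriers)
        & (tiles["start_aligned"] <= a)
        & (tiles["start_aligned"] + k - 1 >= b)
    ]
    return set(sub["sequence"])


def simulate_intensities(
    tiles: pd.DataFrame,
    epitopes: list[PlantedEpitope],
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS,
    isotypes: tuple[str, ...] = ("IgG",),
    isotype_multipliers: dict[str, float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    baseline_log2: float = DEFAULT_BASELINE_LOG2,
    missing: set[tuple[str, int]] | None = None,
    seed: int = 0,
) -> ReactivityMatrix:
    """Simulate the array readout for every subject/timepoint/isotype.

    ``missing`` optionally lists (subject, timepoint) samplings that were
    never collected (they are absent from the matrix, not zero-filled).
    """
    if noise_sd <= 0:
        raise SyntheticError("noise_sd must be > 0")
    if isotype_multipliers is None:
        isotype_multipliers = DEFAULT_ISOTYPE_MULTIPLIERS
    rng = np.random.default_rng(seed)
    peptides = sorted(tiles["sequence"].unique())
    pep_pos = {p: i for i, p in enumerate(peptides)}
    subjects = sorted({e.subject for e in epitopes})
    by_subject: dict[str, list[PlantedEpitope]] = {s: [] for s in subjects}
    for e in epitopes:
        by_subject[e.subject].append(e)
    elevated = {id(e): elevated_peptides(e, tiles) for e in epitopes}
    missing = missing or set()
    rows = []
    keys = []
    for subject in subjects:
        for tp in timepoints:
            if (subject, tp) in missing:
                continue
            effect = np.zeros(len(peptides))
            for e in by_subject[subject]:
                if e.active_at(tp):
                    for pep in elevated[id(e)]:
                        effect[pep_pos[pep]] += e.affinity
            for isotype in isotypes:
                mult = isotype_multipliers.get(isotype, 0.0)
                noise = rng.normal(0.0, noise_sd, size=len(peptides))
                rows.append(baseline_log2 + mult * effect + noise)
                keys.append((subject, tp, isotype))
    log2 = pd.DataFrame(
        np.array(rows),
        index=pd.MultiIndex.from_tuples(
            keys, names=["subject", "timepoint", "isotype"]
        ),
        columns=peptides,
    )
    return matrix_from_log2(log2)


def write_intensity_tsv(matrix: ReactivityMatrix, path: str | Path) -> None:
    """Export a matrix in the long intensity-TSV contract."""
    long = (
        matrix.raw.stack()
        .rename("intensity")
        .reset_index()
        .rename(columns={"level_3": "peptide"})
    )
    long.columns = ["subject", "timepoint", "isotype", "peptide", "intensity"]
    long.to_csv(path, sep="\t", index=False, float_format="%.6f")


def simulate_cohort(
    seed: int = 0,
    n_allergens: int = DEFAULT_N_ALLERGENS,
    length: int = DEFAULT_LENGTH,
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE,
    n_subjects: int = DEFAULT_N_SUBJECTS,
    epitopes_per_subject: int = DEFAULT_EPITOPES_PER_SUBJECT,
    induction_fraction: float = DEFAULT_INDUCTION_FRACTION,
    key_residue_fraction: float = DEFAULT_KEY_RESIDUE_FRACTION,
    affinity: float = DEFAULT_AFFINITY,
    noise_sd: float = DEFAULT_NOISE_SD,
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS,
    isotypes: tuple[str, ...] = ("IgG",),
    tile_k: int = 16,
):
    """One-call end-to-end simulation at the default study scale.

    Returns ``(panel, alignment, tiles, truth, matrix)``.  Sub-seeds for
    the three stages are derived deterministically from ``seed``.
    """
    panel, alignment, truth = generate_panel(
        n_allergens, length, substitution_rate, seed=seed
    )
    epitopes = simulate_subjects(
        panel,
        n_subjects=n_subjects,
        epitopes_per_subject=epitopes_per_subject,
        induction_fraction=induction_fraction,
        key_residue_fraction=key_residue_fraction,
        affinity=affinity,
        tile_k=tile_k,
        timepoints=timepoints,
        seed=seed + 1,
    )
    tiles = tile_panel(panel, k=tile_k, alignment=alignment)
    matrix = simulate_intensities(
        tiles,
        epitopes,
        timepoints=timepoints,
        isotypes=isotypes,
        noise_sd=noise_sd,
        seed=seed + 2,
    )
    truth.epitopes = epitopes
    truth.timepoints = tuple(timepoints)
    truth.noise_sd = noise_sd
    return panel, alignment, tiles, truth, matrix


def evaluate_recovery(
    truth: SyntheticTruth,
    tiles: pd.DataFrame,
    calls: pd.DataFrame,
    induced_events: pd.DataFrame | None = None,
    matrix: ReactivityMatrix | None = None,
    alignment: MasterAlignment | None = None,
    isotype: str = "IgG",
) -> dict[str, float]:
    """Score pipeline outputs against the planted truth.

    Returns precision of confirmed calls, planted-window recall, key-residue
    attribution accuracy (when ``matrix`` and ``alignment`` are given),
    and induction recall / false-event count (when ``induced_events`` is
    given).  All fractions lie in [0, 1].
    """
    mult = truth.isotype_multipliers.get(isotype, 0.0)
    active_epitopes = [e for e in truth.epitopes if mult > 0]
    elevated = {id(e): elevated_peptides(e, tiles) for e in active_epitopes}
    by_subject: dict[str, list[PlantedEpitope]] = {}
    for e in active_epitopes:
        by_subject.setdefault(e.subject, []).append(e)

    metrics: dict[str, float] = {}
    confirmed = calls[(calls["confirmed"]) & (calls["isotype"] == isotype)]
    if len(confirmed):
        tp = 0
        for row in confirmed.itertuples(index=False):
            truthy = any(
                e.active_at(row.timepoint) and row.peptide in elevated[id(e)]
                for e in by_subject.get(row.subject, [])
            )
            tp += bool(truthy)
        metrics["confirmed_precision"] = tp / len(confirmed)
    else:
        metrics["confirmed_precision"] = float("nan")

    recovered = 0
    for e in active_epitopes:
        hit = any(
            row.peptide in elevated[id(e)] and e.active_at(row.timepoint)
            for row in confirmed.itertuples(index=False)
            if row.subject == e.subject
        )
        recovered += bool(hit)
    metrics["window_recall"] = (
        recovered / len(active_epitopes) if active_epitopes else float("nan")
    )

    if matrix is not None and alignment is not None:
        key_eps = [e for e in active_epitopes if e.key_column is not None]
        correct = 0
        scored = 0
        for e in key_eps:
            sample = (e.subject, max(truth.timepoints), isotype)
            if sample not in matrix.log2.index:
                continue
            group = group_homologs(tiles, aligned_start=e.window[0])
            signals = {}
            for seq, members in group.members.items():
                v = matrix.log2.loc[sample].get(seq)
                if v is not None and not pd.isna(v):
                    for a in members:
                        signals[a] = float(v)
            try:
                assoc = residue_association(group, signals, alignment)
            except Exception:
                continue
            scored += 1
            if (
                not assoc.empty
                and bool(assoc.iloc[0]["flagged"])
                and int(assoc.iloc[0]["column"]) == e.key_column
            ):
                correct += 1
        metrics["key_residue_accuracy"] = (
            correct / scored if scored else float("nan")
        )
        metrics["n_key_epitopes"] = float(scored)

    if induced_events is not None:
        truth_induced = [
            e for e in active_epitopes if e.induction_timepoint is not None
        ]
        events = induced_events[induced_events["isotype"] == isotype]
        hit = 0
        for e in truth_induced:
            a, b = e.window
            match = events[
                (events["subject"] == e.subject)
                & (events["induced_timepoint"] == e.induction_timepoint)
            ]
            overlap = any(
                not (row.window[1] < a or row.window[0] > b)
                for row in match.itertuples(index=False)
            )
            hit += bool(overlap)
        metrics["induction_recall"] = (
            hit / len(truth_induced) if truth_induced else float("nan")
        )
        false_events = 0
        seen = set()
        for row in events.itertuples(index=False):
            key = (row.subject, row.allergen_id, row.aligned_start_min)
            matched = any(
                e.subject == row.subject
                and e.induction_timepoint is not None
                and not (row.window[1] < e.window[0] or row.window[0] > e.window[1])
                for e in truth_induced
            )
            if not matched and (row.subject, row.aligned_start_min) not in seen:
                # count distinct false windows once across isoforms
                false_events += 1
                seen.add((row.subject, row.aligned_start_min))
        metrics["false_induction_events"] = float(false_events)
        metrics["n_truth_induced"] = float(len(truth_induced))
    return metrics
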