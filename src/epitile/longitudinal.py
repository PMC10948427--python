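"""Longitudinal stability and induced-reactivity detection.

Antibody repertoires of adults are expected to be largely stable across
samplings: log2 profiles of the same subject at different timepoints should
correlate more strongly than profiles of different subjects.  Occasionally,
however, a new specificity arises mid-study — a peptide region silent at
every earlier timepoint that becomes strongly reactive later.  Induction is
deliberately asymmetric: a signal merely growing from an already-elevated
baseline is not an induction event.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reactivity import ReactivityMatrix


class LongitudinalError(ValueError):
    pass


@dataclass
class StabilitySummary:
    within_subject: list[float] = field(default_factory=list)
    between_subject: list[float] = field(default_factory=list)

    @property
    def mean_within(self) -> float:
        return float(np.mean(self.within_subject)) if self.within_subject else float("nan")

    @property
    def mean_between(self) -> float:
        return float(np.mean(self.between_subject)) if self.between_subject else float("nan")


def stability_correlation(
    matrix: ReactivityMatrix | pd.DataFrame,
    isotype: str | None = None,
    min_shared: int = 3,
) -> StabilitySummary:
    """Pearson correlations of log2 profiles, split within/between subjects.

    Every pair of samples of the same isotype is correlated over their
    shared measured peptides; pairs of the same subject (distinct
    timepoints) populate the within-subject list, pairs of different
    subjects the between-subject list.  Pairs sharing fewer than
    ``min_shared`` peptides are skipped with a warning.
    """
    log2 = matrix.log2 if isinstance(matrix, ReactivityMatrix) else matrix
    if isotype is not None:
        log2 = log2[log2.index.get_level_values("isotype") == isotype]
    summary = StabilitySummary()
    for sa, sb in itertools.combinations(log2.index, 2):
        if sa[2] != sb[2]:  # isotype must match
            continue
        xa, xb = log2.loc[sa], log2.loc[sb]
        ok = xa.notna() & xb.notna()
        if ok.sum() < min_shared:
            warnings.warn(
                f"samples {sa} and {sb} share only {int(ok.sum())} peptides; "
                "pair skipped",
                stacklevel=2,
            )
            continue
        a, b = xa[ok].to_numpy(), xb[ok].to_numpy()
        if a.std() == 0 or b.std() == 0:
            continue
        r = float(stats.pearsonr(a, b).statistic)
        if sa[0] == sb[0]:
            summary.within_subject.append(r)
        else:
            summary.between_subject.append(r)
    return summary


@dataclass
class InducedReactivity:
    """One merged induction event: a peptide window silent early, bright later."""

    subject: str
    isotype: str
    allergen_id: str
    aligned_start_min: int
    aligned_start_max: int
    window: tuple[int, int]  # aligned residue span covered by the tiles
    induced_timepoint: int
    max_z: float
    log2_fold_increase: float
    n_peptides: int
    support: str

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["window"] = list(self.window)
        return d


def detect_induced(
    z: pd.DataFrame,
    log2: pd.DataFrame,
    tiles: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    z_low: float = 1.0,
    z_cut: float = 3.0,
    fold_min: float = 2.0,
    require_confirmed: bool = True,
    merge_gap: int | None = None,
) -> pd.DataFrame:
    """Detect reactivities induced during the study.

    A peptide is induced for a subject/isotype at timepoint t when every
    earlier observed timepoint sits below ``z_low`` (true baseline
    silence), t reaches ``z_cut``, and the log2 intensity rises by at least
    ``fold_min`` over the mean baseline.  With ``require_confirmed`` the
    induced call must also be a confirmed reactive call (support tags are
    carried over), which suppresses one-off artifact spots.  Induced
    peptides are expanded to their tile occurrences and merged into
    aligned-start windows per allergen (default merge gap: overlapping
    tiles, k − 1).

    Timepoints after the induced one are ignored, so appending a later
    all-quiet sample never removes an event.
    """
    k = len(tiles["sequence"].iloc[0])
    if merge_gap is None:
        merge_gap = k - 1
    confirmed_support: dict[tuple, str] = {}
    if calls is not None and not calls.empty:
        for row in calls.itertuples(index=False):
            if row.confirmed:
                confirmed_support[
                    (row.subject, int(row.timepoint), row.isotype, row.peptide)
                ] = row.support
    occ: dict[str, list[tuple[str, int, int]]] = {}
    for row in tiles.itertuples(index=False):
        occ.setdefault(row.sequence, []).append(
            (row.allergen_id, int(row.start_local), int(row.start_aligned))
        )

    # per subject/isotype: peptide -> (induced timepoint, max z, fold)
    induced_peps: dict[tuple[str, str], dict[str, tuple[int, float, float, str]]] = {}
    grouped = z.groupby(level=["subject", "isotype"], sort=False)
    for (subject, isotype), zg in grouped:
        tps = sorted(zg.index.get_level_values("timepoint").unique())
        if len(tps) < 2:
            continue
        zt = zg.droplevel(["subject", "isotype"]).sort_index()
        lt = (
            log2.loc[zg.index]
            .droplevel(["subject", "isotype"])
            .sort_index()
        )
        for pep in zt.columns:
            series = zt[pep].dropna()
            if len(series) < 2:
                continue
            obs_tps = list(series.index)
            for i, t in enumerate(obs_tps):
                if i == 0:
                    continue  # needs at least one earlier observation
                earlier = series.iloc[:i]
                if series.loc[t] >= z_cut and (earlier < z_low).all():
                    fold = float(
                        lt.loc[t, pep] - lt.loc[earlier.index, pep].mean()
                    )
                    if fold < fold_min:
                        break
                    key = (subject, int(t), isotype, pep)
                    if require_confirmed and key not in confirmed_support:
                        break
                    induced_peps.setdefault((subject, isotype), {})[pep] = (
                        int(t),
                        float(series.loc[t]),
                        fold,
                        confirmed_support.get(key, ""),
                    )
                    break
                if series.loc[t] >= z_low:
                    break  # baseline contaminated; later rises are increases

    # expand to occurrences and merge into aligned windows per allergen
    records = []
    for (subject, isotype), peps in induced_peps.items():
        per_allergen: dict[str, list[tuple[int, str]]] = {}
        for pep in peps:
            for allergen, _s_local, s_aligned in occ.get(pep, []):
                per_allergen.setdefault(allergen, []).append((s_aligned, pep))
        for allergen, start_peps in per_allergen.items():
            start_peps.sort()
            clusters: list[list[tuple[int, str]]] = []
            for s, pep in start_peps:
                if clusters and s - clusters[-1][-1][0] <= merge_gap:
                    clusters[-1].append((s, pep))
                else:
                    clusters.append([(s, pep)])
            for cluster in clusters:
                cluster_peps = {pep for _, pep in cluster}
                tp = min(peps[p][0] for p in cluster_peps)
                max_z = max(peps[p][1] for p in cluster_peps)
                fold = max(peps[p][2] for p in cluster_peps)
                tags = sorted(
                    {t for p in cluster_peps for t in peps[p][3].split(",") if t}
                )
                s_min, s_max = cluster[0][0], cluster[-1][0]
                records.append(
                    InducedReactivity(
                        subject=subject,
                        isotype=isotype,
                        allergen_id=allergen,
                        aligned_start_min=s_min,
                        aligned_start_max=s_max,
                        window=(s_min, s_max + k - 1),
                        induced_timepoint=tp,
                        max_z=max_z,
                        log2_fold_increase=fold,
                        n_peptides=len(cluster_peps),
                        support=",".join(tags),
                    ).to_dict()
                )
    columns = [
        "subject", "isotype", "allergen_id", "aligned_start_min",
        "aligned_start_max", "window", "induced_timepoint", "max_z",
        "log2_fold_increase", "n_peptides", "support",
    ]
    return pd.DataFrame(records, columns=columns)
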