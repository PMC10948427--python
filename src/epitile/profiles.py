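"""Reactivity-profile similarity: PCA and clustered-heatmap preparation.

Two complementary views of the same log2 matrix: samples as observations
over the unique-peptide set (do samples of one subject group together?),
and allergens as observations over (sample, aligned start) features within
a fixed alignment window (which isoforms are recognised alike?).  Heatmap
preparation clusters rows (samples) only — columns stay in linear tiling
order so epitope positions remain readable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .reactivity import ReactivityMatrix

DEFAULT_ALIGNED_RANGE = (9, 95)


class ProfileError(ValueError):
    pass


def sample_profile_matrix(
    matrix: ReactivityMatrix | pd.DataFrame,
    peptides: list[str] | None = None,
) -> pd.DataFrame:
    """Samples × peptides log2 matrix restricted to a peptide subset."""
    log2 = matrix.log2 if isinstance(matrix, ReactivityMatrix) else matrix
    if peptides is None:
        return log2.copy()
    if len(peptides) == 0:
        raise ProfileError("empty peptide subset")
    unknown = [p for p in peptides if p not in log2.columns]
    if unknown:
        raise ProfileError(
            f"{len(unknown)} peptides not in matrix, e.g. {unknown[0]!r}"
        )
    return log2.loc[:, list(peptides)].copy()


def allergen_profile_matrix(
    matrix: ReactivityMatrix | pd.DataFrame,
    tiles: pd.DataFrame,
    aligned_range: tuple[int, int] = DEFAULT_ALIGNED_RANGE,
) -> pd.DataFrame:
    """Allergens × (sample, aligned start) log2 matrix.

    Cell value is the signal of the allergen's tile starting at that
    alignment position in that sample.  An allergen lacking a tile at a
    start (gap region, or the start is outside its row) leaves the cell
    missing; columns containing any missing value are dropped so every
    allergen is compared over the same features.
    """
    log2 = matrix.log2 if isinstance(matrix, ReactivityMatrix) else matrix
    lo, hi = aligned_range
    if lo > hi or lo < 1:
        raise ProfileError(f"bad aligned range {aligned_range}")
    max_start = int(tiles["start_aligned"].max())
    if lo > max_start:
        raise ProfileError(
            f"aligned range {aligned_range} outside tiled region (max start "
            f"{max_start})"
        )
    sub = tiles[(tiles["start_aligned"] >= lo) & (tiles["start_aligned"] <= hi)]
    allergens = sorted(tiles["allergen_id"].unique())
    starts = sorted(sub["start_aligned"].unique())
    tile_at = {
        (row.allergen_id, row.start_aligned): row.sequence
        for row in sub.itertuples(index=False)
    }
    columns = pd.MultiIndex.from_tuples(
        [(sample, s) for sample in log2.index for s in starts],
        names=["sample", "aligned_start"],
    )
    data = np.full((len(allergens), len(columns)), np.nan)
    for i, allergen in enumerate(allergens):
        for j, (sample, s) in enumerate(columns):
            pep = tile_at.get((allergen, s))
            if pep is not None and pep in log2.columns:
                data[i, j] = log2.loc[sample, pep]
    out = pd.DataFrame(data, index=pd.Index(allergens, name="allergen_id"), columns=columns)
    return out.dropna(axis=1, how="any")


@dataclass
class PcaResult:
    scores: pd.DataFrame  # observations × components
    loadings: pd.DataFrame  # features × components
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(profile: pd.DataFrame) -> PcaResult:
    """Principal component analysis by SVD of the column-centered matrix.

    Scores are the projections of observations, loadings the orthonormal
    feature directions, explained fractions the normalised squared singular
    values.  Sign convention: within each component the largest-magnitude
    loading is positive, which makes the factorisation deterministic.
    """
    if profile.shape[0] < 2 or profile.shape[1] < 2:
        raise ProfileError("PCA needs at least 2 observations and 2 features")
    X = profile.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ProfileError("PCA input contains missing values")
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float((Xc**2).sum())
    if total_var == 0:
        raise ProfileError("constant matrix: zero variance, PCA undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix signs: largest-|loading| entry of each component positive
    for j in range(len(S)):
        i_star = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_star] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    n_comp = int((S > 1e-12 * S[0]).sum()) if S[0] > 0 else 0
    comp_names = [f"PC{j + 1}" for j in range(len(S))]
    scores = pd.DataFrame(U * S, index=profile.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=profile.columns, columns=comp_names)
    explained = (S**2) / (S**2).sum()
    return PcaResult(scores, loadings, explained)


@dataclass
class HeatmapSpec:
    """Row-clustered heatmap layout: samples reordered, peptides left linear."""

    row_order: list  # sample keys, dendrogram leaf order
    column_order: list  # peptides in linear tiling order
    values: pd.DataFrame  # log2 layer, rows reordered
    linkage: np.ndarray  # scipy linkage record over rows


def cluster_order(
    sample_matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
) -> HeatmapSpec:
    """Agglomeratively cluster samples (rows) for heatmap display.

    Columns are never clustered: they stay in the order given, which for a
    tile matrix is the linear order along the allergen.  Missing cells are
    not allowed (subset the matrix first).
    """
    if sample_matrix.shape[0] < 2:
        raise ProfileError("clustering needs at least 2 samples")
    X = sample_matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ProfileError("clustering input contains missing values")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    leaves = hierarchy.leaves_list(Z)
    row_order = [sample_matrix.index[i] for i in leaves]
    return HeatmapSpec(
        row_order=row_order,
        column_order=list(sample_matrix.columns),
        values=sample_matrix.iloc[leaves],
        linkage=Z,
    )
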