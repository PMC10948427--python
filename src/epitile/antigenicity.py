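"""Kolaskar–Tongaonkar antigenic-propensity prediction of linear B-cell epitopes.

The method slides a window over the sequence, averaging an empirical
per-residue antigenic propensity scale; runs of residues whose windowed
average exceeds a threshold are reported as predicted antigenic segments.
The threshold follows the common web-tool convention: the mean of the
defined windowed values for the protein at hand (overridable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Per-residue antigenic propensity values from the original Kolaskar &
# Tongaonkar scale (FEBS Lett. 276:172-174, 1990), as used by the common
# antibody-epitope prediction web tools.
KOLASKAR_TONGAONKAR_SCALE: dict[str, float] = {
    "A": 1.064, "R": 0.873, "N": 0.776, "D": 0.866, "C": 1.412,
    "Q": 1.015, "E": 0.851, "G": 0.874, "H": 1.105, "I": 1.152,
    "L": 1.250, "K": 0.930, "M": 0.826, "F": 1.091, "P": 1.064,
    "S": 1.012, "T": 0.909, "W": 0.893, "Y": 1.161, "V": 1.383,
}


class AntigenicityError(ValueError):
    pass


@dataclass
class AntigenicityProfile:
    allergen_id: str
    propensity: np.ndarray  # NaN at flank residues with no full window
    predicted_segments: list[tuple[int, int]]  # 1-based inclusive


def antigenic_propensity(sequence: str, window: int = 7) -> np.ndarray:
    """Windowed mean antigenic propensity per residue.

    Value at residue i (0-based array, 1-based biology) is the mean scale
    value over the ``window`` residues centred on i; the first and last
    ``(window - 1) // 2`` residues carry NaN since no full window fits.
    """
    if window < 1 or window % 2 == 0:
        raise AntigenicityError("window must be a positive odd integer")
    if len(sequence) < window:
        raise AntigenicityError(
            f"sequence length {len(sequence)} shorter than window {window}"
        )
    try:
        values = np.array(
            [KOLASKAR_TONGAONKAR_SCALE[c] for c in sequence.upper()]
        )
    except KeyError as exc:
        raise AntigenicityError(f"unknown residue {exc.args[0]!r}") from None
    half = (window - 1) // 2
    out = np.full(len(sequence), np.nan)
    # moving average via cumulative sum
    csum = np.concatenate(([0.0], np.cumsum(values)))
    out[half : len(sequence) - half] = (csum[window:] - csum[:-window]) / window
    return out


def predict_antigenic_segments(
    propensity: np.ndarray,
    threshold: float | None = None,
    min_length: int = 6,
) -> list[tuple[int, int]]:
    """Maximal runs of residues whose propensity exceeds the threshold.

    ``threshold`` defaults to the mean of the defined (non-NaN) propensity
    values of this protein.  Runs shorter than ``min_length`` are dropped.
    Returned segments are 1-based inclusive, disjoint and sorted.
    """
    propensity = np.asarray(propensity, dtype=float)
    defined = ~np.isnan(propensity)
    if not defined.any():
        raise AntigenicityError("propensity profile has no defined values")
    if threshold is None:
        threshold = float(np.nanmean(propensity))
    above = defined & (propensity > threshold)
    segments: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_length:
                segments.append((start + 1, i))
            start = None
    if start is not None and len(above) - start >= min_length:
        segments.append((start + 1, len(above)))
    return segments


def profile_allergen(
    allergen_id: str,
    sequence: str,
    window: int = 7,
    threshold: float | None = None,
    min_length: int = 6,
) -> AntigenicityProfile:
    """Convenience wrapper: propensity plus predicted segments for one record."""
    prop = antigenic_propensity(sequence, window=window)
    segs = predict_antigenic_segments(prop, threshold=threshold, min_length=min_length)
    return AntigenicityProfile(allergen_id, prop, segs)
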