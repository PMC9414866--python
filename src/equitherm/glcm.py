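"""Entropy-related gray level co-occurrence matrix (GLCM) texture features.

The three Haralick-family entropy features — SumEntrp, Entropy and
DifEntrp — serve as the comparison baseline for the slope-similarity
selection criterion.  The co-occurrence matrix itself is accumulated by
:func:`skimage.feature.graycomatrix`; the entropy features and the
diagonal/antidiagonal marginals are computed here.

Defaults: 64 gray levels (uniform binning of [0, 255]), offset distance
1, four directions (0°, 45°, 90°, 135°) averaged after per-direction
normalization, symmetric accumulation, natural logarithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .errors import DimensionError, ParameterError

__all__ = ["CooccurrenceMatrix", "glcm", "entropy_features", "GLCM_FEATURES", "quantize"]

DEFAULT_ANGLES = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)

#: Feature names emitted by the extraction stage, in a stable order.
GLCM_FEATURES = ("SumEntrp", "Entropy", "DifEntrp")


@dataclass
class CooccurrenceMatrix:
    """Direction-averaged co-occurrence probabilities and marginals.

    ``P[i, j]`` is the probability of gray-level pair (i, j); ``p_sum``
    holds the diagonal marginal p_{x+y}(k) for k = 0..2L-2 (sum of
    indices) and ``p_diff`` the antidiagonal marginal p_{x-y}(k) for
    k = |i - j| = 0..L-1.
    """

    P: np.ndarray
    levels: int
    offsets: tuple
    symmetric: bool
    p_sum: np.ndarray
    p_diff: np.ndarray


def quantize(patch: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin 8-bit intensities into ``levels`` gray levels."""
    x = np.asarray(patch)
    if x.size == 0:
        raise DimensionError("empty patch")
    if np.any(x < 0) or np.any(x > 255):
        raise ParameterError("patch values must lie in [0, 255]")
    return (x.astype(np.int64) * levels) // 256


def _marginals(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    L = P.shape[0]
    idx = np.arange(L)
    sums = idx[:, None] + idx[None, :]
    diffs = np.abs(idx[:, None] - idx[None, :])
    p_sum = np.bincount(sums.ravel(), weights=P.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(diffs.ravel(), weights=P.ravel(), minlength=L)
    return p_sum, p_diff


def glcm(
    patch: np.ndarray,
    levels: int = 64,
    distance: int = 1,
    angles: tuple = DEFAULT_ANGLES,
    symmetric: bool = True,
) -> CooccurrenceMatrix:
    """Direction-averaged, normalized gray level co-occurrence matrix.

    Each direction's count matrix is normalized to probabilities before
    averaging, so directions with unequal pair counts contribute equally.
    """
    q = quantize(patch, levels).astype(np.uint8)
    if q.ndim != 2:
        raise DimensionError(f"patch must be 2-D, got shape {q.shape}")
    counts = graycomatrix(
        q, distances=[distance], angles=list(angles), levels=levels, symmetric=symmetric
    ).astype(float)[:, :, 0, :]
    totals = counts.sum(axis=(0, 1))
    if np.any(totals == 0):
        raise DimensionError("patch too small for the requested offsets")
    P = (counts / totals).mean(axis=2)
    p_sum, p_diff = _marginals(P)
    offsets = tuple(
        (int(round(distance * math.sin(a))), int(round(distance * math.cos(a))))
        for a in angles
    )
    return CooccurrenceMatrix(
        P=P, levels=levels, offsets=offsets, symmetric=symmetric, p_sum=p_sum, p_diff=p_diff
    )


def _shannon(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def entropy_features(C: CooccurrenceMatrix) -> dict[str, float]:
    """The three entropy-type GLCM features, in nats (0·ln 0 = 0).

    Entropy = -sum P(i,j) ln P(i,j); SumEntrp and DifEntrp are the same
    functional applied to the diagonal and antidiagonal marginals.
    """
    return {
        "SumEntrp": _shannon(C.p_sum),
        "Entropy": _shannon(C.P.ravel()),
        "DifEntrp": _shannon(C.p_diff),
    }
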