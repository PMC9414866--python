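"""Bidimensional entropy measures for image texture irregularity.

Five measures quantifying the irregularity/complexity of a 2-D intensity
patch, each computed directly on the pixel matrix:

* :func:`sampen2d` — sample entropy: negative log conditional probability
  that (m+1)x(m+1) windows match within tolerance ``r`` given that their
  m x m sub-windows match.
* :func:`fuzzen2d` — fuzzy entropy: same construction with a continuous
  exponential similarity membership ``exp(-d^n / r)`` on mean-centred
  windows instead of a hard threshold.
* :func:`permen2d` — permutation entropy: Shannon entropy of ordinal
  (rank-order) patterns of dn x dm windows.
* :func:`dispen2d` — dispersion entropy: Shannon entropy of dispersion
  patterns after mapping pixels through the normal CDF into ``c`` classes.
* :func:`disten2d` — distribution entropy: Shannon entropy of the
  histogram (empirical PDF) of inter-window Chebyshev distances.

All window comparisons use the Chebyshev distance (maximum absolute
difference of corresponding pixels).  Windows are enumerated densely at
stride 1 in row-major order.  For the sample/fuzzy measures the m and
m+1 window sets are top-aligned on the same anchor grid, so the ratio of
match densities keeps its conditional-probability interpretation.

Each function returns ``(value, PatternStatistics)`` where the second
element exposes the intermediate quantities (match densities, pattern
probability vectors, distance histogram) for inspection and testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist
from scipy.special import ndtr

from .errors import DimensionError, ParameterError, UndefinedEntropyError

__all__ = [
    "EntropyParams",
    "PatternStatistics",
    "sampen2d",
    "fuzzen2d",
    "permen2d",
    "dispen2d",
    "disten2d",
    "ENTROPY_MEASURES",
]

# anchor-row block size for pairwise-distance passes; bounds peak memory
_CHUNK = 1024


@dataclass
class EntropyParams:
    """Tunable parameters of the five bidimensional entropy measures.

    Parameters
    ----------
    m : int
        Template window size for sample/fuzzy/distribution entropy:
        windows are m x m (and (m+1) x (m+1) for the conditional stage).
    r : float
        Similarity tolerance.  Interpreted as a fraction of the patch
        standard deviation when ``r_mode == "sd_fraction"`` (default), or
        in absolute intensity units when ``r_mode == "absolute"``.
    n : float
        Fuzzy membership exponent (sharpness of ``exp(-d^n / r)``).
    dn, dm : int
        Embedding window shape (rows x columns) for permutation and
        dispersion entropy.
    c : int
        Number of dispersion classes.
    M : int
        Number of histogram bins for distribution entropy.
    normalized : bool
        Divide permutation / dispersion / distribution entropy by the log
        of the number of possible patterns (or bins), mapping to [0, 1].
    paper_literal : bool
        For permutation and dispersion entropy, replace the normalization
        with the prefactor 1 / ((H - dn + 1)(W - dm + 1)) — i.e. divide
        the raw Shannon entropy by the window count.  Provided because
        both conventions appear in the bidimensional-entropy literature.
    fuzzy_center : bool
        Remove each window's own mean before fuzzy distance computation
        (the original 2-D fuzzy formulation).
    """

    m: int = 2
    r: float = 0.2
    r_mode: str = "sd_fraction"
    n: float = 2.0
    dn: int = 2
    dm: int = 2
    c: int = 3
    M: int = 512
    normalized: bool = True
    paper_literal: bool = False
    fuzzy_center: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError(f"m must be >= 1, got {self.m}")
        if self.r < 0:
            raise ParameterError(f"r must be >= 0, got {self.r}")
        if self.n <= 0:
            raise ParameterError(f"n must be > 0, got {self.n}")
        if self.dn * self.dm < 2:
            raise ParameterError("embedding window must have at least 2 cells")
        if self.c < 2:
            raise ParameterError(f"c must be >= 2, got {self.c}")
        if self.M < 2:
            raise ParameterError(f"M must be >= 2, got {self.M}")
        if self.r_mode not in ("sd_fraction", "absolute"):
            raise ParameterError(f"unknown r_mode {self.r_mode!r}")

    def resolve_r(self, patch: np.ndarray) -> float:
        """Tolerance in absolute intensity units for a given patch."""
        if self.r_mode == "absolute":
            return float(self.r)
        return float(self.r * np.asarray(patch, dtype=float).std())


@dataclass
class PatternStatistics:
    """Intermediate pattern statistics behind one entropy value.

    Only the fields relevant to the producing measure are filled: match
    densities ``phi_m``/``phi_m1`` (sample/fuzzy), the ordinal pattern
    probability vector (permutation), the dispersion pattern probability
    vector plus the patch mean/SD used by the normal-CDF mapping
    (dispersion), or the inter-window distance histogram (distribution).
    """

    phi_m: float | None = None
    phi_m1: float | None = None
    ordinal_probs: np.ndarray | None = None
    dispersion_probs: np.ndarray | None = None
    distance_hist: np.ndarray | None = None
    mu: float | None = None
    sigma: float | None = None
    n_windows: int | None = None
    extra: dict = field(default_factory=dict)


def _as_float_patch(patch: np.ndarray) -> np.ndarray:
    x = np.asarray(patch, dtype=float)
    if x.ndim != 2:
        raise DimensionError(f"patch must be 2-D, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("patch contains non-finite values")
    return x


def _windows(x: np.ndarray, h: int, w: int) -> np.ndarray:
    """All h x w windows at stride 1, flattened row-major: (A, h*w)."""
    v = sliding_window_view(x, (h, w))
    return v.reshape(-1, h * w)


def _pair_counts_sampen(wm1: np.ndarray, sub_idx: np.ndarray, r: float) -> tuple[int, int]:
    """Counts of ordered window pairs matching at stage m and m+1.

    ``wm1`` holds flattened (m+1)x(m+1) windows; the m-stage distance is
    the Chebyshev distance over the ``sub_idx`` columns (the top-left
    m x m sub-window), so both stages share one pairwise pass.
    Self-pairs are excluded.  Counts are for unordered pairs; ordered
    counts are exactly double and cancel in the ratio.
    """
    a = wm1.shape[0]
    wm = np.ascontiguousarray(wm1[:, sub_idx])
    count_m = 0
    count_m1 = 0
    for i0 in range(0, a, _CHUNK):
        i1 = min(i0 + _CHUNK, a)
        # only pairs (i, j) with j > i
        dm = cdist(wm[i0:i1], wm[i0:], metric="chebyshev")
        dm1 = cdist(wm1[i0:i1], wm1[i0:], metric="chebyshev")
        mask = np.triu(np.ones((i1 - i0, a - i0), dtype=bool), k=1)
        count_m += int(np.count_nonzero((dm <= r) & mask))
        count_m1 += int(np.count_nonzero((dm1 <= r) & mask))
    return count_m, count_m1


def sampen2d(patch: np.ndarray, params: EntropyParams | None = None) -> tuple[float, PatternStatistics]:
    """Two-dimensional sample entropy: ``-ln(Phi_{m+1} / Phi_m)``.

    ``Phi_m`` is the density of ordered window pairs whose Chebyshev
    distance is at most ``r``; windows of both stages are anchored on the
    same grid and self-matches are excluded.  Raises
    :class:`UndefinedEntropyError` when either density is zero.
    """
    params = params or EntropyParams()
    x = _as_float_patch(patch)
    m = params.m
    h, w = x.shape
    if h < m + 2 or w < m + 2:
        raise DimensionError(
            f"patch {h}x{w} must be strictly larger than {(m + 1)}x{(m + 1)} for m={m}"
        )
    r = params.resolve_r(x)
    wm1 = _windows(x, m + 1, m + 1)
    sub_idx = np.array([i * (m + 1) + j for i in range(m) for j in range(m)])
    count_m, count_m1 = _pair_counts_sampen(wm1, sub_idx, r)
    a = wm1.shape[0]
    total = a * (a - 1) // 2
    if count_m == 0 or count_m1 == 0:
        raise UndefinedEntropyError(
            f"sample entropy undefined: {count_m} m-matches, {count_m1} (m+1)-matches"
        )
    phi_m = count_m / total
    phi_m1 = count_m1 / total
    stats = PatternStatistics(phi_m=phi_m, phi_m1=phi_m1, n_windows=a)
    return -math.log(phi_m1 / phi_m), stats


def _phi_fuzzy(wins: np.ndarray, r: float, n: float) -> float:
    """Mean exponential membership over unordered window pairs."""
    a = wins.shape[0]
    total = 0.0
    for i0 in range(0, a, _CHUNK):
        i1 = min(i0 + _CHUNK, a)
        d = cdist(wins[i0:i1], wins[i0:], metric="chebyshev")
        memb = np.exp(-(d ** n) / r)
        mask = np.triu(np.ones((i1 - i0, a - i0), dtype=bool), k=1)
        total += float(memb[mask].sum())
    return total / (a * (a - 1) / 2)


def fuzzen2d(patch: np.ndarray, params: EntropyParams | None = None) -> tuple[float, PatternStatistics]:
    """Two-dimensional fuzzy entropy: ``-ln(Phi_{m+1}(r) / Phi_m(r))``.

    Windows are mean-centred (their own baseline removed) before the
    Chebyshev distance, and similarity is graded by the continuous
    membership ``exp(-d^n / r)`` rather than a hard threshold.
    """
    params = params or EntropyParams()
    x = _as_float_patch(patch)
    m = params.m
    h, w = x.shape
    if h < m + 2 or w < m + 2:
        raise DimensionError(
            f"patch {h}x{w} must be strictly larger than {(m + 1)}x{(m + 1)} for m={m}"
        )
    r = params.resolve_r(x)
    if np.ptp(x) == 0:
        # constant patch: every distance is 0 and every membership 1, so the
        # ratio is 1 for any r; short-circuit before the division by r
        a = (h - m) * (w - m)
        return 0.0, PatternStatistics(phi_m=1.0, phi_m1=1.0, n_windows=a)
    if r <= 0:
        raise ParameterError("fuzzy entropy requires r > 0 (membership divides by r)")
    wm1 = _windows(x, m + 1, m + 1)
    sub_idx = np.array([i * (m + 1) + j for i in range(m) for j in range(m)])
    wm = wm1[:, sub_idx]
    if params.fuzzy_center:
        wm = wm - wm.mean(axis=1, keepdims=True)
        wm1 = wm1 - wm1.mean(axis=1, keepdims=True)
    phi_m = _phi_fuzzy(np.ascontiguousarray(wm), r, params.n)
    phi_m1 = _phi_fuzzy(np.ascontiguousarray(wm1), r, params.n)
    stats = PatternStatistics(phi_m=phi_m, phi_m1=phi_m1, n_windows=wm1.shape[0])
    return -math.log(phi_m1 / phi_m), stats


def _ordinal_codes(wins: np.ndarray) -> np.ndarray:
    """Integer code of each window's ordinal pattern.

    The pattern is the stable argsort of the flattened window: equal
    pixels keep their row-major position order, so ties are deterministic.
    """
    k = wins.shape[1]
    order = np.argsort(wins, axis=1, kind="stable")
    radix = k ** np.arange(k)
    return order @ radix


def permen2d(patch: np.ndarray, params: EntropyParams | None = None) -> tuple[float, PatternStatistics]:
    """Two-dimensional permutation entropy over dn x dm ordinal patterns.

    Default output is the Shannon entropy of the pattern distribution
    normalized by ``ln((dn*dm)!)`` so a fully disordered image approaches
    1 and a monotone or constant image gives 0.  With
    ``paper_literal=True`` the raw Shannon entropy is instead divided by
    the number of windows.
    """
    params = params or EntropyParams()
    x = _as_float_patch(patch)
    dn, dm = params.dn, params.dm
    h, w = x.shape
    if h < dn or w < dm:
        raise DimensionError(f"patch {h}x{w} smaller than embedding window {dn}x{dm}")
    wins = _windows(x, dn, dm)
    codes = _ordinal_codes(wins)
    _, counts = np.unique(codes, return_counts=True)
    probs = counts / counts.sum()
    raw = float(-(probs * np.log(probs)).sum())
    k = dn * dm
    n_wins = wins.shape[0]
    if params.paper_literal:
        value = raw / n_wins
    elif params.normalized:
        value = raw / math.log(math.factorial(k))
    else:
        value = raw
    stats = PatternStatistics(ordinal_probs=probs, n_windows=n_wins)
    return value, stats


def dispen2d(patch: np.ndarray, params: EntropyParams | None = None) -> tuple[float, PatternStatistics]:
    """Two-dimensional dispersion entropy.

    Pixels are mapped through the normal CDF under the patch mean and SD,
    then discretized to classes ``z = round(c*v + 0.5)`` (half away from
    zero, clamped to 1..c).  The entropy of the dn x dm class-pattern
    distribution is normalized by ``ln(c^(dn*dm))`` by default.

    A zero-variance patch is degenerate: every pixel maps to the same
    class, there is a single pattern, and the entropy is 0 (a warning is
    emitted, not an error).
    """
    params = params or EntropyParams()
    x = _as_float_patch(patch)
    dn, dm, c = params.dn, params.dm, params.c
    h, w = x.shape
    if h < dn or w < dm:
        raise DimensionError(f"patch {h}x{w} smaller than embedding window {dn}x{dm}")
    mu = float(x.mean())
    sigma = float(x.std())
    k = dn * dm
    n_wins = (h - dn + 1) * (w - dm + 1)
    if sigma == 0.0:
        warnings.warn(
            "dispersion entropy on zero-variance patch: single class, entropy 0",
            RuntimeWarning,
            stacklevel=2,
        )
        probs = np.array([1.0])
        stats = PatternStatistics(dispersion_probs=probs, mu=mu, sigma=sigma, n_windows=n_wins)
        return 0.0, stats
    v = ndtr((x - mu) / sigma)
    # round half away from zero of (c*v + 0.5), i.e. floor(c*v + 1)
    z = np.clip(np.floor(c * v + 1.0), 1, c).astype(np.int64)
    wins = _windows(z, dn, dm)
    codes = wins @ (c ** np.arange(k))
    _, counts = np.unique(codes, return_counts=True)
    probs = counts / counts.sum()
    raw = float(-(probs * np.log(probs)).sum())
    if params.paper_literal:
        value = raw / n_wins
    elif params.normalized:
        value = raw / (k * math.log(c))
    else:
        value = raw
    stats = PatternStatistics(dispersion_probs=probs, mu=mu, sigma=sigma, n_windows=n_wins)
    return value, stats


def disten2d(patch: np.ndarray, params: EntropyParams | None = None) -> tuple[float, PatternStatistics]:
    """Two-dimensional distribution entropy.

    The Chebyshev distances between all distinct pairs of m x m windows
    (not mean-centred, self-pairs excluded) are histogrammed into ``M``
    equal bins spanning [0, max distance]; the output is the Shannon
    entropy (base 2) of the bin probabilities, divided by ``log2(M)``
    when ``normalized``.  An all-zero distance multiset occupies a single
    bin and yields 0.
    """
    params = params or EntropyParams()
    x = _as_float_patch(patch)
    m = params.m
    h, w = x.shape
    if h < m or w < m or (h - m + 1) * (w - m + 1) < 2:
        raise DimensionError(f"patch {h}x{w} yields fewer than 2 windows of size {m}x{m}")
    wins = _windows(x, m, m)
    a = wins.shape[0]
    # two passes: max distance first, then histogram accumulation
    blocks = []
    d_max = 0.0
    for i0 in range(0, a, _CHUNK):
        i1 = min(i0 + _CHUNK, a)
        d = cdist(wins[i0:i1], wins[i0:], metric="chebyshev")
        mask = np.triu(np.ones((i1 - i0, a - i0), dtype=bool), k=1)
        vals = d[mask]
        blocks.append(vals)
        if vals.size:
            d_max = max(d_max, float(vals.max()))
    bins = params.M
    if d_max == 0.0:
        probs = np.zeros(bins)
        probs[0] = 1.0
        stats = PatternStatistics(distance_hist=probs, n_windows=a)
        return 0.0, stats
    counts = np.zeros(bins, dtype=np.int64)
    for vals in blocks:
        counts += np.histogram(vals, bins=bins, range=(0.0, d_max))[0]
    probs = counts / counts.sum()
    nz = probs[probs > 0]
    value = float(-(nz * np.log2(nz)).sum())
    if params.normalized:
        value /= math.log2(bins)
    stats = PatternStatistics(distance_hist=probs, n_windows=a)
    return value, stats


#: Registry used by the extraction stage: measure name -> function.
ENTROPY_MEASURES = {
    "SampEn": sampen2d,
    "FuzzEn": fuzzen2d,
    "PermEn": permen2d,
    "DispEn": dispen2d,
    "DistEn": disten2d,
}
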