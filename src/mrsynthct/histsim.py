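"""CT-number histograms and global histogram-similarity scores.

Four comparison standards between unit-normalised histograms H1, H2:

* correlation — Pearson correlation of the bin vectors (mean-centred);
  perfect match 1, no correlation 0;
* chi-square — Σ (H1−H2)² / (H1+H2), symmetric denominator, both-zero
  bins contribute 0; perfect match 0, unbounded above;
* intersection — Σ min(H1, H2); perfect match 1 (unit-sum inputs),
  total mismatch 0;
* Bhattacharyya distance — sqrt(1 − Σ√(H1·H2) / √(ΣH1·ΣH2)), the
  Hellinger form; perfect match 0, total mismatch 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    BinningMismatchError,
    DegenerateHistogramError,
)
from .volio import BinaryMask, ImageVolume, check_same_grid

__all__ = [
    "Histogram",
    "HistogramScores",
    "build_histogram",
    "compare_histograms",
    "correlation",
    "DEFAULT_RANGE_HU",
    "DEFAULT_N_BINS",
]

DEFAULT_N_BINS = 256
DEFAULT_RANGE_HU = (-1000.0, 1000.0)


@dataclass(frozen=True)
class Histogram:
    """Binned value distribution; ``counts[i]`` over ``edges[i]..edges[i+1]``."""

    edges: np.ndarray
    counts: np.ndarray
    normalized: bool

    def __post_init__(self):
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=np.float64))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.float64))
        if self.edges.ndim != 1 or self.edges.size != self.counts.size + 1:
            raise ValueError("edges must have len(counts)+1 entries")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.normalized and abs(float(self.counts.sum()) - 1.0) > 1e-9:
            raise ValueError("normalized histogram must sum to 1")


@dataclass(frozen=True)
class HistogramScores:
    correlation: float
    chi_square: float
    intersection: float
    bhattacharyya: float
    degenerate_correlation: bool = False


def build_histogram(
    vol: ImageVolume,
    roi: BinaryMask | None = None,
    n_bins: int = DEFAULT_N_BINS,
    range_hu: tuple[float, float] = DEFAULT_RANGE_HU,
    normalize: bool = True,
) -> Histogram:
    """Histogram of ``vol`` over ``roi`` (full grid when ``roi`` is None).

    Values outside ``range_hu`` are clipped into the end bins, so mass is
    conserved: the unnormalised counts sum to the ROI voxel count.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    lo, hi = float(range_hu[0]), float(range_hu[1])
    if not lo < hi:
        raise ValueError(f"invalid range: {range_hu}")
    if roi is not None:
        check_same_grid(vol, roi)
        if not roi.mask.any():
            raise ValueError("empty ROI")
        values = vol.values[roi.mask]
    else:
        values = vol.values.ravel()
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(np.clip(values, lo, hi), bins=edges)
    counts = counts.astype(np.float64)
    if normalize:
        counts = counts / counts.sum()
    return Histogram(edges, counts, normalized=normalize)


def _check_comparable(h1: Histogram, h2: Histogram) -> None:
    if h1.counts.size != h2.counts.size or not np.allclose(
        h1.edges, h2.edges, rtol=0.0, atol=1e-9
    ):
        raise BinningMismatchError("histograms use different bin edges")
    if not (h1.normalized and h2.normalized):
        raise ValueError("histograms must be unit-normalized for comparison")


def correlation(h1: Histogram, h2: Histogram) -> float:
    """Pearson correlation of the mean-centred bin vectors.

    Raises :class:`DegenerateHistogramError` when either histogram has
    zero variance (all mass in equal bins), for which correlation is
    undefined.
    """
    _check_comparable(h1, h2)
    a = h1.counts - h1.counts.mean()
    b = h2.counts - h2.counts.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0.0:
        raise DegenerateHistogramError("zero-variance histogram: correlation undefined")
    return float((a * b).sum() / denom)


def compare_histograms(h1: Histogram, h2: Histogram) -> HistogramScores:
    """All four similarity scores between two identically-binned histograms.

    A zero-variance histogram leaves correlation undefined; the other
    three scores are still computed and ``degenerate_correlation`` is set
    (correlation reported as NaN).
    """
    _check_comparable(h1, h2)
    a, b = h1.counts, h2.counts

    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(denom > 0, (a - b) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    chi_square = float(terms.sum())

    intersection = float(np.minimum(a, b).sum())

    bc = float(np.sqrt(a * b).sum() / np.sqrt(a.sum() * b.sum()))
    bhattacharyya = float(np.sqrt(max(0.0, 1.0 - bc)))

    try:
        corr = correlation(h1, h2)
        degenerate = False
    except DegenerateHistogramError:
        corr = float("nan")
        degenerate = True

    return HistogramScores(
        correlation=corr,
        chi_square=chi_square,
        intersection=intersection,
        bhattacharyya=bhattacharyya,
        degenerate_correlation=degenerate,
    )
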