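"""Gamma-index analysis on CT numbers.

For every reference voxel r1 inside the ROI the gamma index is

    gamma(r1) = min over r2 of sqrt( |r1-r2|^2 / dta^2
                                     + (D2(r2) - D1(r1))^2 / ddabs^2 )

where ``dta`` is the distance-to-agreement criterion (mm), ``ddabs`` the
value-difference criterion in HU (a percentage of a normalization value
derived from the reference inside the ROI), and r2 runs over evaluated-
image voxel centres within a search radius. A voxel passes when
gamma <= 1 (inclusive); the pass rate is the percentage of ROI voxels
passing.

The search is exhaustive over voxel centres within
``search_radius_factor * dta`` (default factor 2). Any match beyond that
distance has gamma > factor from the distance term alone, so the capped
search is exact for every gamma below the factor and always exact for the
pass/fail decision at gamma <= 1. Offsets are visited in order of
increasing distance and the scan stops as soon as the distance term alone
can no longer lower any voxel's minimum.

Default mode is per-axial-slice 2D (in-plane search, one rectangular ROI
per slice: the minimum rectangle covering the body); full-3D search and
integer sub-voxel upsampling of the evaluated image are options.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateNormalizationError, GridMismatchError
from .volio import BinaryMask, ImageVolume, check_same_grid

__all__ = [
    "GammaCriteria",
    "GammaMap",
    "RectROI",
    "roi_from_body",
    "roi_mask",
    "normalization_value",
    "gamma_map",
    "pass_rate",
    "DEFAULT_CRITERIA",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Acceptance criteria and search configuration.

    ``dd_percent`` is relative to the normalization value computed from
    the reference ROI by ``norm_mode``: "range" (max - min, default),
    "fixed2000" (a constant 2000 HU span) or "shifted_max"
    (max after a +1000 HU shift).
    """

    dta_mm: float
    dd_percent: float
    mode: str = "2d"
    search_radius_factor: float = 2.0
    upsample: int = 1
    norm_mode: str = "range"

    def __post_init__(self):
        if self.dta_mm <= 0 or self.dd_percent <= 0:
            raise ValueError("dta_mm and dd_percent must be positive")
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")
        if self.upsample < 1 or int(self.upsample) != self.upsample:
            raise ValueError("upsample must be a positive integer")
        if self.norm_mode not in ("range", "fixed2000", "shifted_max"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")


#: the three criteria reported by the pipeline: 3 mm/3%, 2 mm/2%, 1 mm/1%
DEFAULT_CRITERIA = (
    GammaCriteria(3.0, 3.0),
    GammaCriteria(2.0, 2.0),
    GammaCriteria(1.0, 1.0),
)


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned box of half-open index intervals (slice, row, column)."""

    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self):
        for lo, hi in self.bounds:
            if hi <= lo or lo < 0:
                raise ValueError(f"invalid ROI interval [{lo}, {hi})")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.bounds)  # type: ignore[return-value]


def roi_from_body(body: BinaryMask, mode: str = "2d"):
    """Minimum rectangle(s) covering the body.

    In "3d" mode: one tight bounding box. In "2d" mode: a list of per-slice
    rectangles (slices without body voxels are skipped).
    """
    if not body.mask.any():
        raise ValueError("empty body mask: no ROI")
    if mode == "3d":
        idx = np.argwhere(body.mask)
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        return RectROI(tuple((int(l), int(h)) for l, h in zip(lo, hi)))
    if mode != "2d":
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    rois = []
    for k in range(body.mask.shape[0]):
        sl = body.mask[k]
        if not sl.any():
            continue
        rows = np.flatnonzero(sl.any(axis=1))
        cols = np.flatnonzero(sl.any(axis=0))
        rois.append(
            RectROI(
                (
                    (k, k + 1),
                    (int(rows[0]), int(rows[-1]) + 1),
                    (int(cols[0]), int(cols[-1]) + 1),
                )
            )
        )
    return rois


def roi_mask(shape, roi) -> np.ndarray:
    """Boolean mask of a RectROI or a list of them."""
    rois = roi if isinstance(roi, (list, tuple)) else [roi]
    out = np.zeros(shape, dtype=bool)
    for r in rois:
        for (lo, hi), n in zip(r.bounds, shape):
            if hi > n:
                raise ValueError(f"ROI {r.bounds} extends outside grid {shape}")
        out[r.slices()] = True
    if not out.any():
        raise ValueError("ROI covers no voxels")
    return out


def normalization_value(
    reference: ImageVolume, roi, mode: str = "range"
) -> float:
    """Normalization value (HU) from the reference image inside the ROI."""
    m = roi_mask(reference.shape, roi)
    vals = reference.values[m]
    if mode == "fixed2000":
        return 2000.0
    if mode == "shifted_max":
        v = float((vals + 1000.0).max())
        if v <= 0:
            raise DegenerateNormalizationError("non-positive shifted maximum")
        return v
    if mode != "range":
        raise ValueError(f"unknown normalization mode {mode!r}")
    rng = float(vals.max() - vals.min())
    if rng <= 0:
        raise DegenerateNormalizationError("constant reference inside ROI")
    return rng


@dataclass
class GammaMap:
    """Per-voxel gamma over the ROI (NaN outside), with its provenance."""

    values: np.ndarray
    criteria: GammaCriteria
    normalization: float
    dd_abs_hu: float
    roi: object
    spacing: tuple[float, float, float]


def _offsets_mm(spacing, dta, factor, mode, upsample, shape):
    """Candidate displacements sorted by distance: (distance_mm, step_vector
    in voxel units), clamped to the grid extent. Fractional steps appear
    only when upsample > 1."""
    radius = factor * dta
    steps = [s / upsample for s in spacing]
    extents = [(n - 1) * upsample for n in shape]  # max useful displacement
    half = [min(int(radius // st), ext) for st, ext in zip(steps, extents)]
    if mode == "2d":
        ranges = [range(0, 1)] + [range(-h, h + 1) for h in half[1:]]
    else:
        ranges = [range(-h, h + 1) for h in half]
    out = []
    for mz, my, mx in itertools.product(*ranges):
        d2 = (mz * steps[0]) ** 2 + (my * steps[1]) ** 2 + (mx * steps[2]) ** 2
        if d2 <= radius**2:
            out.append((d2, (mz / upsample, my / upsample, mx / upsample)))
    out.sort(key=lambda t: t[0])
    return out


def _shifted(values: np.ndarray, step_vox) -> np.ndarray:
    """Evaluated image sampled at r + step (voxel units); NaN where the
    sampled position falls outside the grid."""
    if all(float(s).is_integer() for s in step_vox):
        step = [int(s) for s in step_vox]
        out = np.full_like(values, np.nan)
        src = []
        dst = []
        for n, s in zip(values.shape, step):
            lo_src, hi_src = max(0, s), min(n, n + s)
            if hi_src <= lo_src:
                return out
            src.append(slice(lo_src, hi_src))
            dst.append(slice(lo_src - s, hi_src - s))
        out[tuple(dst)] = values[tuple(src)]
        return out
    # sub-voxel displacement: linear interpolation
    return ndimage.shift(
        values, [-s for s in step_vox], order=1, mode="constant", cval=np.nan,
        prefilter=False,
    )


def gamma_map(
    reference: ImageVolume,
    evaluated: ImageVolume,
    criteria: GammaCriteria,
    roi=None,
) -> GammaMap:
    """Gamma index of ``evaluated`` against ``reference`` over the ROI.

    ``roi`` is a RectROI, a list of per-slice RectROIs, or None for the
    full grid. Distances use the voxel spacing in mm; the value criterion
    is ``dd_percent`` of the normalization value computed from the
    reference inside the ROI.
    """
    check_same_grid(reference, evaluated)
    if roi is None:
        roi = RectROI(tuple((0, n) for n in reference.shape))
    mask = roi_mask(reference.shape, roi)
    norm = normalization_value(reference, roi, criteria.norm_mode)
    dd_abs = criteria.dd_percent / 100.0 * norm

    ref = reference.values
    ev = evaluated.values
    dta2 = criteria.dta_mm**2
    dd2 = dd_abs**2

    best = np.full(ref.shape, np.inf)
    for d2, step in _offsets_mm(
        reference.spacing,
        criteria.dta_mm,
        criteria.search_radius_factor,
        criteria.mode,
        criteria.upsample,
        reference.shape,
    ):
        finite = best[mask]
        finite = finite[np.isfinite(finite)]
        if finite.size and d2 / dta2 >= finite.max():
            break  # farther candidates cannot lower any minimum
        cand = d2 / dta2 + (_shifted(ev, step) - ref) ** 2 / dd2
        best = np.fmin(best, cand)

    gamma = np.sqrt(best)
    gamma[~mask] = np.nan
    return GammaMap(
        values=gamma,
        criteria=criteria,
        normalization=norm,
        dd_abs_hu=dd_abs,
        roi=roi,
        spacing=reference.spacing,
    )


def pass_rate(g: GammaMap) -> float:
    """Percentage of ROI voxels with gamma <= 1 (inclusive)."""
    finite = np.isfinite(g.values)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("gamma map has no ROI voxels")
    return 100.0 * int((g.values[finite] <= 1.0).sum()) / n
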