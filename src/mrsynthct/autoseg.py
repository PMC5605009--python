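"""Automatic eight-class segmentation of the head from T1/T2/PETRA MR.

The method combines intensity rules (thresholding on per-sequence
normalised values) with locational priors expressed in a normalised head
frame, followed by morphological cleanup. The rule cascade runs in a fixed
order — air, bone, cavity, ventricle, eyeball, lens, brainstem, body — and
the first matching rule wins, which makes the output deterministic and the
tie-break explicit.

Normalisation divides each sequence by its median intensity inside the
body mask, so thresholds are expressed relative to bulk soft tissue
(body ≈ 1.0) and are robust to global scale changes and mild bias fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import SegmentationFailureError
from .volio import (
    CLASS_NAMES,
    BinaryMask,
    ImageVolume,
    LabelMap,
    check_same_grid,
)

__all__ = [
    "RuleSet",
    "AtlasPrior",
    "default_rules",
    "default_priors",
    "segment_body",
    "classify_tissues",
    "to_masks",
]

AIR, BODY, EYEBALL, LENS, CAVITY, VENTRICLE, BRAINSTEM, BONE = range(8)

#: cascade order after air; first match wins
CASCADE = (BONE, CAVITY, VENTRICLE, EYEBALL, LENS, BRAINSTEM)


@dataclass(frozen=True)
class RuleSet:
    """Intensity rules over median-normalised T1/T2/PETRA values.

    ``body_threshold_fraction`` scales the 99th-percentile PETRA intensity
    to separate the head from background air. Cleanup: removal of
    connected components below ``min_component_voxels`` (the lens is
    exempt — it is legitimately tiny), plus optional morphological closing
    and opening (both off by default: the rules' intensity margins already
    absorb realistic noise, and closing an anisotropic 1-voxel ball
    measurably distorts the thin skull shell).
    """

    body_threshold_fraction: float = 0.15
    body_percentile: float = 99.0

    bone_petra_min: float = 0.35
    bone_t1_max: float = 0.40
    bone_t2_max: float = 0.45

    cavity_petra_max: float = 0.30
    cavity_t1_max: float = 0.35
    cavity_t2_max: float = 0.40

    ventricle_t2_min: float = 1.7
    ventricle_t1_max: float = 0.65

    eyeball_t2_min: float = 1.5
    eyeball_t1_max: float = 0.70

    lens_t1_min: float = 1.12
    lens_t2_max: float = 0.80

    brainstem_t1_min: float = 0.55
    brainstem_t1_max: float = 0.92
    brainstem_t2_min: float = 1.2
    brainstem_t2_max: float = 1.9

    closing_radius_mm: float = 0.0
    opening_radius_mm: float = 0.0
    min_component_voxels: int = 3


@dataclass(frozen=True)
class AtlasPrior:
    """Spatial support regions for the localised classes.

    Each entry maps a class code to a list of ellipsoids
    ``(center, semiaxes)`` in the normalised head frame: the affine that
    sends the body-mask bounding box to the unit cube, axes
    (slice, row, column). Classes without an entry are not gated.
    """

    supports: dict[int, list[tuple[tuple[float, float, float], tuple[float, float, float]]]] = field(
        default_factory=dict
    )


def default_rules() -> RuleSet:
    return RuleSet()


def default_priors() -> AtlasPrior:
    """Priors matching an adult head: anterior paired orbits, midline
    sinus, paramedian lateral ventricles, inferior midline brainstem.
    Supports are generously inflated so moderate anatomical variation
    stays inside them."""
    eye_semi = (0.22, 0.13, 0.16)
    lens_semi = (0.097, 0.051, 0.067)
    vent_semi = (0.178, 0.226, 0.111)
    return AtlasPrior(
        supports={
            EYEBALL: [
                ((0.556, 0.824, 0.308), eye_semi),
                ((0.556, 0.824, 0.692), eye_semi),
            ],
            LENS: [
                ((0.556, 0.853, 0.308), lens_semi),
                ((0.556, 0.853, 0.692), lens_semi),
            ],
            CAVITY: [((0.411, 0.735, 0.5), (0.245, 0.13, 0.17))],
            VENTRICLE: [
                ((0.567, 0.5, 0.4), vent_semi),
                ((0.567, 0.5, 0.6), vent_semi),
            ],
            BRAINSTEM: [((0.367, 0.471, 0.5), (0.32, 0.122, 0.148))],
        }
    )


def _ball(radius_mm: float, spacing) -> np.ndarray:
    """Anisotropic structuring element: voxels within radius_mm of centre."""
    half = [max(1, int(np.floor(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)],
        indexing="ij",
        sparse=True,
    )
    return sum(g**2 for g in grids) <= radius_mm**2


def segment_body(petra: ImageVolume, rules: RuleSet | None = None) -> BinaryMask:
    """Head/air separation on the PETRA volume.

    Thresholds above the background level (a fraction of the high
    percentile), keeps the largest connected component and fills internal
    holes slice-wise, so air-filled sinuses and any interior low-signal
    voxels end up inside the body.
    """
    rules = rules or default_rules()
    values = petra.values
    level = rules.body_threshold_fraction * np.percentile(values, rules.body_percentile)
    fg = values > level
    if not fg.any():
        raise SegmentationFailureError("no foreground voxels above the body threshold")
    comps, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationFailureError("no connected component found")
    largest = np.argmax(ndimage.sum_labels(fg, comps, index=np.arange(1, n + 1))) + 1
    mask = comps == largest
    for k in range(mask.shape[0]):
        mask[k] = ndimage.binary_fill_holes(mask[k])
    return BinaryMask(mask, petra.spacing, petra.origin)


def _normalized(seq: np.ndarray, body: np.ndarray) -> np.ndarray:
    med = np.median(seq[body])
    if med <= 0:
        raise SegmentationFailureError("non-positive median intensity inside body")
    return seq / med


def _prior_masks(prior: AtlasPrior, body: np.ndarray, shape) -> dict[int, np.ndarray]:
    idx = np.argwhere(body)
    lo = idx.min(axis=0).astype(np.float64)
    hi = idx.max(axis=0).astype(np.float64)
    span = np.maximum(hi - lo + 1.0, 1.0)
    axes = [
        (np.arange(n, dtype=np.float64) - lo[k]) / span[k] for k, n in enumerate(shape)
    ]
    zc, yc, xc = np.meshgrid(*axes, indexing="ij", sparse=True)
    out: dict[int, np.ndarray] = {}
    for code, ellipsoids in prior.supports.items():
        m = np.zeros(shape, dtype=bool)
        for (cz, cy, cx), (az, ay, ax_) in ellipsoids:
            m |= ((zc - cz) / az) ** 2 + ((yc - cy) / ay) ** 2 + ((xc - cx) / ax_) ** 2 <= 1.0
        if not (m & body).any():
            raise SegmentationFailureError(
                f"prior for class '{CLASS_NAMES[code]}' does not intersect the body"
            )
        out[code] = m
    return out


def _raw_rule_masks(rules, t1n, t2n, pn) -> dict[int, np.ndarray]:
    """Per-class intensity predicates, before prior gating and cleanup."""
    return {
        BONE: (pn > rules.bone_petra_min)
        & (t1n < rules.bone_t1_max)
        & (t2n < rules.bone_t2_max),
        CAVITY: (pn < rules.cavity_petra_max)
        & (t1n < rules.cavity_t1_max)
        & (t2n < rules.cavity_t2_max),
        VENTRICLE: (t2n > rules.ventricle_t2_min) & (t1n < rules.ventricle_t1_max),
        EYEBALL: (t2n > rules.eyeball_t2_min) & (t1n < rules.eyeball_t1_max),
        LENS: (t1n > rules.lens_t1_min) & (t2n < rules.lens_t2_max),
        BRAINSTEM: (t1n > rules.brainstem_t1_min)
        & (t1n < rules.brainstem_t1_max)
        & (t2n > rules.brainstem_t2_min)
        & (t2n < rules.brainstem_t2_max),
    }


def _cleanup(mask: np.ndarray, rules: RuleSet, spacing, keep_small: bool) -> np.ndarray:
    if rules.closing_radius_mm > 0:
        mask = ndimage.binary_closing(mask, structure=_ball(rules.closing_radius_mm, spacing))
    if rules.opening_radius_mm > 0:
        mask = ndimage.binary_opening(mask, structure=_ball(rules.opening_radius_mm, spacing))
    if not keep_small and rules.min_component_voxels > 1 and mask.any():
        # 26-connectivity: diagonal contact keeps rasterised shells whole
        comps, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = ndimage.sum_labels(mask, comps, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < rules.min_component_voxels) + 1
        if small.size:
            mask = mask & ~np.isin(comps, small)
    return mask


def classify_tissues(
    t1: ImageVolume,
    t2: ImageVolume,
    petra: ImageVolume,
    body: BinaryMask,
    rules: RuleSet | None = None,
    priors: AtlasPrior | None = None,
) -> LabelMap:
    """Assign one of the eight anatomy classes to every voxel.

    Outside the body mask every voxel is air. Inside, the rule cascade
    (bone, cavity, ventricle, eyeball, lens, brainstem) runs in order with
    first-match-wins tie-breaking; prior-gated classes only fire inside
    their spatial support. Remaining voxels are generic body. Each class
    mask is morphologically cleaned before assignment.
    """
    rules = rules or default_rules()
    priors = priors or default_priors()
    check_same_grid(t1, t2)
    check_same_grid(t1, petra)
    check_same_grid(t1, body)
    if not body.mask.any():
        raise SegmentationFailureError("empty body mask")

    bm = body.mask
    t1n = _normalized(t1.values, bm)
    t2n = _normalized(t2.values, bm)
    pn = _normalized(petra.values, bm)

    prior_masks = _prior_masks(priors, bm, bm.shape)
    raw = _raw_rule_masks(rules, t1n, t2n, pn)
    gated = {}
    for code in CASCADE:
        mask = raw[code] & bm
        if code in prior_masks:
            mask &= prior_masks[code]
        gated[code] = mask

    labels = np.full(bm.shape, AIR, dtype=np.int16)
    assigned = ~bm  # air is settled; cascade fills the rest
    for code in CASCADE:
        mask = _cleanup(gated[code], rules, t1.spacing, keep_small=(code == LENS))
        # closing may only absorb unclaimed voxels, not another class's match
        # (e.g. the eyeball's closure must not swallow the lens)
        for other, other_mask in gated.items():
            if other != code:
                mask &= ~(other_mask & ~gated[code])
        mask &= ~assigned
        labels[mask] = code
        assigned |= mask
    labels[bm & ~assigned] = BODY
    return LabelMap(labels, t1.spacing, t1.origin)


def to_masks(labels: LabelMap) -> dict[int, BinaryMask]:
    """Split a label map into eight disjoint masks covering the grid."""
    return {
        code: BinaryMask(labels.labels == code, labels.spacing, labels.origin)
        for code in CLASS_NAMES
    }
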