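"""Synthetic digital head phantom.

Generates co-registered cases — ground-truth anatomy labels, three MR
sequences (T1-weighted, T2-weighted, PETRA) and a reference CT — on a
2.5 mm-slice, 30 cm field-of-view grid emulating a clinical intracranial
protocol. Geometry is analytic: the head is an ellipsoid, the skull an
ellipsoidal shell, and eyeballs, lenses, sinus cavity, lateral ventricles
and brainstem are spheres/ellipsoids rasterised at voxel centres.

Intensity model per volume: class mean, multiplied by a smooth bias field
(MR) or shifted by a smooth additive perturbation (CT), plus white Gaussian
noise. The reference CT deliberately does NOT equal the ideal bulk-density
CT: its per-class means are offset from the bulk HU table and it carries
noise and a low-frequency field, so that downstream similarity metrics have
dynamic range instead of saturating at a perfect score.

Class contrast (arbitrary units) follows the clinical sequences it stands
in for: CSF-filled ventricles are dark on T1 and bright on T2; bone carries
signal only on the ultrashort-echo PETRA sequence; the lens is T1-bright
and T2-dark relative to vitreous humour.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .volio import CLASS_NAMES, BinaryMask, ImageVolume, LabelMap, check_same_grid

__all__ = ["PhantomSpec", "PhantomCase", "generate_case", "generate_cohort", "noise_free"]

# class codes
AIR, BODY, EYEBALL, LENS, CAVITY, VENTRICLE, BRAINSTEM, BONE = range(8)


@dataclass(frozen=True)
class PhantomSpec:
    """All tunable parameters of the phantom. Defaults are the study
    conditions; lengths in mm, intensities in arbitrary units, CT in HU."""

    shape: tuple[int, int, int] = (40, 128, 128)
    spacing: tuple[float, float, float] = (2.5, 2.34, 2.34)

    # head ellipsoid semi-axes (slice, row=anterior-posterior, column=left-right)
    head_semiaxes: tuple[float, float, float] = (45.0, 85.0, 65.0)
    # skull shell: band of normalised ellipsoidal radius
    skull_inner_scale: float = 0.80
    skull_outer_scale: float = 0.92
    # structure placement: centre offsets from head centre, mm (z, y, x)
    eyeball_offset: tuple[float, float, float] = (5.0, 55.0, 25.0)  # x mirrored
    eyeball_radius: float = 9.5
    lens_offset_anterior: float = 4.5  # relative to eyeball centre, +y
    lens_radius: float = 3.4
    cavity_center: tuple[float, float, float] = (-8.0, 40.0, 0.0)
    cavity_radius: float = 13.0
    ventricle_offset: tuple[float, float, float] = (6.0, 0.0, 13.0)  # x mirrored
    ventricle_semiaxes: tuple[float, float, float] = (10.0, 24.0, 9.0)
    brainstem_center: tuple[float, float, float] = (-12.0, -5.0, 0.0)
    brainstem_semiaxes: tuple[float, float, float] = (18.0, 13.0, 12.0)

    # per-case jitter: multiplicative on radii/semi-axes, additive on centres;
    # the head ellipsoid gets its own (smaller) scale — overall head size
    # varies less across adults than individual internal structures do
    jitter_scale: float = 0.05
    head_jitter_scale: float = 0.02
    jitter_shift_mm: float = 2.5

    # MR class means, (T1, T2, PETRA), arbitrary units
    mr_means: dict = field(
        default_factory=lambda: {
            AIR: (2.0, 2.0, 2.0),
            BODY: (70.0, 40.0, 70.0),
            EYEBALL: (30.0, 80.0, 55.0),
            LENS: (90.0, 25.0, 55.0),
            CAVITY: (2.0, 2.0, 2.0),
            VENTRICLE: (25.0, 90.0, 50.0),
            BRAINSTEM: (55.0, 60.0, 70.0),
            BONE: (6.0, 6.0, 45.0),
        }
    )
    mr_noise_sd: float = 3.0
    bias_amplitude: float = 0.03  # multiplicative smooth field (RMS fraction)

    # reference-CT class means (HU); offset from the bulk table on purpose
    ct_means: dict = field(
        default_factory=lambda: {
            AIR: -1000.0,
            BODY: 25.0,
            EYEBALL: 295.0,
            LENS: 310.0,
            CAVITY: -995.0,
            VENTRICLE: 12.0,
            BRAINSTEM: -45.0,
            BONE: 990.0,
        }
    )
    ct_noise_sd: float = 8.0
    ct_perturbation_hu: float = 22.0  # additive smooth field amplitude (RMS)
    # coarse control-grid of the smooth fields; sets the heterogeneity
    # correlation length (~19 mm at the default grid/spacing)
    field_coarse_shape: tuple[int, int, int] = (8, 16, 16)
    ct_clip: tuple[float, float] = (-1000.0, 3071.0)

    seed: int = 20170919

    def validate(self) -> None:
        if any(n < 4 for n in self.shape):
            raise PhantomSpecError(f"grid too small: {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomSpecError(f"spacing must be positive: {self.spacing}")
        if not 0 < self.skull_inner_scale < self.skull_outer_scale <= 1.0:
            raise PhantomSpecError("skull shell scales must satisfy 0 < inner < outer <= 1")
        if self.lens_offset_anterior + self.lens_radius >= self.eyeball_radius:
            raise PhantomSpecError("lens must lie strictly inside the eyeball")
        for table, name in ((self.mr_means, "mr_means"), (self.ct_means, "ct_means")):
            missing = set(CLASS_NAMES) - set(table)
            if missing:
                raise PhantomSpecError(f"{name} missing classes {sorted(missing)}")


def noise_free(spec: PhantomSpec) -> PhantomSpec:
    """Copy of ``spec`` with all noise, bias and perturbation switched off
    (geometry jitter is retained)."""
    return dataclasses.replace(
        spec, mr_noise_sd=0.0, bias_amplitude=0.0, ct_noise_sd=0.0, ct_perturbation_hu=0.0
    )


@dataclass
class PhantomCase:
    """One synthetic patient: ground truth plus four co-registered volumes."""

    case_id: int
    truth: LabelMap
    t1: ImageVolume
    t2: ImageVolume
    petra: ImageVolume
    reference_ct: ImageVolume
    seed: int

    def volumes(self) -> dict[str, ImageVolume]:
        return {
            "t1": self.t1,
            "t2": self.t2,
            "petra": self.petra,
            "ct": self.reference_ct,
        }


def _rng(spec: PhantomSpec, case_id: int, stream: int) -> np.random.Generator:
    # one seed stream per (spec.seed, case_id), split per volume by offset
    return np.random.default_rng([int(spec.seed), int(case_id), int(stream)])


def _coords(spec: PhantomSpec):
    """World coordinates of voxel centres, relative to the head centre."""
    axes = []
    for n, s in zip(spec.shape, spec.spacing):
        c = (n - 1) / 2.0 * s
        axes.append(np.arange(n, dtype=np.float64) * s - c)
    z, y, x = np.meshgrid(*axes, indexing="ij", sparse=True)
    return z, y, x


def _ellipsoid(z, y, x, center, semiaxes) -> np.ndarray:
    cz, cy, cx = center
    az, ay, ax_ = semiaxes
    r2 = ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax_) ** 2
    return r2 <= 1.0


def _smooth_field(rng: np.random.Generator, shape, coarse) -> np.ndarray:
    """Low-frequency random field, normalised to unit RMS.

    RMS (not peak) normalisation keeps the field energy identical across
    cases, so the amplitude parameter means the same thing for every case."""
    coarse_field = rng.standard_normal(coarse)
    zoom = [s / c for s, c in zip(shape, coarse)]
    fine = ndimage.zoom(coarse_field, zoom, order=3, mode="nearest")
    fine = fine[tuple(slice(0, n) for n in shape)]
    rms = float(np.sqrt(np.mean(fine**2)))
    return fine / rms if rms > 0 else fine


def _jitter(rng, value, scale):
    return value * (1.0 + rng.uniform(-scale, scale))


def _jitter3(rng, center, shift):
    return tuple(c + rng.uniform(-shift, shift) for c in center)


def _rasterize_truth(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    z, y, x = _coords(spec)
    js, jm = spec.jitter_scale, spec.jitter_shift_mm

    head_ax = tuple(_jitter(rng, a, spec.head_jitter_scale) for a in spec.head_semiaxes)
    r2 = (z / head_ax[0]) ** 2 + (y / head_ax[1]) ** 2 + (x / head_ax[2]) ** 2
    rnorm = np.sqrt(r2)
    head = rnorm <= 1.0
    skull = (rnorm >= spec.skull_inner_scale) & (rnorm <= spec.skull_outer_scale)

    eyes, lenses = [], []
    for sign in (-1.0, 1.0):
        oz, oy, ox = spec.eyeball_offset
        center = _jitter3(rng, (oz, oy, sign * ox), jm)
        radius = _jitter(rng, spec.eyeball_radius, js)
        lens_r = _jitter(rng, spec.lens_radius, js)
        # the lens rides with its eyeball: shared centre shift
        lens_center = (center[0], center[1] + spec.lens_offset_anterior, center[2])
        eyes.append(_ellipsoid(z, y, x, center, (radius,) * 3))
        lenses.append(_ellipsoid(z, y, x, lens_center, (lens_r,) * 3))

    cavity = _ellipsoid(
        z, y, x,
        _jitter3(rng, spec.cavity_center, jm),
        (_jitter(rng, spec.cavity_radius, js),) * 3,
    )
    vents = []
    for sign in (-1.0, 1.0):
        oz, oy, ox = spec.ventricle_offset
        vents.append(
            _ellipsoid(
                z, y, x,
                _jitter3(rng, (oz, oy, sign * ox), jm),
                tuple(_jitter(rng, a, js) for a in spec.ventricle_semiaxes),
            )
        )
    brainstem = _ellipsoid(
        z, y, x,
        _jitter3(rng, spec.brainstem_center, jm),
        tuple(_jitter(rng, a, js) for a in spec.brainstem_semiaxes),
    )

    structures = {
        BONE: skull,
        CAVITY: cavity,
        VENTRICLE: vents[0] | vents[1],
        BRAINSTEM: brainstem,
        EYEBALL: eyes[0] | eyes[1],
        LENS: lenses[0] | lenses[1],
    }
    for code, mask in structures.items():
        if np.any(mask & ~head):
            raise PhantomSpecError(
                f"structure '{CLASS_NAMES[code]}' extends outside the head"
            )
    for eye, lens in zip(eyes, lenses):
        if np.any(lens & ~eye):
            raise PhantomSpecError("lens extends outside its eyeball")

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[head] = BODY
    # paint order: later structures override (eyeball carves the orbit in bone)
    for code in (BONE, CAVITY, VENTRICLE, BRAINSTEM, EYEBALL, LENS):
        labels[structures[code]] = code

    present = set(np.unique(labels).tolist())
    missing = set(CLASS_NAMES) - present
    if missing:
        raise PhantomSpecError(
            f"classes {sorted(CLASS_NAMES[m] for m in missing)} rasterised to zero voxels"
        )
    return labels


def _mr_volume(spec, labels, seq_index, rng) -> np.ndarray:
    means = np.zeros(8)
    for code, triple in spec.mr_means.items():
        means[code] = triple[seq_index]
    img = means[labels]
    if spec.bias_amplitude > 0:
        img = img * (
            1.0 + spec.bias_amplitude * _smooth_field(rng, spec.shape, spec.field_coarse_shape)
        )
    if spec.mr_noise_sd > 0:
        img = img + rng.normal(0.0, spec.mr_noise_sd, size=spec.shape)
    return img


def _ct_volume(spec, labels, rng) -> np.ndarray:
    means = np.zeros(8)
    for code, hu in spec.ct_means.items():
        means[code] = hu
    img = means[labels].astype(np.float64)
    if spec.ct_perturbation_hu > 0:
        img = img + spec.ct_perturbation_hu * _smooth_field(
            rng, spec.shape, spec.field_coarse_shape
        )
    if spec.ct_noise_sd > 0:
        img = img + rng.normal(0.0, spec.ct_noise_sd, size=spec.shape)
    return np.clip(img, *spec.ct_clip)


def generate_case(spec: PhantomSpec, case_id: int) -> PhantomCase:
    """Generate one deterministic phantom case.

    The same ``(spec, case_id)`` always yields bit-identical volumes; the
    per-case geometry jitter and all noise draws derive from
    ``(spec.seed, case_id)``.
    """
    if case_id < 0:
        raise ValueError(f"case_id must be >= 0, got {case_id}")
    spec.validate()

    labels = _rasterize_truth(spec, _rng(spec, case_id, 0))
    truth = LabelMap(labels, spec.spacing)
    t1 = ImageVolume(_mr_volume(spec, labels, 0, _rng(spec, case_id, 1)), spec.spacing)
    t2 = ImageVolume(_mr_volume(spec, labels, 1, _rng(spec, case_id, 2)), spec.spacing)
    petra = ImageVolume(_mr_volume(spec, labels, 2, _rng(spec, case_id, 3)), spec.spacing)
    ct = ImageVolume(_ct_volume(spec, labels, _rng(spec, case_id, 4)), spec.spacing)

    case = PhantomCase(case_id, truth, t1, t2, petra, ct, spec.seed)
    for vol in case.volumes().values():
        check_same_grid(truth, vol)
    return case


def generate_cohort(spec: PhantomSpec, n_cases: int = 20) -> list[PhantomCase]:
    """Generate ``n_cases`` cases with ids 0..n-1 (default cohort size 20)."""
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    return [generate_case(spec, i) for i in range(n_cases)]


def body_mask_from_truth(truth: LabelMap) -> BinaryMask:
    """Ground-truth body-or-interior mask (everything that is not external air)."""
    return BinaryMask(truth.labels != AIR, truth.spacing, truth.origin)
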