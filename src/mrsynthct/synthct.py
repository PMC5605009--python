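"""Synthetic CT synthesis by bulk HU assignment.

Two variants:

* ``synthesize_bct`` — bulk-density CT: every anatomy class is replaced by
  one representative CT number from an :class:`HUTable`;
* ``synthesize_wct`` — water-equivalent CT: body interior 0 HU, exterior
  -1000 HU, no inhomogeneity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .volio import CLASS_NAMES, BinaryMask, ImageVolume, LabelMap

__all__ = ["HUTable", "DEFAULT_HU", "synthesize_bct", "synthesize_wct"]

#: default bulk CT numbers per anatomy class (HU)
DEFAULT_HU: dict[int, float] = {
    0: -1000.0,  # air
    1: 0.0,      # body
    2: 300.0,    # eyeball
    3: 300.0,    # lens
    4: -1000.0,  # cavity
    5: 15.0,     # ventricle
    6: -50.0,    # brainstem
    7: 1000.0,   # bone
}

_HU_MIN, _HU_MAX = -1024.0, 3071.0


@dataclass(frozen=True)
class HUTable:
    """Class-code → CT-number assignment. Complete over all eight classes,
    values restricted to the representable CT range [-1024, 3071] HU."""

    values: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_HU))

    def validate(self) -> None:
        missing = set(CLASS_NAMES) - set(self.values)
        if missing:
            names = sorted(CLASS_NAMES[m] for m in missing)
            raise ConfigurationError(f"HU table missing classes: {names}")
        for code, hu in self.values.items():
            if not _HU_MIN <= hu <= _HU_MAX:
                raise ConfigurationError(
                    f"HU for class '{CLASS_NAMES.get(code, code)}' out of range: {hu}"
                )

    def as_array(self) -> np.ndarray:
        self.validate()
        arr = np.empty(len(CLASS_NAMES))
        for code in CLASS_NAMES:
            arr[code] = self.values[code]
        return arr


def synthesize_bct(labels: LabelMap, table: HUTable | None = None) -> ImageVolume:
    """Bulk-density CT: per-voxel lookup of the class CT number."""
    table = table or HUTable()
    lut = table.as_array()
    return ImageVolume(lut[labels.labels], labels.spacing, labels.origin)


def synthesize_wct(body: BinaryMask) -> ImageVolume:
    """Water-equivalent CT: 0 HU inside the body, -1000 HU outside."""
    values = np.where(body.mask, 0.0, -1000.0)
    return ImageVolume(values, body.spacing, body.origin)
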