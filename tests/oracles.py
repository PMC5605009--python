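"""Independent reference implementations used to cross-check the package.

Deliberately written along a different path than the production code:
the gamma oracle enumerates every reference/evaluated voxel pair of a
slice through a scipy distance matrix, with no search cap, no offset
enumeration and no early termination.
"""

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_gamma_2d(ref_slice, ev_slice, spacing_rc, dta_mm, dd_abs):
    """All-pairs gamma of one 2D slice; returns a per-pixel gamma array."""
    ref_slice = np.asarray(ref_slice, dtype=float)
    ev_slice = np.asarray(ev_slice, dtype=float)
    nr, nc = ref_slice.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    pos = np.stack(
        [rows.ravel() * spacing_rc[0], cols.ravel() * spacing_rc[1]], axis=1
    )
    d2 = cdist(pos, pos, metric="sqeuclidean")
    dv = ev_slice.ravel()[None, :] - ref_slice.ravel()[:, None]
    gamma2 = d2 / dta_mm**2 + dv**2 / dd_abs**2
    return np.sqrt(gamma2.min(axis=1)).reshape(nr, nc)
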