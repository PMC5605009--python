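import numpy as np
import pytest

from mrsynthct import gammaeval
from mrsynthct.errors import DegenerateNormalizationError
from mrsynthct.gammaeval import (
    GammaCriteria,
    GammaMap,
    RectROI,
    gamma_map,
    normalization_value,
    pass_rate,
    roi_from_body,
)
from mrsynthct.volio import BinaryMask, ImageVolume

from oracles import brute_force_gamma_2d

UNIT = (1.0, 1.0, 1.0)


def _vol(arr, spacing=UNIT):
    return ImageVolume(np.asarray(arr, float), spacing)


# ---------------------------------------------------------------- ROI


def test_roi_single_voxel():
    m = np.zeros((1, 10, 10), bool)
    m[0, 5, 7] = True
    (roi,) = roi_from_body(BinaryMask(m, UNIT), mode="2d")
    assert roi.bounds == ((0, 1), (5, 6), (7, 8))


def test_roi_full_slice():
    m = np.ones((1, 6, 8), bool)
    (roi,) = roi_from_body(BinaryMask(m, UNIT), mode="2d")
    assert roi.bounds == ((0, 1), (0, 6), (0, 8))


def test_roi_l_shape_bounding_rectangle():
    m = np.zeros((1, 10, 10), bool)
    m[0, 2:6, 3] = True   # vertical arm, rows 2..5
    m[0, 5, 3:9] = True   # horizontal arm, cols 3..8
    (roi,) = roi_from_body(BinaryMask(m, UNIT), mode="2d")
    assert roi.bounds == ((0, 1), (2, 6), (3, 9))


def test_roi_3d_and_empty_slice_skipping():
    m = np.zeros((3, 4, 4), bool)
    m[0, 1, 1] = True
    m[2, 2, 2] = True  # middle slice empty
    rois = roi_from_body(BinaryMask(m, UNIT), mode="2d")
    assert [r.bounds[0] for r in rois] == [(0, 1), (2, 3)]
    roi3d = roi_from_body(BinaryMask(m, UNIT), mode="3d")
    assert roi3d.bounds == ((0, 3), (1, 3), (1, 3))


def test_roi_empty_mask_rejected():
    with pytest.raises(ValueError):
        roi_from_body(BinaryMask(np.zeros((1, 2, 2), bool), UNIT))


# ------------------------------------------------------ normalization


def test_normalization_dynamic_range():
    vals = np.zeros((1, 4, 4))
    vals[0, 0, 0], vals[0, 1, 1] = -1000.0, 1000.0
    roi = RectROI(((0, 1), (0, 4), (0, 4)))
    assert normalization_value(_vol(vals), roi) == 2000.0
    # 3% of the range is the absolute value criterion
    g = gamma_map(_vol(vals), _vol(vals), GammaCriteria(3.0, 3.0), roi)
    assert g.dd_abs_hu == pytest.approx(60.0)


def test_normalization_uniform_reference_degenerate():
    roi = RectROI(((0, 1), (0, 3), (0, 3)))
    with pytest.raises(DegenerateNormalizationError):
        normalization_value(_vol(np.zeros((1, 3, 3))), roi)


def test_normalization_small_span():
    vals = np.zeros((1, 3, 3))
    vals[0, 2, 2] = 100.0
    roi = RectROI(((0, 1), (0, 3), (0, 3)))
    assert normalization_value(_vol(vals), roi) == 100.0


# ------------------------------------------------------------- gamma


def _step_field(value_left=-1000.0, value_right=1000.0, shape=(1, 8, 8)):
    vals = np.full(shape, value_left)
    vals[..., shape[-1] // 2:] = value_right
    return vals


def test_identical_images_gamma_zero_everywhere():
    ref = _vol(_step_field())
    g = gamma_map(ref, ref, GammaCriteria(3.0, 3.0))
    assert np.nanmax(g.values) == 0.0
    assert pass_rate(g) == 100.0


def test_uniform_offset_of_exactly_dd_gives_gamma_one():
    """Offsetting by exactly the value criterion lands on the pass boundary."""
    ref_vals = _step_field()
    crit = GammaCriteria(3.0, 3.0)
    ref = _vol(ref_vals)
    dd_abs = 0.03 * 2000.0
    ev = _vol(ref_vals + dd_abs)
    g = gamma_map(ref, ev, crit)
    np.testing.assert_allclose(g.values[np.isfinite(g.values)], 1.0, atol=1e-12)
    assert pass_rate(g) == 100.0  # gamma <= 1 is inclusive


def test_shifted_step_edge_gamma_half():
    """A 1 mm mis-placed edge under 2 mm DTA costs gamma = 0.5."""
    n = 20
    ref_vals = np.zeros((1, 1, n))
    ref_vals[..., 10:] = 100.0          # edge at index 10
    ev_vals = np.zeros((1, 1, n))
    ev_vals[..., 11:] = 100.0           # same edge at index 11
    g = gamma_map(_vol(ref_vals), _vol(ev_vals), GammaCriteria(2.0, 2.0))
    assert np.nanmax(g.values) == pytest.approx(0.5, abs=1e-12)


def _random_pair(rng, shape=(1, 24, 24)):
    ref = rng.random(shape) * 100.0
    ev = ref + rng.normal(scale=5.0, size=shape)
    return _vol(ref, (1.0, 1.2, 0.8)), _vol(ev, (1.0, 1.2, 0.8))


@pytest.mark.parametrize("dta,dd", [(3.0, 3.0), (2.0, 2.0), (1.0, 1.0)])
def test_matches_brute_force_all_pairs(dta, dd):
    """Exhaustive-search production gamma equals the all-pairs oracle."""
    rng = np.random.default_rng(17)
    for _ in range(5):
        ref, ev = _random_pair(rng)
        crit = GammaCriteria(dta, dd, search_radius_factor=1000.0)
        g = gamma_map(ref, ev, crit)
        dd_abs = dd / 100.0 * normalization_value(ref, g.roi)
        oracle = brute_force_gamma_2d(
            ref.values[0], ev.values[0], ref.spacing[1:], dta, dd_abs
        )
        np.testing.assert_allclose(g.values[0], oracle, rtol=0, atol=1e-9)


def test_capped_search_exact_below_factor_and_for_pass_fail():
    """The default radius cap changes nothing below the cap factor and
    never changes the pass/fail decision."""
    rng = np.random.default_rng(29)
    ref, ev = _random_pair(rng)
    crit_full = GammaCriteria(2.0, 2.0, search_radius_factor=1000.0)
    crit_capped = GammaCriteria(2.0, 2.0)  # default factor 2
    full = gamma_map(ref, ev, crit_full).values
    capped = gamma_map(ref, ev, crit_capped).values
    below = full < crit_capped.search_radius_factor
    np.testing.assert_allclose(capped[below], full[below], rtol=0, atol=1e-9)
    assert np.all(capped >= full - 1e-9)
    assert np.array_equal(capped <= 1.0, full <= 1.0)


def test_tightening_criteria_never_lowers_gamma():
    rng = np.random.default_rng(31)
    ref, ev = _random_pair(rng)
    g3 = gamma_map(ref, ev, GammaCriteria(3.0, 3.0)).values
    g2 = gamma_map(ref, ev, GammaCriteria(2.0, 2.0)).values
    g1 = gamma_map(ref, ev, GammaCriteria(1.0, 1.0)).values
    assert np.all(g2 >= g3 - 1e-12)
    assert np.all(g1 >= g2 - 1e-12)
    rates = [
        pass_rate(gamma_map(ref, ev, GammaCriteria(d, d)))
        for d in (3.0, 2.0, 1.0)
    ]
    assert rates[0] >= rates[1] >= rates[2]


def test_scale_invariance_under_renormalization():
    """Scaling both images about the reference mean rescales the dynamic
    range identically, leaving gamma unchanged."""
    rng = np.random.default_rng(37)
    ref, ev = _random_pair(rng)
    m = ref.values.mean()
    scale = 7.5
    ref2 = _vol(m + scale * (ref.values - m), ref.spacing)
    ev2 = _vol(m + scale * (ev.values - m), ev.spacing)
    crit = GammaCriteria(2.0, 2.0)
    g = gamma_map(ref, ev, crit).values
    g_scaled = gamma_map(ref2, ev2, crit).values
    np.testing.assert_allclose(g_scaled, g, rtol=0, atol=1e-9)


def test_gamma_nonnegative_and_nan_outside_roi(case0):
    from mrsynthct import autoseg, synthct

    body = autoseg.segment_body(case0.petra)
    roi = roi_from_body(body, "2d")
    wct = synthct.synthesize_wct(body)
    g = gamma_map(case0.reference_ct, wct, GammaCriteria(3.0, 3.0), roi)
    finite = np.isfinite(g.values)
    assert np.all(g.values[finite] >= 0.0)
    mask = gammaeval.roi_mask(case0.reference_ct.shape, roi)
    assert np.all(~finite[~mask])


def test_pass_rate_counting():
    vals = np.full((1, 2, 2), np.nan)
    vals[0] = [[0.5, 1.0], [1.5, 2.0]]
    g = GammaMap(vals, GammaCriteria(3.0, 3.0), 2000.0, 60.0, None, UNIT)
    assert pass_rate(g) == 50.0


def test_pass_rate_empty_map_rejected():
    g = GammaMap(np.full((1, 2, 2), np.nan), GammaCriteria(3.0, 3.0), 2000.0, 60.0, None, UNIT)
    with pytest.raises(ValueError):
        pass_rate(g)
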