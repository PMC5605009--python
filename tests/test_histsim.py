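import numpy as np
import pytest

from mrsynthct import histsim
from mrsynthct.errors import BinningMismatchError, DegenerateHistogramError
from mrsynthct.histsim import Histogram, build_histogram, compare_histograms
from mrsynthct.synthct import synthesize_wct
from mrsynthct.volio import BinaryMask, ImageVolume

SPACING = (2.5, 2.34, 2.34)


def _hist(counts):
    counts = np.asarray(counts, float)
    edges = np.arange(counts.size + 1, dtype=float)
    return Histogram(edges, counts / counts.sum(), normalized=True)


def test_uniform_volume_single_bin():
    vol = ImageVolume(np.zeros((2, 4, 4)), SPACING)
    h = build_histogram(vol, n_bins=256, range_hu=(-1000, 1000))
    assert int((h.counts > 0).sum()) == 1
    assert h.counts.sum() == pytest.approx(1.0, abs=1e-12)


def test_water_ct_has_exactly_two_bins(case0):
    body = BinaryMask(case0.truth.labels != 0, SPACING)
    h = build_histogram(synthesize_wct(body))
    assert int((h.counts > 0).sum()) == 2


def test_unnormalized_counts_conserve_mass(case0):
    roi = BinaryMask(case0.truth.labels != 0, SPACING)
    h = build_histogram(case0.reference_ct, roi=roi, normalize=False)
    assert h.counts.sum() == roi.mask.sum()


def test_out_of_range_values_clip_into_end_bins():
    vol = ImageVolume(np.full((1, 2, 2), 5000.0), SPACING)
    h = build_histogram(vol, n_bins=10, range_hu=(-1000, 1000))
    assert h.counts[-1] == 1.0


def test_empty_roi_rejected(case0):
    empty = BinaryMask(np.zeros(case0.truth.shape, bool), SPACING)
    with pytest.raises(ValueError):
        build_histogram(case0.reference_ct, roi=empty)


def test_self_comparison_anchors(case0):
    """A non-degenerate histogram against itself hits every perfect-match
    anchor: correlation 1, chi-square 0, intersection 1, Bhattacharyya 0."""
    h = build_histogram(case0.reference_ct)
    s = compare_histograms(h, h)
    assert s.correlation == pytest.approx(1.0, abs=1e-9)
    assert s.chi_square == pytest.approx(0.0, abs=1e-9)
    assert s.intersection == pytest.approx(1.0, abs=1e-9)
    assert s.bhattacharyya == pytest.approx(0.0, abs=1e-9)


def test_disjoint_two_bin_histograms_hand_computed():
    """H1=[1,0] vs H2=[0,1]: mean-centred vectors are ±0.5, so correlation
    is -1; chi-square 1/1 + 1/1 = 2; no shared mass elsewhere."""
    s = compare_histograms(_hist([1, 0]), _hist([0, 1]))
    assert s.correlation == pytest.approx(-1.0, abs=1e-12)
    assert s.chi_square == pytest.approx(2.0, abs=1e-12)
    assert s.intersection == pytest.approx(0.0, abs=1e-12)
    assert s.bhattacharyya == pytest.approx(1.0, abs=1e-12)


def test_constant_histogram_degenerate_correlation():
    flat = _hist([1, 1, 1, 1])
    with pytest.raises(DegenerateHistogramError):
        histsim.correlation(flat, flat)
    s = compare_histograms(flat, flat)
    assert s.degenerate_correlation
    assert np.isnan(s.correlation)
    assert s.chi_square == pytest.approx(0.0)
    assert s.intersection == pytest.approx(1.0)
    assert s.bhattacharyya == pytest.approx(0.0, abs=1e-9)


def test_binning_mismatch_rejected():
    a = _hist([1, 2, 3])
    b = Histogram(np.array([0.0, 2.0, 4.0, 6.0]), a.counts, normalized=True)
    with pytest.raises(BinningMismatchError):
        compare_histograms(a, b)


def _random_unit_hist(rng, n=32):
    c = rng.random(n)
    return _hist(c)


def test_symmetry_and_bounds_on_random_pairs():
    """All four scores are symmetric; bounds hold for 1000 random pairs."""
    rng = np.random.default_rng(23)
    for _ in range(1000):
        h1 = _random_unit_hist(rng)
        h2 = _random_unit_hist(rng)
        s12 = compare_histograms(h1, h2)
        s21 = compare_histograms(h2, h1)
        for attr in ("correlation", "chi_square", "intersection", "bhattacharyya"):
            assert getattr(s12, attr) == pytest.approx(getattr(s21, attr), abs=1e-12)
        assert -1.0 - 1e-12 <= s12.correlation <= 1.0 + 1e-12
        assert s12.chi_square >= 0.0
        assert 0.0 <= s12.intersection <= 1.0 + 1e-12
        assert 0.0 <= s12.bhattacharyya <= 1.0 + 1e-12


def test_mixing_towards_uniform_degrades_monotonically():
    """Blending a histogram towards uniform makes intersection fall and
    Bhattacharyya rise monotonically in the mixing weight."""
    rng = np.random.default_rng(4)
    base = rng.random(64)
    base[rng.random(64) < 0.5] = 0.0  # structured, partly empty bins
    base /= base.sum()
    uniform = np.full(64, 1.0 / 64)
    h1 = _hist(base)
    inters, bhats = [], []
    for lam in np.linspace(0.0, 1.0, 11):
        mixed = (1 - lam) * base + lam * uniform
        s = compare_histograms(h1, _hist(mixed))
        inters.append(s.intersection)
        bhats.append(s.bhattacharyya)
    assert all(a >= b - 1e-12 for a, b in zip(inters, inters[1:]))
    assert all(a <= b + 1e-12 for a, b in zip(bhats, bhats[1:]))
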