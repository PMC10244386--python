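"""Tubeness score, naive-percentile calibration and PVS segmentation."""

import numpy as np
import pytest

from perivasc.core import GeometryError, ImageVolume
from perivasc.tubeness import (
    PVSSegmenter,
    TubenessConfig,
    brain_regions,
    calibrate_threshold,
    compute_tubeness,
    histogram_mode,
    percent_volume,
    remap_intensity,
    segment_pvs,
)

SP = (0.04, 0.04, 0.04)


def gaussian_ridge(n=40, a=0.08, amplitude=100.0):
    """Bright tube along axis 0 with Gaussian cross-section of scale ``a`` mm.

    The axis runs exactly through the centers of the voxels at in-plane
    index ``n // 2`` so on-axis samples sit at radius zero.
    """
    x = (np.arange(n) + 0.5) * SP[0]
    c = (n // 2 + 0.5) * SP[0]
    Y, Z = np.meshgrid(x - c, x - c, indexing="ij")
    r2 = Y**2 + Z**2
    img = amplitude * np.exp(-r2 / (2 * a**2))
    return ImageVolume(np.broadcast_to(img, (n, n, n)).copy(), SP), c


# ---------------------------------------------------------------- tubeness


def test_constant_volume_has_zero_tubeness():
    vol = ImageVolume(np.full((20, 20, 20), 42.0), SP)
    assert (compute_tubeness(vol).data == 0).all()


@pytest.mark.parametrize("method", ["central", "gaussian"])
def test_gaussian_ridge_matches_analytic_on_axis(method):
    """For a Gaussian ridge of scale a, smoothing with sigma gives a ridge
    of scale s^2 = a^2 + sigma^2 and amplitude A a^2/s^2; on the axis
    lam1 ~ 0, lam2 = lam3 = -A a^2/s^4, so tubeness = A a^2/s^4."""
    a, A, sigma = 0.08, 100.0, 0.04
    vol, c = gaussian_ridge(a=a, amplitude=A)
    tub = compute_tubeness(vol, TubenessConfig(gaussian_sigma=sigma, hessian=method))
    s2 = a**2 + sigma**2
    amp = A * a**2 / s2  # smoothed ridge amplitude
    h = SP[0]
    if method == "central":
        # what the [1,-2,1]/h^2 stencil reads off a Gaussian of scale s
        expected = amp * 2 * (1 - np.exp(-h**2 / (2 * s2))) / h**2
    else:
        expected = amp / s2  # continuous second derivative at the axis
    axis_idx = int(c / SP[1] - 0.5)
    on_axis = tub.data[20, axis_idx, axis_idx]
    assert on_axis == pytest.approx(expected, rel=0.05)
    # maximal on the axis within the mid cross-section
    mid = tub.data[20]
    assert mid.max() == mid[axis_idx, axis_idx]


def test_on_axis_eigenvalue_structure():
    """lam1 ~ 0 and lam2 ~ lam3 < 0 on the axis of a bright tube."""
    vol, c = gaussian_ridge()
    cfg = TubenessConfig(gaussian_sigma=0.04)
    from perivasc.tubeness import _hessian_fields

    H = _hessian_fields(vol.data, SP, cfg.gaussian_sigma, cfg.hessian)
    i = int(c / SP[1] - 0.5)
    lam = np.sort(np.linalg.eigvalsh(H[20, i, i].astype(np.float64)))  # ascending
    lam3, lam2, lam1 = lam
    assert lam2 < 0 and lam3 < 0
    assert lam2 == pytest.approx(lam3, rel=0.02)
    assert abs(lam1) < 0.05 * abs(lam2)


def test_dark_tube_has_zero_tubeness_on_axis():
    vol, c = gaussian_ridge()
    dark = ImageVolume(-vol.data, SP)
    tub = compute_tubeness(dark)
    i = int(c / SP[1] - 0.5)
    assert tub.data[20, i, i] == 0


def test_tubeness_nonnegative_and_zero_where_required(rng):
    vol = ImageVolume(rng.normal(100, 10, (24, 24, 24)), SP)
    tub = compute_tubeness(vol)
    assert (tub.data >= 0).all()


def test_rotation_covariance_under_axis_permutation():
    """Permuting the axes of the volume permutes the tubeness field exactly
    (up to float roundoff): the score has no preferred axis."""
    vol, _ = gaussian_ridge(n=30)
    tub = compute_tubeness(vol).data
    rot = ImageVolume(np.transpose(vol.data, (2, 0, 1)).copy(), SP)
    tub_rot = compute_tubeness(rot).data
    np.testing.assert_allclose(tub_rot, np.transpose(tub, (2, 0, 1)), rtol=1e-4, atol=1e-4)


def test_tubeness_scales_linearly_with_intensity():
    vol, _ = gaussian_ridge(n=30)
    t1 = compute_tubeness(vol).data
    t3 = compute_tubeness(ImageVolume(3.0 * vol.data, SP)).data
    np.testing.assert_allclose(t3, 3.0 * t1, rtol=1e-4, atol=1e-3)


# ---------------------------------------------------------------- remap


def test_remap_identity_when_mode_matches(rng):
    data = rng.normal(100.0, 5.0, (24, 24, 24))
    vol = ImageVolume(data, SP)
    brain = ImageVolume(np.ones((24, 24, 24), dtype=bool), SP)
    mode = histogram_mode(data)
    out = remap_intensity(vol, brain, reference_peak=mode)
    assert out.meta["remap_scale"] == pytest.approx(1.0)
    np.testing.assert_allclose(out.data, vol.data)


def test_remap_aligns_two_modes(rng):
    brain = ImageVolume(np.ones((30, 30, 30), dtype=bool), SP)
    for mode in (100.0, 400.0):
        vol = ImageVolume(rng.normal(mode, mode / 25, (30, 30, 30)), SP)
        out = remap_intensity(vol, brain, reference_peak=200.0)
        new_mode = histogram_mode(out.data)
        vals = out.data.ravel()
        lo, hi = np.percentile(vals, [0.5, 99.5])
        bin_width = (hi - lo) / 256
        assert abs(new_mode - 200.0) <= 2 * bin_width


def test_remap_rejects_constant_volume():
    vol = ImageVolume(np.full((10, 10, 10), 7.0), SP)
    brain = ImageVolume(np.ones((10, 10, 10), dtype=bool), SP)
    with pytest.raises(ValueError):
        remap_intensity(vol, brain, reference_peak=100.0)


# ---------------------------------------------------------------- calibration


def sorted_percentile(values, q):
    """Independent quantile oracle: linear interpolation on the sorted array."""
    v = np.sort(np.asarray(values).ravel())
    pos = q * (v.size - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, v.size - 1)
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


def test_single_naive_threshold_is_its_own_percentile(rng):
    tub = ImageVolume(rng.exponential(1.0, (15, 15, 15)), SP)
    region = {"interior": ImageVolume(np.ones((15, 15, 15), dtype=bool), SP)}
    thr = calibrate_threshold([tub], region, quantile=0.95)
    assert thr["interior"] == pytest.approx(sorted_percentile(tub.data, 0.95))


def test_threshold_is_mean_of_per_volume_percentiles():
    """Region percentiles 3.0 and 4.5 average to 3.75."""
    n = 11**3
    region = {"all": ImageVolume(np.ones((11, 11, 11), dtype=bool), SP)}
    v1 = ImageVolume(np.linspace(0, 3.0 / 0.95, n).reshape(11, 11, 11), SP)
    v2 = ImageVolume(np.linspace(0, 4.5 / 0.95, n).reshape(11, 11, 11), SP)
    thr = calibrate_threshold([v1, v2], region, quantile=0.95)
    assert thr["all"] == pytest.approx(3.75, rel=1e-6)


def test_threshold_converges_to_distribution_quantile(rng):
    true_q = -np.log(0.05)  # exponential(1) 95th percentile
    errs = []
    for n in (10, 40):
        tub = ImageVolume(rng.exponential(1.0, (n, n, n)), SP)
        region = {"r": ImageVolume(np.ones((n, n, n), dtype=bool), SP)}
        thr = calibrate_threshold([tub], region, 0.95)["r"]
        errs.append(abs(thr - true_q))
    assert errs[-1] < 0.02 * true_q


def test_empty_region_rejected(rng):
    tub = ImageVolume(rng.exponential(1.0, (8, 8, 8)), SP)
    region = {"r": ImageVolume(np.zeros((8, 8, 8), dtype=bool), SP)}
    with pytest.raises(ValueError, match="empty"):
        calibrate_threshold([tub], region)
    with pytest.raises(ValueError):
        calibrate_threshold([], region)


# ---------------------------------------------------------------- segmentation


def _masks(shape):
    ones = np.ones(shape, dtype=bool)
    return ImageVolume(ones, SP)


def test_threshold_above_max_gives_empty_mask(rng):
    tub = ImageVolume(rng.random((12, 12, 12)), SP)
    brain = _masks((12, 12, 12))
    seg = segment_pvs(tub, {"all": 2.0}, {"all": brain}, brain)
    assert not seg.data.any()


def test_ventricle_and_exclusions_removed(rng):
    shape = (12, 12, 12)
    tub = ImageVolume(rng.random(shape) + 1.0, SP)  # everything above threshold
    brain = _masks(shape)
    vent = ImageVolume(np.zeros(shape, dtype=bool), SP)
    vent.data[3:6] = True
    excl = ImageVolume(np.zeros(shape, dtype=bool), SP)
    excl.data[:, 0:2] = True
    seg = segment_pvs(tub, {"all": 0.5}, {"all": brain}, brain, vent, [excl])
    assert not (seg.data & vent.data).any()
    assert not (seg.data & excl.data).any()
    assert seg.data.any()


def test_raising_threshold_never_adds_voxels(rng):
    shape = (14, 14, 14)
    tub = ImageVolume(rng.random(shape), SP)
    brain = _masks(shape)
    lo = segment_pvs(tub, {"all": 0.3}, {"all": brain}, brain)
    hi = segment_pvs(tub, {"all": 0.6}, {"all": brain}, brain)
    assert (hi.data <= lo.data).all()


def test_geometry_mismatch_raises(rng):
    tub = ImageVolume(rng.random((10, 10, 10)), SP)
    brain = ImageVolume(np.ones((11, 11, 11), dtype=bool), SP)
    with pytest.raises(GeometryError):
        segment_pvs(tub, {"all": 0.5}, {"all": brain}, brain)


def test_joint_intensity_scaling_leaves_segmentation_unchanged(rng):
    """Multiplying volume and naive controls by c scales tubeness and
    thresholds alike, so the segmented set is identical."""
    vol = ImageVolume(rng.normal(100, 10, (20, 20, 20)), SP)
    naive = ImageVolume(rng.normal(100, 10, (20, 20, 20)), SP)
    brain = _masks((20, 20, 20))
    brain_small = ImageVolume(np.zeros((20, 20, 20), dtype=bool), SP)
    brain_small.data[4:16, 4:16, 4:16] = True

    def run(c):
        seg = PVSSegmenter(surface_shell_voxels=2)
        seg.fit([ImageVolume(c * naive.data, SP)], [brain_small])
        return seg.predict(ImageVolume(c * vol.data, SP), brain_small)

    # power-of-two scale: float rounding commutes, so equality is exact
    np.testing.assert_array_equal(run(1.0).data, run(8.0).data)


def test_brain_regions_partition():
    shape = (20, 20, 20)
    brain = ImageVolume(np.zeros(shape, dtype=bool), SP)
    brain.data[3:17, 3:17, 3:17] = True
    regions = brain_regions(brain, shell_voxels=3)
    assert not (regions["interior"].data & regions["surface"].data).any()
    np.testing.assert_array_equal(
        regions["interior"].data | regions["surface"].data, brain.data
    )


# ---------------------------------------------------------------- percent volume


def test_percent_volume_counts(rng):
    shape = (10, 10, 10)
    voi = ImageVolume(np.zeros(shape, dtype=bool), SP)
    voi.data[:5] = True  # 500 voxels
    pvs = ImageVolume(np.zeros(shape, dtype=bool), SP)
    assert percent_volume(pvs, voi) == 0.0
    pvs.data[0, 0, 0] = True
    assert percent_volume(pvs, voi) == pytest.approx(100.0 / 500)
    # random masks vs brute-force voxel count
    pvs_r = ImageVolume(rng.random(shape) > 0.6, SP)
    voi_r = ImageVolume(rng.random(shape) > 0.4, SP)
    expected = 100.0 * sum(
        1
        for i in range(10)
        for j in range(10)
        for k in range(10)
        if pvs_r.data[i, j, k] and voi_r.data[i, j, k]
    ) / int(voi_r.data.sum())
    assert percent_volume(pvs_r, voi_r) == pytest.approx(expected)
    with pytest.raises(ValueError):
        percent_volume(pvs, ImageVolume(np.zeros(shape, dtype=bool), SP))


# ---------------------------------------------------------------- recovery


def test_segmentation_recovers_phantom_tubes(recovery_phantom, recovery_segmentation):
    from perivasc.pipeline import dice

    truth = recovery_phantom["truth"]
    assert dice(recovery_segmentation, truth.pvs_mask) >= 0.7
    assert not (recovery_segmentation.data & truth.ventricle_mask.data).any()
    assert (recovery_segmentation.data <= truth.brain_mask.data).all()


def test_segmenter_requires_fit_before_predict(recovery_phantom):
    seg = PVSSegmenter()
    truth = recovery_phantom["truth"]
    with pytest.raises(RuntimeError):
        seg.predict(recovery_phantom["volume"], truth.brain_mask)


def test_segmenter_sklearn_params_roundtrip():
    seg = PVSSegmenter(interior_quantile=0.9)
    params = seg.get_params()
    assert params["interior_quantile"] == 0.9
    seg.set_params(gaussian_sigma=0.08)
    assert seg.gaussian_sigma == 0.08
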