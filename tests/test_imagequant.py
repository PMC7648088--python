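"""Enrichment index, fractal metrics, trichrome chain, orientation, fronts."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import fibroswarm as fs
from fibroswarm.errors import InputError, UndefinedMetricError
from fibroswarm.quant import (
    count_nuclei,
    enrichment_index,
    fractal_metrics,
    front_trajectories,
    orientation_field,
    rgb_to_cmyk,
    scar_area,
    trajectory_contour_angles,
)
from fibroswarm.types import ROI, ImageStack

# ---------------------------------------------------------------------------
# enrichment index


def test_enrichment_symmetry_and_extremes():
    g = np.full((32, 32), 7.0)
    assert enrichment_index(g, g) == pytest.approx(0.5)
    assert enrichment_index(g, np.zeros_like(g)) == pytest.approx(1.0)
    assert enrichment_index(np.full((32, 32), 200.0), np.full((32, 32), 600.0)) == pytest.approx(0.25)


def test_enrichment_complement_and_gain_invariance():
    rng = np.random.default_rng(0)
    g, r = rng.random((24, 24)), rng.random((24, 24))
    roi = ROI(mask=np.tri(24, 24, dtype=bool) | np.eye(24, dtype=bool))
    e = enrichment_index(g, r, roi)
    assert e + enrichment_index(r, g, roi) == pytest.approx(1.0)
    assert enrichment_index(5.0 * g, 5.0 * r, roi) == pytest.approx(e)  # common gain
    assert enrichment_index(5.0 * g, r, roi) != pytest.approx(e)  # per-channel gain


def test_enrichment_undefined_on_zero_channels():
    z = np.zeros((8, 8))
    with pytest.raises(UndefinedMetricError):
        enrichment_index(z, z)
    with pytest.raises(InputError):
        enrichment_index(z, np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# fractal metrics


def test_fd_of_reference_patterns():
    assert fractal_metrics(fs.fractal_fixture("filled_square", 729)).fd == pytest.approx(2.0, abs=0.05)
    assert fractal_metrics(fs.fractal_fixture("line", 729)).fd == pytest.approx(1.0, abs=0.05)
    m = fractal_metrics(fs.fractal_fixture("sierpinski", 729, 5))
    assert m.fd == pytest.approx(np.log(8) / np.log(3), abs=0.05)
    assert m.fit_r2 > 0.99


def test_all_ones_lacunarity_zero_at_dividing_scales():
    m = fractal_metrics(np.ones((256, 256), bool), scales=[2, 4, 8, 16, 32, 64])
    assert (m.per_scale["lacunarity"] == 0).all()
    assert m.lacunarity == 0.0


def test_fd_invariant_to_translation_and_rotation():
    carpet = fs.fractal_fixture("sierpinski", 243, 5)
    base = fractal_metrics(carpet).fd
    shifted = np.zeros((300, 300), bool)
    shifted[31:274, 17:260] = carpet
    assert fractal_metrics(shifted).fd == pytest.approx(base, abs=0.02)
    assert fractal_metrics(np.rot90(carpet)).fd == pytest.approx(base, abs=0.02)


def test_dense_fixture_scores_higher_fd_lower_lacunarity_than_porous():
    # dense woven matrix (scar-like) vs sparse porous matrix (healthy-like)
    rng = np.random.default_rng(1)
    d = ndi.gaussian_filter(rng.random((512, 512)), 2)
    p = ndi.gaussian_filter(rng.random((512, 512)), 6)
    dense = d > np.percentile(d, 10)  # ~90% cover, fine holes
    porous = p > np.percentile(p, 80)  # ~20% cover, coarse blobs
    md, mp = fractal_metrics(dense), fractal_metrics(porous)
    assert md.fd > mp.fd
    assert md.lacunarity < mp.lacunarity


def test_fractal_error_contracts():
    with pytest.raises(UndefinedMetricError):
        fractal_metrics(np.zeros((64, 64), bool))
    with pytest.raises(InputError):
        fractal_metrics(np.ones((64, 64), bool), scales=[2, 4, 8])


def test_grayscale_binarised_at_040_of_max():
    img = np.zeros((64, 64))
    img[:32] = 100.0
    img[32:] = 30.0  # below 0.40 * 100
    m = fractal_metrics(img, scales=[2, 4, 8, 16])
    assert m.per_scale["box_count"].iloc[0] == (32 // 2) * (64 // 2)


# ---------------------------------------------------------------------------
# CMYK and trichrome chain


def test_cmyk_reference_pixels():
    px = lambda rgb: rgb_to_cmyk(np.array([[rgb]], float))[0, 0]
    assert np.allclose(px((0.0, 0.0, 0.0)), [0, 0, 0, 1])  # black
    assert np.allclose(px((1.0, 1.0, 1.0)), [0, 0, 0, 0])  # white
    assert np.allclose(px((0.0, 0.0, 1.0)), [1, 1, 0, 0])  # blue
    with pytest.raises(InputError):
        rgb_to_cmyk(np.zeros((4, 4)))


def test_count_nuclei_exact_on_planted_disks(trichrome_fixture):
    img, truth = trichrome_fixture
    n, labels = count_nuclei(img)
    assert n == truth.n_nuclei == 12
    assert labels.max() == 12


def test_count_nuclei_blank_and_size_gate():
    blank, _ = fs.histology_fixture(0, collagen_area=0)
    assert count_nuclei(blank)[0] == 0
    big, _ = fs.histology_fixture(1, nucleus_area=500, seed=3)
    assert count_nuclei(big)[0] == 0  # 500 px² object outside the 30-200 gate


def test_scar_area_recovers_planted_collagen(trichrome_fixture):
    img, truth = trichrome_fixture
    res = scar_area(img)
    assert res["area_px2"] == pytest.approx(truth.collagen_area, rel=0.02)


def test_scar_area_dark_cyan_images():
    white = np.ones((64, 64, 3))
    assert scar_area(white)["area_px2"] == 0
    red = np.zeros((64, 64, 3))
    red[..., 0] = 1.0
    assert scar_area(red)["area_px2"] == 0


# ---------------------------------------------------------------------------
# orientation


def _stripes(angle_deg, shape=(450, 450), period=12.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    th = np.radians(angle_deg)
    return np.sin(2 * np.pi * (yy * np.cos(th) - xx * np.sin(th)) / period)


def _circ_diff(a, b):
    d = np.abs(a - b) % 180.0
    return np.minimum(d, 180.0 - d)


@pytest.mark.parametrize("angle", [0.0, 30.0, 121.0])
def test_orientation_recovers_stripe_angle(angle):
    fld = orientation_field(_stripes(angle), grid_size=150)
    assert _circ_diff(fld.angle_deg, angle).max() <= 2.0
    assert fld.coherence.min() > 0.9
    assert fld.reliable.all()


def test_orientation_rotation_equivariance():
    base = _stripes(0.0, shape=(600, 600))
    rot = ndi.rotate(base, 25.0, reshape=False, order=1)
    centre = rot[150:450, 150:450]
    fld = orientation_field(centre, grid_size=150)
    got = fld.angle_deg[fld.reliable]
    assert _circ_diff(got, -25.0 % 180).max() <= 2.0 or _circ_diff(got, 25.0).max() <= 2.0


def test_flat_image_has_zero_coherence_and_noise_is_incoherent():
    flat = orientation_field(np.full((300, 300), 3.0), grid_size=150)
    assert (flat.coherence == 0).all()
    assert not flat.reliable.any()
    rng = np.random.default_rng(0)
    coh = [
        orientation_field(rng.random((300, 300)), grid_size=150).coherence.mean()
        for _ in range(3)
    ]
    assert np.mean(coh) < 0.2


# ---------------------------------------------------------------------------
# fronts


def _advancing_planar_stack(n=5, shape=(128, 256), step=30):
    frames = []
    for t in range(n):
        img = np.zeros(shape)
        img[:, : 40 + step * t] = 100.0
        frames.append(img)
    return ImageStack(np.array(frames)[:, None], axes="TCYX")


def test_planar_front_trajectories_straight_and_orthogonal():
    model = front_trajectories(_advancing_planar_stack(), smoothing=5)
    angles = trajectory_contour_angles(model)
    assert np.abs(angles - 90.0).max() <= 3.0
    # trajectories are straight +x lines
    for traj in model.trajectories:
        if len(traj) > 5:
            assert np.ptp(traj[:, 1]) < 1.0
            assert traj[-1, 0] > traj[0, 0]


def test_shrinking_circular_front_gives_radial_inward_trajectories():
    yy, xx = np.mgrid[0:200, 0:200]
    frames = []
    for r in (80, 60, 40, 20):
        frames.append(np.where((xx - 100) ** 2 + (yy - 100) ** 2 > r**2, 100.0, 0.0))
    model = front_trajectories([f for f in frames], smoothing=4)
    centre = np.array([100.0, 100.0])
    for traj in model.trajectories:
        if len(traj) < 6:
            continue
        d = traj[5] - traj[0]
        to_centre = centre - traj[0]
        cos = d @ to_centre / (np.linalg.norm(d) * np.linalg.norm(to_centre))
        assert cos > 0.95  # moves towards the centre


def test_static_front_zero_length_trajectories():
    img = np.zeros((64, 64))
    img[:, :30] = 50.0
    model = front_trajectories([img, img, img], smoothing=3)
    assert all(len(t) == 1 for t in model.trajectories)


def test_front_needs_two_usable_times():
    with pytest.raises(InputError):
        front_trajectories([np.zeros((32, 32))], smoothing=2)
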