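"""Iterative PIV: recovery of planted flows, median-test validation, summaries."""

import numpy as np
import pytest

import fibroswarm as fs
from fibroswarm.errors import InputError, InvalidConfigError
from fibroswarm.piv import PIVConfig, VectorField, field_summary, normalized_median_test, run_piv


def _uniform_field(shape=(8, 8), u=2.0, v=1.0):
    return VectorField(
        grid_x=np.arange(shape[1], dtype=float),
        grid_y=np.arange(shape[0], dtype=float),
        u=np.full(shape, u),
        v=np.full(shape, v),
        valid=np.ones(shape, bool),
    )


def test_config_validation():
    with pytest.raises(InvalidConfigError):
        PIVConfig(window_sizes=(16, 32))
    with pytest.raises(InvalidConfigError):
        PIVConfig(window_sizes=(16, 4))
    with pytest.raises(InvalidConfigError):
        PIVConfig(overlap_fraction=1.0)
    cfg = PIVConfig()
    assert cfg.window_sizes == (64, 32, 16)
    assert cfg.mediantest_noise == 0.2 and cfg.mediantest_threshold == 5.0


def test_identical_frames_give_zero_field():
    rng = np.random.default_rng(0)
    a = rng.random((128, 128))
    fld = run_piv(a, a)
    assert np.all(fld.u == 0) and np.all(fld.v == 0)
    assert fld.valid.all()


def test_frame_shape_mismatch_rejected():
    with pytest.raises(InputError):
        run_piv(np.zeros((64, 64)), np.zeros((64, 65)))
    with pytest.raises(InvalidConfigError):
        run_piv(np.zeros((32, 32)), np.zeros((32, 32)))  # 64-window > frame


def test_translation_recovered_within_subpixel(translation_pair):
    a, b, _ = translation_pair
    fld = run_piv(a, b)
    err = np.hypot(fld.u - 5, fld.v + 3)
    assert err[fld.valid].max() <= 0.2
    assert fld.u[fld.valid].mean() == pytest.approx(5.0, abs=0.05)
    assert fld.v[fld.valid].mean() == pytest.approx(-3.0, abs=0.05)


def test_rotation_field_matches_rigid_rotation():
    flow = fs.FlowSpec("rotation", centre=(255.5, 255.5), angle_deg=2.0)
    a, b = fs.advected_pair(flow, shape=(512, 512), seed=4)
    fld = run_piv(a, b)
    pts = fld.points()
    gu, gv = flow.displacement(pts[:, 0], pts[:, 1])
    err = np.hypot(fld.u.ravel() - gu, fld.v.ravel() - gv)[fld.valid.ravel()]
    assert np.sqrt((err**2).mean()) <= 0.3


def test_translation_equivariance_for_integer_shifts():
    # shifting both frames by the same integer vector leaves interior vectors unchanged
    flow = fs.FlowSpec("translation", dx=3.0, dy=2.0)
    a, b = fs.advected_pair(flow, shape=(288, 288), seed=6)
    f0 = run_piv(a[:256, :256], b[:256, :256])
    f1 = run_piv(a[16:272, 16:272], b[16:272, 16:272])
    inner = np.s_[5:-5, 5:-5]
    assert np.allclose(f0.u[inner], f1.u[inner], atol=0.05)
    assert np.allclose(f0.v[inner], f1.v[inner], atol=0.05)


def test_swapping_frames_negates_field():
    a, b = fs.advected_pair(fs.FlowSpec("translation", dx=2.5, dy=1.25), shape=(256, 256), seed=5)
    f1 = run_piv(a, b)
    f2 = run_piv(b, a)
    both = f1.valid & f2.valid
    assert np.abs(f1.u + f2.u)[both].max() < 0.3
    assert np.abs(f1.v + f2.v)[both].max() < 0.3


def test_error_non_increasing_with_passes():
    a, b = fs.advected_pair(fs.FlowSpec("translation", dx=4.0, dy=2.0), shape=(256, 256), seed=8)
    errs = []
    for windows in [(64,), (64, 32), (64, 32, 16)]:
        fld = run_piv(a, b, PIVConfig(window_sizes=windows))
        err = np.hypot(fld.u - 4, fld.v - 2)[fld.valid]
        errs.append(err.mean())
    assert errs[1] <= errs[0] + 1e-3
    assert errs[2] <= errs[1] + 1e-3


def test_single_pass_matches_bruteforce_ncc_argmax():
    # oracle equivalence: FFT-accelerated NCC peak == explicit spatial NCC argmax
    flow = fs.FlowSpec("translation", dx=4.0, dy=7.0)
    a, b = fs.advected_pair(flow, shape=(256, 256), seed=7)
    fld = run_piv(a, b, PIVConfig(window_sizes=(64,), mediantest_threshold=1e9))
    w, step, search = 64, 32, 32
    for i, y0 in enumerate(range(0, 256 - w + 1, step)):
        for j, x0 in enumerate(range(0, 256 - w + 1, step)):
            wa = a[y0 : y0 + w, x0 : x0 + w]
            best = (-2.0, 0, 0)
            for dy in range(max(-y0, -search), min(256 - w - y0, search) + 1):
                for dx in range(max(-x0, -search), min(256 - w - x0, search) + 1):
                    wb = b[y0 + dy : y0 + dy + w, x0 + dx : x0 + dx + w]
                    za, zb = wa - wa.mean(), wb - wb.mean()
                    c = (za * zb).sum() / np.sqrt((za * za).sum() * (zb * zb).sum())
                    if c > best[0]:
                        best = (c, dy, dx)
            assert round(float(fld.u[i, j])) == best[2]
            assert round(float(fld.v[i, j])) == best[1]


def test_median_test_flags_exactly_the_planted_outlier():
    fld = _uniform_field()
    fld.u[4, 4] += 50.0
    out = normalized_median_test(fld, noise=0.2, threshold=5.0)
    assert (~out.valid).sum() == 1 and not out.valid[4, 4]
    # residual = |50 - 0| / (0 + 0.2) = 250 for the planted vector
    assert out.residual[4, 4] == pytest.approx(250.0)
    assert out.u[4, 4] == pytest.approx(2.0)  # replaced by neighbourhood median


def test_median_test_keeps_uniform_field():
    out = normalized_median_test(_uniform_field(), noise=0.2, threshold=5.0)
    assert out.valid.all()
    assert np.all(out.residual == 0)


def test_median_test_grid_too_small():
    with pytest.raises(InvalidConfigError):
        normalized_median_test(_uniform_field(shape=(1, 3)))


def test_field_summary_345():
    fld = _uniform_field(u=3.0, v=4.0)
    s = field_summary(fld, dt=30.0)
    assert np.allclose(s.magnitude, 5.0 / 30.0)
    assert s.mean_speed == pytest.approx(5.0 / 30.0)
    assert np.allclose(s.direction_deg, np.degrees(np.arctan2(4, 3)))


def test_field_summary_zero_and_opposing_populations():
    assert field_summary(_uniform_field(u=0.0, v=0.0), dt=30.0).mean_speed == 0.0
    fld = _uniform_field(u=1.0, v=0.0)
    fld.u[:, 4:] = -1.0
    s = field_summary(fld, dt=10.0)
    assert s.mean_speed == pytest.approx(1.0 / 10.0)
    assert s.mean_direction_deg is None  # circular mean undefined
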