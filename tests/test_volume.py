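import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skullray import (
    CTVolume,
    FormatError,
    dda_traverse,
    hu_histogram,
    hu_profile,
    load_volume,
    neighbor_average_sample,
    save_volume,
    threshold_mask,
)


def _random_volume(rng, n=16):
    data = rng.integers(-1000, 3000, size=(n, n, n)).astype(np.int16)
    return CTVolume(data, spacing=(0.7, 1.0, 1.3), origin=(-5.0, 2.5, 0.0))


@pytest.mark.parametrize("fmt,name", [("nifti", "v.nii.gz"), ("metaimage", "v.mha"), ("raw+json", "v.json")])
def test_save_load_round_trip(tmp_path, fmt, name):
    vol = _random_volume(np.random.default_rng(7))
    save_volume(vol, tmp_path / name, format=fmt)
    back = load_volume(tmp_path / name, format=fmt)
    np.testing.assert_array_equal(np.asarray(back.data), np.asarray(vol.data))
    np.testing.assert_allclose(back.spacing, vol.spacing)
    np.testing.assert_allclose(back.origin, vol.origin)


def test_load_zero_volume_identity(tmp_path):
    vol = CTVolume(np.zeros((8, 8, 8), dtype=np.int16), spacing=(1, 1, 1), origin=(0, 0, 0))
    save_volume(vol, tmp_path / "z.json", format="raw+json")
    back = load_volume(tmp_path / "z.json")
    assert back.shape == (8, 8, 8)
    assert np.all(np.asarray(back.data) == 0)


def test_non_3d_rejected(tmp_path):
    with pytest.raises(FormatError):
        CTVolume(np.zeros((4, 4)), spacing=(1, 1, 1), origin=(0, 0, 0))
    (tmp_path / "flat.json").write_text(
        '{"shape": [4, 4], "spacing_mm": [1, 1, 1], "origin_mm": [0, 0, 0], "dtype": "int16"}'
    )
    np.zeros(16, dtype=np.int16).tofile(tmp_path / "flat.raw")
    with pytest.raises(FormatError):
        load_volume(tmp_path / "flat.json")


def test_missing_sidecar_metadata(tmp_path):
    (tmp_path / "bad.json").write_text('{"shape": [4, 4, 4]}')
    with pytest.raises(FormatError):
        load_volume(tmp_path / "bad.json")


def test_world_voxel_round_trip():
    vol = _random_volume(np.random.default_rng(0))
    pts = np.random.default_rng(1).uniform(0, 10, size=(50, 3))
    for p in pts:
        np.testing.assert_allclose(vol.voxel_to_world(vol.world_to_voxel(p)), p, atol=1e-9)


# ---------------------------------------------------------------------------
# Histogram / threshold
# ---------------------------------------------------------------------------


def test_histogram_constant_volume_single_bin():
    vol = CTVolume(np.full((6, 6, 6), 700.0), (1, 1, 1), (0, 0, 0))
    _, counts = hu_histogram(vol, bins=4)
    assert counts.sum() == 6**3
    assert (counts > 0).sum() == 1


def test_histogram_two_valued_split():
    data = np.zeros((4, 4, 4))
    data[:2] = 1000.0
    vol = CTVolume(data, (1, 1, 1), (0, 0, 0))
    _, counts = hu_histogram(vol, bins=2)
    assert counts[0] == counts[1] == 32


def test_histogram_counts_total():
    vol = _random_volume(np.random.default_rng(3))
    edges, counts = hu_histogram(vol, bins=37)
    assert counts.sum() == vol.data.size
    assert edges[0] == vol.data.min() and edges[-1] == vol.data.max()


def test_threshold_mask_matches_shell_ground_truth(shell96):
    vol, gt = shell96
    mask = threshold_mask(vol, 1155, 3000)
    np.testing.assert_array_equal(mask, gt.shell_mask)


def test_threshold_mask_extremes(water_vol):
    assert threshold_mask(water_vol, -2000, 4000).all()
    assert not threshold_mask(water_vol, 1155, 3000).any()
    with pytest.raises(ValueError):
        threshold_mask(water_vol, 10, -10)


# ---------------------------------------------------------------------------
# DDA traversal
# ---------------------------------------------------------------------------


def _dda_oracle(start, end, n=10_000):
    """Dense supersampling: sample the segment uniformly and round to voxels."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = np.rint(np.asarray(start) + t * (np.asarray(end) - np.asarray(start))).astype(int)
    return {tuple(p) for p in pts}


def _segment_hits_cube(start, end, voxel, min_chord=1e-9):
    """Exact slab test: does the segment cross the unit cube centered on voxel?"""
    p0 = np.asarray(start, dtype=float)
    d = np.asarray(end, dtype=float) - p0
    v = np.asarray(voxel, dtype=float)
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        lo, hi = v[ax] - 0.5, v[ax] + 0.5
        if d[ax] == 0.0:
            if not lo <= p0[ax] <= hi:
                return False
            continue
        ta, tb = sorted(((lo - p0[ax]) / d[ax], (hi - p0[ax]) / d[ax]))
        t0, t1 = max(t0, ta), min(t1, tb)
    return t1 - t0 > min_chord


def test_dda_axis_aligned():
    out = dda_traverse((0, 0, 0), (3, 0, 0))
    np.testing.assert_array_equal(out, [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])


def test_dda_degenerate_segment():
    np.testing.assert_array_equal(dda_traverse((2, 5, 7), (2, 5, 7)), [[2, 5, 7]])


def test_dda_matches_supersampling_oracle():
    out = dda_traverse((0, 0, 0), (5, 3, 2))
    assert {tuple(v) for v in out} == _dda_oracle((0, 0, 0), (5, 3, 2))
    assert tuple(out[0]) == (0, 0, 0) and tuple(out[-1]) == (5, 3, 2)


@given(st.integers(0, 10**6))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_dda_random_segments_properties(seed):
    rng = np.random.default_rng(seed)
    start, end = rng.integers(0, 32, size=(2, 3))
    out = dda_traverse(start, end)
    assert tuple(out[0]) == tuple(start) and tuple(out[-1]) == tuple(end)
    if len(out) > 1:
        steps = np.diff(out, axis=0)
        assert np.all(np.abs(steps) <= 1) and np.all(np.any(steps != 0, axis=1))
    ours = {tuple(v) for v in out}
    # complete: every densely sampled voxel is listed; sound: every listed voxel
    # is genuinely crossed by the segment (exact slab test)
    assert _dda_oracle(start, end) <= ours
    assert all(_segment_hits_cube(start, end, v) for v in ours)


# ---------------------------------------------------------------------------
# Neighbor averaging
# ---------------------------------------------------------------------------


def test_neighbor_average_constant():
    vol = CTVolume(np.full((7, 7, 7), 500.0), (1, 1, 1), (0, 0, 0))
    assert neighbor_average_sample(vol, (3, 3, 3)) == pytest.approx(500.0)


def test_neighbor_average_impulse_center_excluded():
    data = np.zeros((7, 7, 7))
    data[3, 3, 3] = 2600.0
    vol = CTVolume(data, (1, 1, 1), (0, 0, 0))
    assert neighbor_average_sample(vol, (3, 3, 3)) == pytest.approx(0.0)
    assert neighbor_average_sample(vol, (4, 3, 3)) == pytest.approx(100.0)  # 2600 / 26


def test_neighbor_average_bounds_and_boundary():
    vol = CTVolume(np.full((5, 5, 5), 10.0), (1, 1, 1), (0, 0, 0))
    # corner has only 7 existing neighbors, mean is still 10
    assert neighbor_average_sample(vol, (0, 0, 0)) == pytest.approx(10.0)
    with pytest.raises(IndexError):
        neighbor_average_sample(vol, (5, 0, 0))


def test_neighbor_average_commutes_with_offset():
    rng = np.random.default_rng(11)
    data = rng.uniform(0, 2000, size=(9, 9, 9))
    v1 = CTVolume(data, (1, 1, 1), (0, 0, 0))
    v2 = CTVolume(data + 250.0, (1, 1, 1), (0, 0, 0))
    for coord in [(4, 4, 4), (0, 3, 8), (1, 1, 1)]:
        assert neighbor_average_sample(v2, coord) == pytest.approx(
            neighbor_average_sample(v1, coord) + 250.0, abs=1e-6
        )


# ---------------------------------------------------------------------------
# HU profile
# ---------------------------------------------------------------------------


def _tv(x):
    return np.abs(np.diff(x)).sum()


def test_profile_constant_volume(water_vol):
    prof = hu_profile(water_vol, (-20.0, 0.0, 0.0), (20.0, 0.0, 0.0))
    assert len(prof) > 5
    assert np.allclose(prof.values, 0.0)
    assert np.all(np.diff(prof.positions) > 0)


def test_profile_smoothing_reduces_total_variation():
    from skullray import ShellPhantomSpec, make_shell_phantom

    vol, gt = make_shell_phantom(
        ShellPhantomSpec(noise_sd=80.0), shape=(96, 96, 96), spacing=2.0, seed=5
    )
    start, end = np.array([0.0, 0.0, 92.0]), np.array([0.0, 0.0, 0.0])
    rough = hu_profile(vol, start, end, smooth=False)
    smooth = hu_profile(vol, start, end, smooth=True)
    assert _tv(smooth.values) < _tv(rough.values)


def test_profile_brackets_shell_crossing(shell96):
    vol, gt = shell96
    start = np.array([0.0, 0.0, 92.0])
    prof = hu_profile(vol, start, np.zeros(3), smooth=False)
    above = prof.values > 1155
    assert above.any()
    runs = np.flatnonzero(above)
    assert np.all(np.diff(runs) == 1), "skull window hits must be one contiguous run"
    dist_from_center = 92.0 - prof.positions[runs]
    assert dist_from_center.max() <= gt.outer_radius_mm + 2 * np.sqrt(3)
    assert dist_from_center.min() >= gt.inner_radius_mm - 2 * np.sqrt(3)


def test_profile_positions_span_clipped_length(water_vol):
    start, end = np.array([-10.0, -4.0, 6.0]), np.array([18.0, 12.0, -8.0])
    prof = hu_profile(water_vol, start, end)
    seg_len = np.linalg.norm(end - start)
    diag = np.linalg.norm(water_vol.spacing)
    assert prof.positions[0] >= 0.0
    assert seg_len - diag <= prof.positions[-1] <= seg_len


def test_profile_outside_volume_is_empty(water_vol):
    prof = hu_profile(water_vol, (500.0, 500.0, 500.0), (600.0, 500.0, 500.0))
    assert len(prof) == 0
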