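"""Occupancy scoring: normalization, trilinear sampling, thresholding, matrix."""

import numpy as np
import pytest

from ribohet.blocks import BlockLibrary, BlockSpec
from ribohet.errors import DegenerateVolumeError, GeometryError, ValidationError
from ribohet.io_formats import AtomicModel, AtomRecord, DensityVolume
from ribohet.occupancy import (
    block_occupancy,
    normalize_volume,
    occupancy_matrix,
    occupancy_values,
    trilinear_sample,
)
from ribohet.synthetic import make_phantom, render_volume


def _vol(data, voxel=1.0, origin=(0.0, 0.0, 0.0)):
    return DensityVolume(np.asarray(data, dtype=np.float32), (voxel,) * 3, origin)


class TestNormalize:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        out = normalize_volume(_vol(rng.normal(2.0, 3.0, size=(6, 6, 6))))
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1.0) < 1e-6

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        once = normalize_volume(_vol(rng.normal(size=(5, 5, 5))))
        twice = normalize_volume(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-6)

    def test_two_level_hand_computed(self):
        data = np.zeros((4, 4, 4))
        data[:2] = 2.0  # half 0, half 2 -> z-scores -1 and +1
        out = normalize_volume(_vol(data))
        assert set(np.round(np.unique(out.data), 6)) == {-1.0, 1.0}

    def test_constant_rejected(self):
        with pytest.raises(DegenerateVolumeError):
            normalize_volume(_vol(np.full((4, 4, 4), 3.0)))


class TestTrilinear:
    def test_constant_volume(self):
        vol = _vol(np.full((5, 5, 5), 7.0))
        values, outside = trilinear_sample(vol, [[1.3, 2.7, 3.1]])
        assert not outside[0]
        assert values[0] == pytest.approx(7.0)

    def test_exact_on_linear_field(self):
        # trilinear interpolation reproduces f = x exactly at arbitrary points
        ix = np.arange(8, dtype=float)
        data = np.broadcast_to(ix[:, None, None], (8, 8, 8))
        vol = _vol(data)
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 7, size=(50, 3))
        values, outside = trilinear_sample(vol, pts)
        assert not outside.any()
        np.testing.assert_allclose(values, pts[:, 0], atol=1e-12)

    def test_voxel_center_returns_stored_value(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(6, 6, 6))
        vol = _vol(data, voxel=2.0, origin=(10.0, 0.0, -4.0))
        point = np.array([10.0 + 2 * 3, 0.0 + 2 * 1, -4.0 + 2 * 5])
        values, _ = trilinear_sample(vol, [point])
        assert values[0] == pytest.approx(data[3, 1, 5])

    def test_outside_points_flagged(self):
        vol = _vol(np.ones((4, 4, 4)))
        values, outside = trilinear_sample(vol, [[-1.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        assert outside.tolist() == [True, False]
        assert np.isnan(values[0])


class TestBlockOccupancy:
    def test_all_above_threshold(self):
        vol = _vol(np.full((4, 4, 4), 5.0))
        assert block_occupancy(vol, [[1, 1, 1], [2, 2, 2]], threshold=1.5) == 1.0

    def test_background_noise_scores_near_zero(self):
        rng = np.random.default_rng(7)
        vol = normalize_volume(_vol(rng.normal(size=(16, 16, 16))))
        atoms = rng.uniform(2, 13, size=(40, 3))
        occ = block_occupancy(vol, atoms, threshold=1.5)
        # direct count oracle at the same atoms
        values, outside = trilinear_sample(vol, atoms)
        expected = np.mean(np.where(outside, False, values >= 1.5))
        assert occ == pytest.approx(expected)
        assert occ <= 0.1

    def test_two_level_fixture_four_of_ten(self):
        data = np.zeros((8, 8, 8))
        data[:4] = 10.0  # rendered density in half the box
        vol = normalize_volume(_vol(data))
        inside = [[1.0, y, 4.0] for y in (1, 2, 3, 4)]
        background = [[6.0, y, 4.0] for y in (1, 2, 3, 4, 5, 6)]
        occ = block_occupancy(vol, inside + background, threshold=0.0)
        assert occ == pytest.approx(0.4)

    def test_empty_coords_rejected(self):
        vol = _vol(np.ones((4, 4, 4)))
        with pytest.raises(ValidationError):
            block_occupancy(vol, np.empty((0, 3)))

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        vol = normalize_volume(_vol(rng.normal(size=(12, 12, 12))))
        atoms = rng.uniform(1, 10, size=(60, 3))
        occs = [block_occupancy(vol, atoms, threshold=t) for t in np.linspace(-2, 2, 9)]
        assert all(a >= b for a, b in zip(occs, occs[1:]))


class TestOccupancyMatrix:
    def test_fully_present_volume_row_of_ones(self, phantom):
        model, library = phantom
        vol = render_volume(model, library, np.ones(len(library)), noise_sd=0.0)
        matrix = occupancy_matrix([vol], model, library, threshold=0.5)
        np.testing.assert_array_equal(occupancy_values(matrix)[0], 1.0)

    def test_absent_block_scores_lower(self, phantom):
        model, library = phantom
        occ_full = np.ones(len(library))
        occ_missing = occ_full.copy()
        occ_missing[3] = 0.0
        v1 = render_volume(model, library, occ_full, noise_sd=0.01, seed=1, label="full")
        v2 = render_volume(model, library, occ_missing, noise_sd=0.01, seed=2, label="gap")
        matrix = occupancy_matrix([v1, v2], model, library)
        vals = occupancy_values(matrix)
        assert vals[1, 3] < vals[0, 3]

    def test_geometry_mismatch_rejected(self, phantom):
        model, library = phantom
        v1 = _vol(np.random.default_rng(0).normal(size=(8, 8, 8)))
        v2 = _vol(np.random.default_rng(1).normal(size=(10, 8, 8)))
        with pytest.raises(GeometryError):
            occupancy_matrix([v1, v2], model, library)

    def test_library_order_permutes_columns_only(self, phantom):
        model, library = phantom
        rng = np.random.default_rng(5)
        vol = render_volume(model, library, rng.uniform(0.3, 1.0, len(library)),
                            noise_sd=0.02, seed=5)
        fwd = occupancy_matrix([vol], model, library)
        rev_lib = BlockLibrary(list(reversed(library.blocks)), library.reference_id)
        rev = occupancy_matrix([vol], model, rev_lib)
        for name in library.names:
            assert fwd.at[0, name] == rev.at[0, name]

    def test_matches_nearest_voxel_oracle(self, phantom):
        # brute-force oracle: per atom, threshold the nearest voxel's density
        model, library = phantom
        rng = np.random.default_rng(9)
        vol = render_volume(
            model, library, rng.uniform(0.0, 1.0, len(library)),
            grid=(16, 16, 16), voxel_size=2.1, noise_sd=0.05, seed=9,
        )
        nvol = normalize_volume(vol)
        matrix = occupancy_matrix([vol], model, library, threshold=1.5)
        diffs = []
        for j, block in enumerate(library.blocks):
            coords = np.array(
                [[a.x, a.y, a.z] for a in model.atoms if block.contains(a.chain, a.resnum)]
            )
            idx = np.round(coords / 2.1).astype(int)
            inside = np.all((idx >= 0) & (idx < 16), axis=1)
            vals = np.zeros(len(idx))
            vals[inside] = nvol.data[tuple(idx[inside].T)]
            oracle = np.mean(vals >= 1.5)
            diffs.append(abs(occupancy_values(matrix)[0, j] - oracle))
        assert np.mean(diffs) <= 0.05


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_rendered_occupancy_recovered(seed):
    """Rendering a block at occupancy q and scoring recovers q within 0.1."""
    model, library = make_phantom(seed=seed)
    rng = np.random.default_rng(seed)
    q = rng.uniform(0.2, 1.0, size=len(library))
    vol = render_volume(model, library, q, amplitude=1.0, noise_sd=0.2 * 1.0,
                        seed=seed)
    matrix = occupancy_matrix([vol], model, library, threshold=1.5)
    recovered = occupancy_values(matrix)[0]
    assert np.max(np.abs(recovered - q)) <= 0.1
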