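"""3D centroid, periphery distance, normalization, frequency curves."""

import numpy as np
import pytest
from scipy import ndimage

import radialpos as rp
from radialpos import EmptyInputError, EmptyMaskError, PointOutsideNucleusError
from radialpos.segmentation import Morphometrics, NucleusMask


def brute_force_periphery_distance(point, mask, spacing):
    """Independent loop-based implementation of the face-midpoint
    periphery distance: for every foreground voxel, check its six
    neighbors; every background (or off-grid) neighbor contributes a
    face-midpoint surface sample."""
    pz, py, px = point
    best = np.inf
    nz, ny, nx = mask.shape
    dz, dy, dx = spacing
    steps = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                for sz, sy, sx in steps:
                    zz, yy, xx = z + sz, y + sy, x + sx
                    outside = (
                        zz < 0 or zz >= nz or yy < 0 or yy >= ny
                        or xx < 0 or xx >= nx or not mask[zz, yy, xx]
                    )
                    if outside:
                        cz = z * dz + sz * dz / 2.0
                        cy = y * dy + sy * dy / 2.0
                        cx = x * dx + sx * dx / 2.0
                        d = np.sqrt((cz - pz) ** 2 + (cy - py) ** 2 + (cx - px) ** 2)
                        best = min(best, d)
    return best


def random_blob(rng, shape=(10, 14, 16)):
    field = ndimage.gaussian_filter(rng.random(shape), sigma=2.0)
    mask = field > np.quantile(field, 0.7)
    labels, n = ndimage.label(mask)
    if n == 0:
        return None
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (np.argmax(sizes) + 1)


class TestTerritoryCentroid:
    def test_single_voxel(self):
        m = np.zeros((5, 6, 7), dtype=bool)
        m[2, 3, 4] = True
        assert rp.territory_centroid(m, (0.2, 0.1, 0.1)) == pytest.approx(
            (0.4, 0.3, 0.4)
        )

    def test_symmetric_cube(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        assert rp.territory_centroid(m, (1, 1, 1)) == pytest.approx((3, 3, 3))

    def test_two_voxel_midpoint(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[0, 0, 0] = m[0, 0, 2] = True
        assert rp.territory_centroid(m, (1, 1, 1)) == pytest.approx((0, 0, 1))

    def test_empty_raises(self):
        with pytest.raises(EmptyMaskError):
            rp.territory_centroid(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))


class TestDistanceToPeriphery:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob(rng)
        assume_ok = mask is not None and mask.sum() > 10
        assert assume_ok
        spacing = tuple(rng.uniform(0.05, 0.3, 3))
        nuc = NucleusMask(mask=mask, spacing=spacing)
        idx = np.argwhere(mask)[mask.sum() // 2]
        point = tuple(idx * np.asarray(spacing))
        d = rp.distance_to_periphery(point, nuc)
        expected = brute_force_periphery_distance(point, mask, spacing)
        assert d == pytest.approx(expected, abs=1e-9)

    def test_point_next_to_boundary(self):
        mask = np.zeros((5, 5, 9), dtype=bool)
        mask[1:4, 1:4, 1:8] = True
        nuc = NucleusMask(mask=mask, spacing=(0.2, 0.1, 0.1))
        # voxel (2, 2, 6): boundary foreground voxel at x index 7,
        # nearest exposed face midpoint at x = 7.5 voxels
        d = rp.distance_to_periphery((0.4, 0.2, 0.6), nuc)
        assert d == pytest.approx(0.1, abs=0.051)

    def test_spacing_scale_equivariance(self):
        rng = np.random.default_rng(11)
        mask = random_blob(rng)
        idx = np.argwhere(mask)[0]
        base = (0.2, 0.1, 0.1)
        scaled = tuple(3.0 * s for s in base)
        p1 = tuple(idx * np.asarray(base))
        p3 = tuple(idx * np.asarray(scaled))
        d1 = rp.distance_to_periphery(p1, NucleusMask(mask=mask, spacing=base))
        d3 = rp.distance_to_periphery(p3, NucleusMask(mask=mask, spacing=scaled))
        assert d3 == pytest.approx(3.0 * d1, rel=1e-12)

    def test_ellipsoid_center_distance_converges_to_minor_semi_axis(self):
        """For a centered point in a flattened ellipsoid the periphery
        distance approaches the smallest semi-axis as voxels shrink."""
        errs = []
        for f in (2.0, 1.0):  # coarse, fine
            sp = (0.2 * f, 0.1 * f, 0.1 * f)
            semi = (2.0, 6.0, 8.0)
            dims = [int(2 * (s + 0.5) / h) + 1 for s, h in zip(semi, sp)]
            ctr = [(n - 1) / 2 * h for n, h in zip(dims, sp)]
            z = (np.arange(dims[0]) * sp[0] - ctr[0])[:, None, None]
            y = (np.arange(dims[1]) * sp[1] - ctr[1])[None, :, None]
            x = (np.arange(dims[2]) * sp[2] - ctr[2])[None, None, :]
            mask = (z / semi[0]) ** 2 + (y / semi[1]) ** 2 + (x / semi[2]) ** 2 <= 1
            d = rp.distance_to_periphery(tuple(ctr), NucleusMask(mask=mask, spacing=sp))
            errs.append(abs(d - semi[0]))
            assert abs(d - semi[0]) <= max(sp) / 2 + 1e-9
        assert errs[1] <= errs[0] + 1e-12  # finer grid no worse

    def test_point_outside_raises(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        nuc = NucleusMask(mask=mask, spacing=(1, 1, 1))
        with pytest.raises(PointOutsideNucleusError):
            rp.distance_to_periphery((0.0, 0.0, 0.0), nuc)


class TestNormalizeDistance:
    M = Morphometrics(area=150.0, major_axis=20.0, minor_axis=10.0, aspect_ratio=2.0)

    def test_formulas(self):
        assert rp.normalize_distance(3.0, self.M, "avg_axes") == pytest.approx(0.2)
        assert rp.normalize_distance(3.0, self.M, "major_axis") == pytest.approx(0.15)
        assert rp.normalize_distance(0.0, self.M, "avg_axes") == 0.0
        assert rp.normalize_distance(0.0, self.M, "major_axis") == 0.0

    def test_major_norm_never_exceeds_avg_norm(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            major = rng.uniform(10, 30)
            minor = rng.uniform(5, major)
            m = Morphometrics(area=1.0, major_axis=major, minor_axis=minor,
                              aspect_ratio=major / minor)
            d = rng.uniform(0, 5)
            assert rp.normalize_distance(d, m, "major_axis") <= rp.normalize_distance(
                d, m, "avg_axes"
            ) + 1e-15

    def test_bad_axes_raise(self):
        bad = Morphometrics(area=1.0, major_axis=0.0, minor_axis=0.0, aspect_ratio=1.0)
        with pytest.raises(ValueError):
            rp.normalize_distance(1.0, bad, "avg_axes")


class TestFrequencyDistribution:
    def test_single_value_lands_in_half_open_bin(self):
        fd = rp.frequency_distribution([1.0], bin_width=0.5)
        assert fd.counts.sum() == fd.n == 1
        k = int(fd.counts.argmax())
        assert fd.bin_edges[k] == pytest.approx(1.0)  # bin [1.0, 1.5)

    def test_counts_conserved(self):
        rng = np.random.default_rng(13)
        d = rng.uniform(0, 8, 20)
        fd = rp.frequency_distribution(d, bin_width=0.5)
        assert fd.counts.sum() == 20
        assert np.all(np.diff(fd.bin_edges) > 0)

    def test_identical_values_single_bin(self):
        fd = rp.frequency_distribution([2.2] * 7, bin_width=0.5)
        assert (fd.counts > 0).sum() == 1

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            rp.frequency_distribution([], bin_width=0.5)


class TestRankInvariance:
    M_ROUND = Morphometrics(area=1, major_axis=16.0, minor_axis=14.0,
                            aspect_ratio=16 / 14)

    def test_identical_shape_nuclei_trivially_invariant(self):
        cohorts = {
            "A": [(1.0, self.M_ROUND), (2.0, self.M_ROUND)],
            "B": [(3.0, self.M_ROUND), (4.0, self.M_ROUND)],
        }
        assert rp.rank_invariance_check(cohorts)

    def test_single_cohort_vacuous(self):
        assert rp.rank_invariance_check({"A": [(1.0, self.M_ROUND)]})
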