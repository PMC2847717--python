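"""Equal-area shell partition and per-shell profile measurement."""

import numpy as np
import pytest

import radialpos as rp
from radialpos import MaskTooSmall, SampleSizeError, ZeroSignalError
from radialpos.errors import DegenerateDapiError
from radialpos.segmentation import NucleusMask

from conftest import make_disk_mask, make_ellipse_mask, mask_to_image


class TestShellPartition:
    def test_disk_shells_match_analytic_annuli(self, disk50):
        """Equal-area annuli of a disk have outer radii R*sqrt(1-k/5); the
        computed shell boundaries agree within one pixel at R=50."""
        part = rp.compute_shell_partition(disk50)
        n = disk50.mask.shape[0]
        c = n // 2
        yy, xx = np.mgrid[:n, :n]
        rho = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        bounds = [50.0 * np.sqrt(1 - k / 5) for k in range(6)]  # k=0..5
        for k in range(1, 6):  # shell k occupies radii (bounds[k], bounds[k-1]]
            rho_k = rho[part.labels == k]
            assert rho_k.max() <= bounds[k - 1] + 1.0
            assert rho_k.min() >= bounds[k] - 1.0

    def test_partition_tiles_mask_exactly(self, disk50):
        part = rp.compute_shell_partition(disk50)
        assert np.array_equal(part.labels > 0, disk50.mask)
        assert part.areas.sum() == disk50.mask.sum()
        assert sorted(np.unique(part.labels[disk50.mask])) == [1, 2, 3, 4, 5]

    @pytest.mark.parametrize("seed", range(6))
    def test_random_ellipse_areas_balanced(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(25, 55)
        b = rng.uniform(15, a)
        ell = make_ellipse_mask(a, b, angle=rng.uniform(0, np.pi))
        part = rp.compute_shell_partition(ell)
        total = ell.mask.sum()
        # each shell within one tie-group (plus rounding) of total/5
        from scipy import ndimage

        edt = ndimage.distance_transform_edt(ell.mask)
        _, counts = np.unique(edt[ell.mask], return_counts=True)
        tol = counts.max() + 1
        assert np.all(np.abs(part.areas - total / 5) <= tol)

    def test_shells_are_nested_by_depth(self, disk50):
        """Deeper shells have strictly larger distance-transform values,
        up to ties."""
        from scipy import ndimage

        part = rp.compute_shell_partition(disk50)
        edt = ndimage.distance_transform_edt(disk50.mask)
        for k in range(1, 5):
            assert edt[part.labels == k + 1].min() >= edt[part.labels == k].min()

    def test_tiny_mask_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:3, 1:3] = True
        with pytest.raises(MaskTooSmall):
            rp.compute_shell_partition(NucleusMask(mask=mask, spacing=(1, 1)))


class TestShellProfile:
    def test_self_normalization_identity(self, disk50):
        """probe = c*DAPI gives a flat normalized profile of ones."""
        part = rp.compute_shell_partition(disk50)
        rng = np.random.default_rng(0)
        dapi_px = (rng.random(disk50.mask.shape) * 50 + 50) * disk50.mask
        dapi = rp.Image2D(pixels=dapi_px, pixel_size=1.0)
        for c in (0.5, 1.0, 3.0):
            probe = rp.Image2D(pixels=c * dapi_px, pixel_size=1.0)
            prof = rp.measure_shell_profile(part, dapi, probe)
            np.testing.assert_allclose(prof.normalized, 1.0, atol=1e-9)

    def test_probe_confined_to_shell_one(self, disk50):
        part = rp.compute_shell_partition(disk50)
        dapi = mask_to_image(disk50)
        probe_px = (part.labels == 1).astype(float) * 37.0
        prof = rp.measure_shell_profile(
            part, dapi, rp.Image2D(pixels=probe_px, pixel_size=1.0)
        )
        np.testing.assert_allclose(
            prof.raw_probe_pct, [100, 0, 0, 0, 0], atol=1e-9
        )
        # DAPI% of shell 1 follows from the actual partition areas
        expected_dapi1 = 100.0 * part.areas[0] / part.areas.sum()
        assert prof.normalized[0] == pytest.approx(100.0 / expected_dapi1)
        np.testing.assert_allclose(prof.normalized[1:], 0.0, atol=1e-12)

    def test_zero_probe_raises(self, disk50):
        part = rp.compute_shell_partition(disk50)
        dapi = mask_to_image(disk50)
        zero = rp.Image2D(pixels=np.zeros(disk50.mask.shape), pixel_size=1.0)
        with pytest.raises(ZeroSignalError):
            rp.measure_shell_profile(part, dapi, zero)

    def test_zero_dapi_shell_raises(self, disk50):
        part = rp.compute_shell_partition(disk50)
        dapi_px = ((part.labels > 0) & (part.labels < 5)).astype(float) * 80.0
        probe = mask_to_image(disk50)
        with pytest.raises(DegenerateDapiError):
            rp.measure_shell_profile(
                part, rp.Image2D(pixels=dapi_px, pixel_size=1.0), probe
            )

    def test_rotation_invariance_of_profile(self):
        """A nucleus and its 90°-rotated copy give identical profiles —
        the tie-group rule makes shell assignment orientation-stable."""
        spec = rp.SyntheticSpec(n_nuclei=1, radial_fraction=0.6, seed=21)
        dapi, probe, _ = rp.generate_nucleus_2d(spec, 0)
        p0, _, _ = rp.analyze_nucleus(dapi, probe)
        dapi_r = rp.Image2D(pixels=np.rot90(dapi.pixels).copy(),
                            pixel_size=dapi.pixel_size)
        probe_r = rp.Image2D(pixels=np.rot90(probe.pixels).copy(),
                             pixel_size=probe.pixel_size)
        p1, part1, _ = rp.analyze_nucleus(dapi_r, probe_r)
        _, part0, _ = rp.analyze_nucleus(dapi, probe)
        np.testing.assert_array_equal(part0.areas, part1.areas)
        np.testing.assert_allclose(p0.normalized, p1.normalized,
                                   rtol=0, atol=1e-9)


class TestAggregateCohort:
    @staticmethod
    def _profile(normalized):
        normalized = np.asarray(normalized, dtype=float)
        dapi = np.full(5, 20.0)
        probe = normalized * dapi
        probe = 100 * probe / probe.sum()
        return rp.ShellProfile(
            raw_probe_pct=probe, raw_dapi_pct=dapi, normalized=probe / dapi
        )

    def test_identical_profiles_have_zero_sem(self):
        prof = self._profile([1, 1, 1, 1, 1])
        cohort = rp.aggregate_cohort([prof] * 4, "c")
        np.testing.assert_allclose(cohort.sem, 0.0, atol=1e-12)
        np.testing.assert_allclose(cohort.mean, prof.normalized)

    def test_two_profile_sem_closed_form(self):
        a = self._profile([2, 1, 1, 1, 1])
        b = self._profile([1, 1, 1, 1, 2])
        cohort = rp.aggregate_cohort([a, b], "c")
        expected = np.abs(a.normalized - b.normalized) / 2.0
        np.testing.assert_allclose(cohort.sem, expected, atol=1e-12)

    def test_single_profile_rejected(self):
        with pytest.raises(SampleSizeError):
            rp.aggregate_cohort([self._profile([1, 1, 1, 1, 1])], "c")
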