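"""Disk-ROI enrichment and signed line-profile peak positions."""

import numpy as np
import pytest

from centrofish import (CentrosomeFrame, LineProfile, SceneConfig,
                        disk_enrichment, line_profile, peak_position,
                        simulate_cell)
from centrofish.quantify import disk_pixel_indices
from conftest import add_gaussian

PX = 0.1


def make_frame(center, axis=(0.0, 1.0)):
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    return CentrosomeFrame(center=center, partner_center=center - 8 * axis,
                           axis=axis / np.linalg.norm(axis))


class TestDiskEnrichment:
    def test_uniform_image_enrichment_zero(self):
        img = np.full((224, 224), 13.0)
        mask = np.ones_like(img, dtype=bool)
        d, b, e = disk_enrichment(img, np.array([11.2, 11.2]), 2.0, PX,
                                  mask, [np.array([11.2, 11.2])], seed=0)
        assert e == 0.0
        assert d == b

    def test_point_source_recovered_within_1pct(self):
        img = np.full((224, 224), 5.0)
        center = np.array([11.25, 11.25])
        sigma_px = 1.2
        amp = 200.0
        add_gaussian(img, center / PX, sigma_px, amp)
        integrated = amp * 2 * np.pi * sigma_px**2
        mask = np.ones_like(img, dtype=bool)
        _, _, e = disk_enrichment(img, center, 2.0, PX, mask, [center], seed=1)
        assert e == pytest.approx(integrated, rel=0.01)

    @pytest.mark.parametrize("center", [(11.2, 11.2), (11.23, 11.87),
                                        (5.051, 17.449)])
    def test_disk_pixels_match_bruteforce(self, center):
        """Pixel membership equals a brute-force scan over all pixel centers."""
        shape = (224, 224)
        yy, xx = disk_pixel_indices(shape, np.array(center), 2.0, PX)
        got = set(zip(yy.tolist(), xx.tolist()))
        expected = set()
        for i in range(shape[0]):
            for j in range(shape[1]):
                if ((i - center[0] / PX) ** 2
                        + (j - center[1] / PX) ** 2) <= 20.0**2:
                    expected.add((i, j))
        assert got == expected

    def test_enrichment_linear_in_intensity(self, rng):
        img = rng.poisson(30.0, (224, 224)).astype(float)
        mask = np.ones_like(img, dtype=bool)
        center = np.array([11.2, 8.0])
        args = (2.0, PX, mask, [center])
        d1, b1, e1 = disk_enrichment(img, center, *args, seed=3)
        d3, b3, e3 = disk_enrichment(3.0 * img, center, *args, seed=3)
        assert (d3, b3, e3) == (3 * d1, 3 * b1, 3 * e1)

    def test_background_placement_respects_exclusion(self):
        """No background disk centre may fall near an excluded centrosome."""
        img = np.zeros((224, 224))
        add_gaussian(img, (112, 112), 3.0, 1e6)  # huge signal at exclusion
        mask = np.ones_like(img, dtype=bool)
        center = np.array([11.2, 11.2])
        _, b, _ = disk_enrichment(img, center, 2.0, PX, mask,
                                  [center, np.array([11.2, 11.2])], seed=4)
        assert b < 1e5  # background disks avoided the excluded blob region

    def test_cell_too_small_errors(self):
        img = np.zeros((224, 224))
        mask = np.zeros_like(img, dtype=bool)
        mask[0, 0] = True  # disk cannot fit inside the image there
        with pytest.raises(RuntimeError, match="too small"):
            disk_enrichment(img, np.array([11.2, 11.2]), 2.0, PX, mask,
                            [], seed=0)


class TestLineProfile:
    def _channels(self, protein_offset=-0.3):
        cfg = SceneConfig(noise=False, protein_offset=protein_offset,
                          n_rna_free=0, n_rna_centrosomal=0)
        stack, truth = simulate_cell(cfg, 0)
        names = ("marker", "rna", "protein", "dna")
        return dict(zip(names, stack)), truth

    def test_marker_self_centering(self):
        channels, truth = self._channels()
        frame = make_frame(truth.centrosome_centers[1],
                           truth.spindle_axes[1])
        prof = line_profile(channels, frame, PX)
        assert abs(peak_position(prof, "marker")) <= 0.05 / 2 + 1e-12

    @pytest.mark.parametrize("offset", [-0.4, -0.3, -0.2])
    def test_protein_offset_recovery_noiseless(self, offset):
        channels, truth = self._channels(protein_offset=offset)
        for i in range(2):
            frame = make_frame(truth.centrosome_centers[i],
                               truth.spindle_axes[i])
            prof = line_profile(channels, frame, PX)
            assert peak_position(prof, "protein") == pytest.approx(
                offset, abs=0.05)

    def test_constant_channel_ties_to_zero(self):
        channels, truth = self._channels()
        channels["dna"] = np.full_like(channels["dna"], 4.0)
        frame = make_frame(truth.centrosome_centers[0],
                           truth.spindle_axes[0])
        prof = line_profile(channels, frame, PX)
        assert peak_position(prof, "dna") == 0.0

    def test_out_of_bounds_errors(self):
        channels, _ = self._channels()
        frame = make_frame((0.3, 0.3))
        with pytest.raises(ValueError, match="leaves the image"):
            line_profile(channels, frame, PX)

    def test_grid_symmetric_uniform(self):
        channels, truth = self._channels()
        frame = make_frame(truth.centrosome_centers[1],
                           truth.spindle_axes[1])
        prof = line_profile(channels, frame, PX, half_length=1.0, step=0.05)
        np.testing.assert_allclose(prof.positions, -prof.positions[::-1],
                                   atol=1e-12)
        steps = np.diff(prof.positions)
        np.testing.assert_allclose(steps, steps[0])


class TestPeakPosition:
    def _profile(self, values, half=1.0, step=0.05):
        n = int(round(half / step))
        pos = np.arange(-n, n + 1) * step
        return LineProfile(positions=pos, values={"c": np.asarray(values,
                                                                  float)})

    def test_monotone_increasing_hits_boundary(self):
        prof = self._profile(np.linspace(0, 1, 41))
        assert peak_position(prof, "c") == pytest.approx(1.0)

    def test_symmetric_double_peak_prefers_spindle_side(self):
        pos = np.arange(-20, 21) * 0.05
        v = np.zeros(41)
        v[np.isclose(np.abs(pos), 0.4)] = 7.0  # equal peaks at +-0.4
        prof = LineProfile(positions=pos, values={"c": v})
        assert peak_position(prof, "c") == pytest.approx(-0.4)

    def test_matches_bruteforce_on_200_random_profiles(self, rng):
        """Oracle: independent brute-force scan with the same tie rules."""
        for _ in range(200):
            # quantized values force ties regularly
            v = rng.integers(0, 6, size=41).astype(float)
            prof = self._profile(v)
            best = None
            for p, val in zip(prof.positions, v):
                key = (-val, abs(p), p > 0)
                if best is None or key < best[0]:
                    best = (key, p)
            assert peak_position(prof, "c") == pytest.approx(best[1])

    def test_all_nan_errors(self):
        prof = self._profile(np.full(41, np.nan))
        with pytest.raises(ValueError, match="NaN"):
            peak_position(prof, "c")
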