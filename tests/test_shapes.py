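"""Boundary tracing and Fourier-descriptor tests."""

import numpy as np
import pytest
from shapely.geometry import box

from conftest import disk_pixels, random_star_polygon

from colonycomp import shapes, sim, zones
from colonycomp.shapes import (
    BoundaryLoop,
    DegenerateBoundaryError,
    DissimilarityMatrix,
    boundary_dft,
    eccentricity,
    fourier_descriptors,
    normalize_spectrum,
    pairwise_fd_distances,
    shape_correspondence,
    trace_boundary,
)
from colonycomp.zones import PatchRecord, VoronoiZone


def _circle_loop(r, center=(0.0, 0.0), m=256):
    th = 2 * np.pi * np.arange(m) / m
    return BoundaryLoop(
        np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
    )


def _brute_force_magnitudes(loop, n_max):
    """O(MN) direct summation oracle for the descriptor magnitudes."""
    z = loop.coords[:, 0] + 1j * loop.coords[:, 1]
    m = len(z)
    return np.array(
        [
            np.abs(np.sum(z * np.exp(-2j * np.pi * n * np.arange(m) / m)) / m)
            for n in range(1, n_max + 1)
        ]
    )


class TestTraceBoundary:
    def test_solid_3x3_patch_yields_its_border_pixels(self):
        pix = np.array([(r, c) for r in range(3) for c in range(3)])
        loop = trace_boundary(PatchRecord(1, pix, False))
        assert len(loop) == 8
        coords = {tuple(xy) for xy in loop.coords}
        assert coords == {(c, r) for r in range(3) for c in range(3) if (r, c) != (1, 1)}

    def test_consecutive_raster_points_are_moore_adjacent(self):
        pix = disk_pixels(6.5, center=(10, 10))
        loop = trace_boundary(PatchRecord(1, pix, False))
        gaps = np.abs(np.diff(np.vstack([loop.coords, loop.coords[:1]]), axis=0))
        assert gaps.max() <= 1

    def test_odd_traced_loop_gets_last_point_duplicated(self):
        # this 7-pixel component traces to 9 boundary steps, padded to 10
        pix = np.array([[0, 0], [1, 1], [1, 2], [2, 0], [2, 1], [3, 1], [4, 1]])
        loop = trace_boundary(PatchRecord(1, pix, False))
        assert len(loop) % 2 == 0
        np.testing.assert_array_equal(loop.coords[-1], loop.coords[-2])

    def test_polygon_resampled_to_requested_count(self, rng):
        poly = random_star_polygon(rng, 8)
        loop = trace_boundary(poly, n_samples=64)
        assert len(loop) == 64
        assert loop.signed_area > 0  # counterclockwise

    def test_degenerate_patch_rejected(self):
        with pytest.raises(DegenerateBoundaryError):
            trace_boundary(PatchRecord(1, np.array([[0, 0], [0, 1]]), False))

    def test_multi_component_patch_rejected(self):
        pix = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [5, 5], [5, 6], [6, 5], [6, 6]])
        with pytest.raises(ValueError, match="connected"):
            trace_boundary(PatchRecord(1, pix, False))


class TestFourierDescriptors:
    def test_circle_spectrum_closed_form(self):
        # a circle of radius r has f_1 = r and no higher harmonics
        loop = _circle_loop(7.3, center=(3.0, -2.0))
        spec = fourier_descriptors(loop, 20)
        assert spec.magnitudes[0] == pytest.approx(7.3, rel=1e-3)
        assert spec.magnitudes[1:].max() < 1e-3 * spec.magnitudes[0]

    def test_translation_moves_only_the_zeroth_coefficient(self):
        loop = _circle_loop(2.0)
        shifted = BoundaryLoop(loop.coords + np.array([10.0, -7.0]))
        f1 = fourier_descriptors(loop, 10).magnitudes
        f2 = fourier_descriptors(shifted, 10).magnitudes
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_matches_brute_force_summation_oracle(self):
        loop = trace_boundary(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]), n_samples=256)
        ours = fourier_descriptors(loop, 20).magnitudes
        oracle = _brute_force_magnitudes(loop, 20)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_odd_length_loop_rejected(self):
        th = 2 * np.pi * np.arange(9) / 9
        loop = BoundaryLoop(np.column_stack([np.cos(th), np.sin(th)]))
        with pytest.raises(ValueError, match="even"):
            fourier_descriptors(loop, 2)

    def test_descriptor_count_limited_by_samples(self):
        with pytest.raises(ValueError):
            fourier_descriptors(_circle_loop(1.0, m=16), 20)

    def test_parseval_energy_identity(self, rng):
        # total spectral energy equals the mean squared boundary radius
        for _ in range(5):
            loop = trace_boundary(random_star_polygon(rng) + rng.normal(0, 3, 2), 256)
            c = boundary_dft(loop)
            z = loop.coords[:, 0] + 1j * loop.coords[:, 1]
            assert np.sum(np.abs(c) ** 2) == pytest.approx(
                np.mean(np.abs(z) ** 2), abs=1e-9 * np.mean(np.abs(z) ** 2)
            )


class TestNormalization:
    def test_scaled_copy_has_identical_signature(self, rng):
        poly = random_star_polygon(rng, 9)
        a = normalize_spectrum(fourier_descriptors(trace_boundary(poly, 256), 20))
        b = normalize_spectrum(fourier_descriptors(trace_boundary(poly * 3.0, 256), 20))
        np.testing.assert_allclose(a.magnitudes, b.magnitudes, atol=1e-9)
        assert a.magnitudes[0] == 1.0

    def test_rotated_copy_has_identical_signature(self, rng):
        poly = random_star_polygon(rng, 9)
        th = np.deg2rad(37)
        rot = poly @ np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        a = normalize_spectrum(fourier_descriptors(trace_boundary(poly, 256), 20))
        b = normalize_spectrum(fourier_descriptors(trace_boundary(rot, 256), 20))
        np.testing.assert_allclose(a.magnitudes, b.magnitudes, atol=1e-9)

    def test_circle_signature_is_delta_at_one(self):
        spec = normalize_spectrum(fourier_descriptors(_circle_loop(5.0), 10))
        assert spec.magnitudes[0] == 1.0
        assert spec.magnitudes[1:].max() < 1e-3

    def test_degenerate_spectrum_rejected(self):
        spec = shapes.FDSpectrum(magnitudes=np.zeros(5))
        with pytest.raises(ValueError):
            normalize_spectrum(spec)

    def test_invariance_suite_continuous(self, rng):
        # translated / rotated / scaled / cyclically relabelled copies of 50
        # random polygons give the same signature within 1e-6 when the
        # boundary is densely resampled
        for _ in range(50):
            poly = random_star_polygon(rng)
            base = normalize_spectrum(
                fourier_descriptors(trace_boundary(poly, 4096), 20)
            ).magnitudes
            th = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            variants = [
                poly + rng.normal(0, 10, 2),
                poly @ rot.T,
                poly * rng.uniform(0.2, 5),
                np.roll(poly, int(rng.integers(1, len(poly))), axis=0),
            ]
            for v in variants:
                mags = normalize_spectrum(
                    fourier_descriptors(trace_boundary(v, 4096), 20)
                ).magnitudes
                np.testing.assert_allclose(mags, base, atol=1e-6)

    def test_invariance_suite_raster(self, rng):
        # exact raster transforms (translation, quarter-turn, 2x upscale) of
        # a blob change the re-traced signature by at most 2 percent
        mask = np.zeros((40, 40), dtype=bool)
        pix = disk_pixels(9.5, center=(18, 20))
        mask[pix[:, 0], pix[:, 1]] = True
        mask[10:16, 22:30] = True  # asymmetric bump

        def signature(m):
            p = PatchRecord(1, np.argwhere(m), False)
            loop = shapes.resample_loop(trace_boundary(p), 256)
            return normalize_spectrum(fourier_descriptors(loop, 20)).magnitudes

        base = signature(mask)
        translated = np.zeros((60, 60), dtype=bool)
        translated[7:47, 11:51] = mask
        rotated = np.rot90(mask)
        upscaled = np.kron(mask, np.ones((2, 2), dtype=bool))
        for variant in (translated, rotated, upscaled):
            mags = signature(variant)[: len(base)]
            assert np.max(np.abs(mags - base[: len(mags)])) < 0.02

    def test_mirror_image_has_identical_magnitudes(self, rng):
        poly = random_star_polygon(rng, 11)
        a = normalize_spectrum(fourier_descriptors(trace_boundary(poly, 256), 20))
        b = normalize_spectrum(
            fourier_descriptors(trace_boundary(poly * np.array([-1, 1]), 256), 20)
        )
        np.testing.assert_allclose(a.magnitudes, b.magnitudes, atol=1e-9)


class TestDistances:
    def test_identical_spectra_have_zero_distance(self):
        s = shapes.FDSpectrum(magnitudes=np.array([1.0, 0.2, 0.1]), normalized=True)
        D = pairwise_fd_distances([s, s])
        assert D.values[0, 1] == 0.0

    def test_three_four_five(self):
        a = shapes.FDSpectrum(magnitudes=np.array([1.0, 0.0, 0.0]), normalized=True)
        b = shapes.FDSpectrum(magnitudes=np.array([1.0, 0.3, 0.4]), normalized=True)
        assert pairwise_fd_distances([a, b]).values[0, 1] == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self, rng):
        mats = rng.random((20, 8))
        mats[:, 0] = 1.0
        specs = [shapes.FDSpectrum(magnitudes=m, normalized=True) for m in mats]
        D = pairwise_fd_distances(specs)
        for i in range(20):
            for j in range(20):
                assert D.values[i, j] == pytest.approx(
                    np.linalg.norm(mats[i] - mats[j]), abs=1e-12
                )

    def test_mismatched_descriptor_counts_rejected(self):
        a = shapes.FDSpectrum(magnitudes=np.ones(5), normalized=True)
        b = shapes.FDSpectrum(magnitudes=np.ones(6), normalized=True)
        with pytest.raises(ValueError):
            pairwise_fd_distances([a, b])

    def test_unnormalized_spectra_rejected(self):
        a = shapes.FDSpectrum(magnitudes=np.ones(5), normalized=False)
        with pytest.raises(ValueError):
            pairwise_fd_distances([a, a])


class TestEccentricity:
    def test_disk_is_isotropic(self):
        assert eccentricity(PatchRecord(1, disk_pixels(15.5), False)) < 0.05

    def test_two_to_one_ellipse(self):
        rr, cc = np.meshgrid(np.arange(-25, 26), np.arange(-45, 46), indexing="ij")
        inside = (cc / 40.0) ** 2 + (rr / 20.0) ** 2 <= 1.0
        pix = np.column_stack([rr[inside], cc[inside]])
        e = eccentricity(PatchRecord(1, pix, False))
        assert e == pytest.approx(np.sqrt(1 - 0.25), abs=0.01)

    def test_square_is_isotropic(self):
        pix = np.array([(r, c) for r in range(20) for c in range(20)])
        assert eccentricity(PatchRecord(1, pix, False)) < 0.05

    def test_collinear_pixels_flagged_degenerate(self):
        pix = np.array([(5, c) for c in range(2, 13)])
        e, degenerate = eccentricity(PatchRecord(1, pix, False), return_degenerate=True)
        assert e == 1.0
        assert degenerate


class TestCorrespondence:
    def test_patch_equal_to_rasterized_zone_is_near_zero(self):
        pts = np.array([[x, y] for y in (5, 15, 25) for x in (5, 15, 25)], dtype=float)
        zl = zones.voronoi_tessellate(pts, zones.default_domain((30, 30)))
        raster = zones.rasterize_zones(zl, (30, 30))
        centre = [z for z in zl if z.founder_id == 5][0]
        patch = [p for p in zones.extract_patches(raster) if p.lineage_id == 5][0]
        assert shape_correspondence(patch, centre) < 0.05

    def test_square_zone_vs_disk_patch_matches_fd_oracle(self):
        # equal-area square and disk: distance must equal the brute-force FD
        # distance computed independently from the same two boundaries
        zone = VoronoiZone(1, box(0, 0, 20, 20), (10.0, 10.0), False)
        patch = PatchRecord(1, disk_pixels(20 / np.sqrt(np.pi), center=(30, 30)), False)
        d = shape_correspondence(patch, zone)
        patch_loop = shapes.resample_loop(trace_boundary(patch), 256)
        zone_loop = trace_boundary(zone, n_samples=256)
        n = 20
        fa = _brute_force_magnitudes(patch_loop, n)
        fb = _brute_force_magnitudes(zone_loop, n)
        oracle = np.linalg.norm(fa / fa[0] - fb / fb[0])
        assert d == pytest.approx(oracle, abs=1e-10)
        assert d > 0.01  # square and circle genuinely differ

    def test_perimeter_regime_patches_track_zones_more_closely(self):
        # growth restricted to colony perimeters produces near-Voronoi
        # patches; exponential-area growth produces ragged ones
        means = {}
        for regime in ("exponential_area", "perimeter"):
            dists = []
            for seed in (0, 1):
                cfg = sim.SimConfig(
                    width=150, height=150, n_seeds=36, rng_seed=seed, regime=regime
                )
                result = sim.run(cfg)
                _, _, zl = zones.analyze_label_map(result.founders, result.label_map)
                by_id = {z.founder_id: z for z in zl}
                for p in zones.extract_patches(result.label_map):
                    if not p.touches_edge and p.lineage_id in by_id:
                        dists.append(shape_correspondence(p, by_id[p.lineage_id]))
            means[regime] = np.mean(dists)
        assert means["perimeter"] < means["exponential_area"]
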