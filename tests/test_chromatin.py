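"""Voronoi density thresholding, nanodomain clustering, nucleus geometry."""

import numpy as np
import pytest

from cellmech.chromatin import (
    LocalizationSet,
    calibrate_threshold,
    classify_heterochromatin,
    classify_peripheral,
    cluster_domains,
    nucleus_boundary,
    peripheral_thickness,
    voronoi_areas,
)
from cellmech.simulate import gen_nucleus_localizations


def square_grid(n=20, spacing=100.0):
    xs = np.arange(n) * spacing
    X, Y = np.meshgrid(xs, xs)
    return np.column_stack([X.ravel(), Y.ravel()])


class TestVoronoi:
    def test_regular_lattice_interior_areas(self):
        vmap = voronoi_areas(LocalizationSet(points=square_grid(spacing=100.0)))
        np.testing.assert_allclose(vmap.interior_areas, 1e4, rtol=1e-9)

    def test_hull_cells_flagged(self):
        vmap = voronoi_areas(LocalizationSet(points=square_grid(n=10)))
        # all four edges of the grid touch the hull
        assert vmap.boundary_flag.sum() >= 4 * 10 - 4

    def test_dense_region_has_smaller_areas(self):
        locs = gen_nucleus_localizations(
            n_background=1500, domains=[((0, 0), 150, 500)],
            nucleus_radius_nm=3000, jitter_sd=5, seed=0)
        vmap = voronoi_areas(locs)
        inside = locs.truth_labels == 0
        keep = ~vmap.boundary_flag
        assert (np.median(vmap.areas[inside & keep])
                < np.median(vmap.areas[~inside & keep]))

    def test_duplicates_deduplicated(self):
        pts = np.vstack([square_grid(n=5), [[0.0, 0.0]]])
        with pytest.warns(UserWarning, match="dedup"):
            vmap = voronoi_areas(LocalizationSet(points=pts))
        assert len(vmap.areas) == len(pts)
        assert vmap.areas[0] == vmap.areas[-1]

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            voronoi_areas(LocalizationSet(points=pts))


class TestThreshold:
    def test_single_nucleus_median(self):
        locs = gen_nucleus_localizations(n_background=2000, seed=1)
        vmap = voronoi_areas(locs)
        thr = calibrate_threshold([vmap], target_fraction=0.5)
        med = np.median(vmap.interior_areas)
        assert thr == pytest.approx(med, rel=0.05)

    def test_mean_fraction_hits_target(self):
        maps = [voronoi_areas(gen_nucleus_localizations(
            n_background=2000, domains=[(None, 150, 600)], seed=s))
            for s in range(4)]
        thr = calibrate_threshold(maps, target_fraction=0.5)
        fracs = [np.mean(m.interior_areas < thr) for m in maps]
        assert np.mean(fracs) == pytest.approx(0.5, abs=1e-3)

    def test_disjoint_distributions(self):
        # two nuclei whose area distributions do not overlap
        a = LocalizationSet(points=square_grid(spacing=10.0))
        b = LocalizationSet(points=square_grid(spacing=1000.0))
        thr = calibrate_threshold([voronoi_areas(a), voronoi_areas(b)],
                                  target_fraction=0.5)
        fa = np.mean(voronoi_areas(a).interior_areas < thr)
        fb = np.mean(voronoi_areas(b).interior_areas < thr)
        assert np.mean([fa, fb]) == pytest.approx(0.5, abs=1e-3)

    def test_target_one_includes_everything(self):
        vmap = voronoi_areas(LocalizationSet(points=square_grid()))
        thr = calibrate_threshold([vmap], target_fraction=1.0)
        assert np.all(vmap.interior_areas < thr)

    def test_empty_control_errors(self):
        with pytest.raises(ValueError, match="empty"):
            calibrate_threshold([])


class TestClassification:
    def test_threshold_extremes(self):
        vmap = voronoi_areas(LocalizationSet(points=square_grid()))
        assert classify_heterochromatin(vmap, 1e-3).sum() == 0
        labels = classify_heterochromatin(vmap, 1e12)
        assert labels.sum() == (~vmap.boundary_flag).sum()

    def test_monotone_in_threshold(self):
        locs = gen_nucleus_localizations(n_background=1000, seed=2)
        vmap = voronoi_areas(locs)
        counts = [classify_heterochromatin(vmap, t).sum()
                  for t in np.quantile(vmap.interior_areas, [0.2, 0.5, 0.8])]
        assert counts[0] <= counts[1] <= counts[2]


class TestDomains:
    def test_single_planted_domain(self):
        locs = gen_nucleus_localizations(
            n_background=2000, domains=[((500, 300), 80, 500)],
            nucleus_radius_nm=4000, jitter_sd=5, seed=1)
        domains = cluster_domains(locs.points[locs.truth_labels == 0])
        assert len(domains) == 1
        assert domains[0].radius == pytest.approx(80.0, rel=0.1)

    def test_two_separated_domains_membership(self):
        locs = gen_nucleus_localizations(
            n_background=0, domains=[((-1500, 0), 80, 400), ((1500, 0), 80, 400)],
            nucleus_radius_nm=4000, jitter_sd=5, seed=2)
        domains = cluster_domains(locs.points)
        assert len(domains) == 2
        for dom in domains:
            labs = locs.truth_labels[dom.members]
            agreement = np.mean(labs == np.bincount(labs).argmax())
            assert agreement >= 0.95

    def test_radius_area_relation(self):
        locs = gen_nucleus_localizations(
            n_background=0, domains=[((0, 0), 100, 600)], jitter_sd=0, seed=3)
        dom, = cluster_domains(locs.points)
        assert dom.radius == pytest.approx(np.sqrt(dom.area / np.pi), rel=1e-12)

    def test_partition_disjoint(self):
        locs = gen_nucleus_localizations(
            n_background=300, domains=[((-1000, 0), 80, 300), ((1000, 0), 80, 300)],
            nucleus_radius_nm=3000, jitter_sd=5, seed=4)
        domains = cluster_domains(locs.points)
        all_members = np.concatenate([d.members for d in domains])
        assert len(all_members) == len(np.unique(all_members))

    def test_voronoi_adjacency_mode_agrees(self):
        locs = gen_nucleus_localizations(
            n_background=0, domains=[((-1500, 0), 80, 400), ((1500, 0), 80, 400)],
            nucleus_radius_nm=4000, jitter_sd=5, seed=5)
        d_db = cluster_domains(locs.points, method="dbscan")
        d_vor = cluster_domains(locs.points, method="voronoi_adjacency")
        assert len(d_db) == len(d_vor) == 2
        radii = sorted(d.radius for d in d_db), sorted(d.radius for d in d_vor)
        np.testing.assert_allclose(radii[0], radii[1], rtol=0.05)


class TestNucleusGeometry:
    def test_disk_radius(self):
        locs = gen_nucleus_localizations(n_background=5000,
                                         nucleus_radius_nm=5000, seed=6)
        geom = nucleus_boundary(locs)
        assert geom.R == pytest.approx(5000.0, rel=0.03)

    def test_square_equivalent_radius(self, rng):
        L = 8000.0
        pts = rng.uniform(0, L, size=(5000, 2))
        geom = nucleus_boundary(LocalizationSet(points=pts))
        assert geom.R == pytest.approx(L / np.sqrt(np.pi), rel=0.05)

    def test_radius_scales_linearly(self):
        locs = gen_nucleus_localizations(n_background=3000,
                                         nucleus_radius_nm=4000, seed=7)
        R1 = nucleus_boundary(locs).R
        R2 = nucleus_boundary(LocalizationSet(points=2.0 * locs.points)).R
        assert R2 == pytest.approx(2.0 * R1, rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="100"):
            nucleus_boundary(LocalizationSet(points=np.zeros((10, 2))))


class TestPeripheralRule:
    def test_band_membership(self):
        locs = gen_nucleus_localizations(
            n_background=4000, nucleus_radius_nm=4000,
            domains=[((0, 0), 80, 300), ((3600, 0), 80, 300)], jitter_sd=5,
            seed=8)
        geom = nucleus_boundary(locs)
        for i, expect in ((0, False), (1, True)):
            pts = locs.points[locs.truth_labels == i]
            dom, = classify_peripheral(cluster_domains(pts), geom,
                                       hetero_points=pts)
            assert dom.peripheral is expect

    def test_zero_band_no_peripheral(self):
        locs = gen_nucleus_localizations(
            n_background=4000, nucleus_radius_nm=4000,
            domains=[((3600, 0), 80, 300)], jitter_sd=5, seed=9)
        geom = nucleus_boundary(locs)
        pts = locs.points[locs.truth_labels == 0]
        dom, = classify_peripheral(cluster_domains(pts), geom, band=0.0,
                                   hetero_points=pts)
        assert dom.peripheral is False


class TestThickness:
    def _shell(self, R, width, n, seed):
        rng = np.random.default_rng(seed)
        r = np.sqrt(rng.uniform(((R - width) / R) ** 2, 1.0, n)) * R
        th = rng.uniform(0, 2 * np.pi, n)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    def test_planted_shell_width(self):
        R = 5000.0
        shell = self._shell(R, 300.0, 20000, seed=0)
        bg = gen_nucleus_localizations(n_background=3000, nucleus_radius_nm=R,
                                       seed=1).points
        geom = nucleus_boundary(LocalizationSet(points=np.vstack([bg, shell])))
        res = peripheral_thickness(geom, shell)
        assert res["mean"] == pytest.approx(300.0, rel=0.15)

    def test_doubling_width_doubles_thickness(self):
        R = 5000.0
        geoms, means = [], []
        for width, n in ((250.0, 16000), (500.0, 32000)):
            shell = self._shell(R, width, n, seed=2)
            geom = nucleus_boundary(LocalizationSet(points=shell))
            means.append(peripheral_thickness(geom, shell)["mean"])
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.2)

    def test_no_points_warns_zero(self):
        locs = gen_nucleus_localizations(n_background=2000, seed=3)
        geom = nucleus_boundary(locs)
        with pytest.warns(UserWarning, match="thickness"):
            res = peripheral_thickness(geom, np.zeros((0, 2)))
        assert res["mean"] == 0.0


class TestScaleInvariance:
    def test_geometry_scales_counts_invariant(self):
        locs = gen_nucleus_localizations(
            n_background=2000, domains=[((500, 300), 80, 400)],
            nucleus_radius_nm=3000, jitter_sd=5, seed=10)
        d1 = cluster_domains(locs.points[locs.truth_labels == 0])
        d2 = cluster_domains(2.5 * locs.points[locs.truth_labels == 0])
        assert len(d1) == len(d2) == 1
        assert d2[0].radius == pytest.approx(2.5 * d1[0].radius, rel=1e-9)
        assert len(d2[0].members) == len(d1[0].members)
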