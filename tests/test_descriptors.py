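"""Shape, surface, profile, distance and RDF descriptors against oracles."""

import numpy as np
import pytest

from conftest import make_system
from wdpu.descriptors import (eccentricity, end_to_end_distances,
                              radial_density_profile, radius_of_gyration, rdf,
                              shape_descriptors, summarize, surface_area)


class TestRadiusOfGyration:
    def test_single_particle_is_zero(self):
        assert radius_of_gyration(make_system([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_equal_masses_at_unit_offsets(self):
        s = make_system([[1, 0, 0], [-1, 0, 0]])
        assert radius_of_gyration(s) == pytest.approx(1.0)

    def test_matches_definitional_double_pass_sum(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(scale=5.0, size=(100, 3))
        m = rng.uniform(1.0, 20.0, size=100)
        s = make_system(pos, masses=m)
        com = (m[:, None] * pos).sum(0) / m.sum()        # first pass
        rg2 = (m * ((pos - com) ** 2).sum(1)).sum() / m.sum()   # second pass
        assert radius_of_gyration(s) == pytest.approx(np.sqrt(rg2), rel=1e-12)

    def test_matches_mdanalysis(self):
        import MDAnalysis as mda
        rng = np.random.default_rng(1)
        pos = rng.normal(scale=8.0, size=(200, 3))
        m = rng.uniform(1.0, 16.0, size=200)
        u = mda.Universe.empty(200, trajectory=True)
        u.add_TopologyAttr("masses", m)
        u.atoms.positions = pos.astype(np.float32)
        s = make_system(pos, masses=m)
        assert radius_of_gyration(s) == pytest.approx(
            float(u.atoms.radius_of_gyration()), rel=1e-5)

    def test_zero_mass_rejected(self):
        s = make_system([[0, 0, 0], [1, 0, 0]], masses=[0.0, 0.0])
        with pytest.raises(ValueError, match="mass"):
            radius_of_gyration(s)


class TestEccentricity:
    def test_cube_vertices_are_isotropic(self):
        verts = [[x, y, z] for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)]
        assert eccentricity(make_system(verts)) == pytest.approx(0.0, abs=1e-12)

    def test_discrete_ellipsoid_matches_analytic_moment_ratio(self):
        # oracle: for a cloud with diagonal second moments (s², s², (cs)²),
        # I = (m Σ) diag(s²+c²s², s²+c²s², 2s²), so
        # ecc = 1 − I_min/I_avg = 1 − 6/(4 + 2c²) for c > 1
        rng = np.random.default_rng(2)
        n = 20000
        pts = rng.normal(size=(n, 3))
        pts = (pts - pts.mean(0))
        cov = pts.T @ pts / n
        w, v = np.linalg.eigh(cov)
        pts = pts @ v / np.sqrt(w)            # exactly whitened cloud
        c = 1.4
        pts[:, 2] *= c
        expected = 1.0 - 3.0 / (2.0 + c * c)
        assert eccentricity(make_system(pts)) == pytest.approx(expected, rel=1e-9)

    def test_collinear_input_rejected(self):
        s = make_system([[0, 0, 0], [1, 0, 0], [2, 0, 0], [5, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            eccentricity(s)


class TestSurfaceArea:
    def test_isolated_sphere_closed_form(self):
        s = make_system([[0, 0, 0]], radii=[1.7])
        res = surface_area(s, n_sphere_points=960)
        assert res.area_measured == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_two_distant_spheres_sum(self):
        s = make_system([[0, 0, 0], [30, 0, 0]], radii=[1.7, 1.5])
        res = surface_area(s, n_sphere_points=960)
        exact = 4 * np.pi * (3.1**2 + 2.9**2)
        assert res.area_measured == pytest.approx(exact, rel=0.01)

    def test_overlapping_spheres_match_cap_closed_form(self):
        # independent oracle: exact spherical-cap (lens) geometry for the
        # union surface of two equal overlapping spheres
        r1 = r2 = 1.7 + 1.4
        d = 3.0
        # analytic union area of two equal spheres overlapping at distance d:
        # each sphere loses a cap of height h = r − d/2
        h = r1 - d / 2.0
        exact = 2 * (4 * np.pi * r1**2) - 2 * (2 * np.pi * r1 * h)
        s = make_system([[0, 0, 0], [d, 0, 0]], radii=[1.7, 1.7])
        res = surface_area(s, n_sphere_points=1920)
        assert res.area_measured == pytest.approx(exact, rel=0.02)

    def test_convergence_with_point_count(self):
        s = make_system([[0, 0, 0], [2.5, 0.5, 0]], radii=[1.7, 1.6])
        exact = surface_area(s, n_sphere_points=7680).area_measured
        errs = [abs(surface_area(s, n_sphere_points=n).area_measured - exact)
                for n in (120, 480, 1920)]
        assert errs[2] < errs[0]

    def test_ratio_above_one_for_elongated_body(self):
        pos = [[3.0 * i, 0, 0] for i in range(8)]
        res = surface_area(make_system(pos, radii=[1.7] * 8),
                           n_sphere_points=480, grid_spacing=0.3)
        assert res.ratio > 1.0

    def test_missing_radii_rejected(self):
        s = make_system([[0, 0, 0]], radii=[np.nan])
        with pytest.raises(ValueError, match="radius"):
            surface_area(s)


class TestRadialProfile:
    def test_uniform_ball_plateau_then_zero(self):
        rng = np.random.default_rng(3)
        r = 30.0 * rng.uniform(size=20000) ** (1 / 3)
        u = rng.normal(size=(20000, 3))
        pos = u / np.linalg.norm(u, axis=1, keepdims=True) * r[:, None]
        prof = radial_density_profile(make_system(pos), bin_width=5.0)
        c = prof.bin_centers
        inner = prof.density[c < 25]
        assert inner.std() / inner.mean() < 0.15
        # the sample COM is offset slightly from the ball center, so support
        # can spill one bin past the nominal radius
        assert prof.density[c > 35].sum() == 0.0

    def test_mass_conservation(self):
        rng = np.random.default_rng(4)
        s = make_system(rng.normal(scale=10, size=(500, 3)),
                        masses=rng.uniform(1, 20, 500))
        prof = radial_density_profile(s, bin_width=3.0)
        assert prof.total_mass() == pytest.approx(s.total_mass, rel=1e-9)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            radial_density_profile(make_system([[0, 0, 0]]), bin_width=0.0)


class TestEndToEnd:
    def _chain(self, pos, ends, seg_ends=None, seg_types=None):
        n = len(pos)
        return make_system(
            pos, chain_ends=np.array([ends]),
            segment_ends=np.array(seg_ends) if seg_ends else None,
            segment_ends_type=np.array(seg_types, dtype="U6") if seg_types else None,
            segment_ends_chain=np.zeros(len(seg_ends or []), dtype=np.intp))

    def test_straight_chain_equals_contour(self):
        pos = [[1.5 * i, 0, 0] for i in range(10)]
        s = self._chain(pos, [0, 9])
        assert end_to_end_distances(s).mean == pytest.approx(13.5)

    def test_never_exceeds_contour(self, small_config):
        from wdpu.generator import pack_assembly
        asm = pack_assembly(None, small_config)
        stats = end_to_end_distances(asm.system)
        for chain, bb in zip(range(asm.system.n_chains), asm.system.backbones):
            contour = np.linalg.norm(
                np.diff(asm.system.positions[bb], axis=0), axis=1).sum()
            assert stats.per_chain[chain] <= contour + 1e-9

    def test_segment_grouping_by_type(self):
        pos = [[float(i), 0, 0] for i in range(8)]
        s = self._chain(pos, [0, 7], seg_ends=[[0, 2], [3, 7]],
                        seg_types=["PCL", "PLA"])
        stats = end_to_end_distances(s)
        assert stats.per_segment["PCL"].tolist() == [2.0]
        assert stats.per_segment["PLA"].tolist() == [4.0]

    def test_missing_markers_named(self):
        s = make_system([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="marker"):
            end_to_end_distances(s)


class TestRdf:
    def test_two_points_single_occupied_bin(self):
        res = rdf(np.array([[0.0, 0, 0], [7.3, 0, 0]]), bin_width=0.5, r_max=10)
        assert res.raw_counts.sum() == 1
        assert res.bin_centers[res.raw_counts > 0][0] == pytest.approx(7.25)

    def test_ideal_gas_is_flat_at_unity(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=(4000, 3))
        pos = (u / np.linalg.norm(u, axis=1, keepdims=True)
               * 30.0 * rng.uniform(size=(4000, 1)) ** (1 / 3))
        res = rdf(pos, bin_width=0.5, r_max=30.0)
        sel = (res.bin_centers > 2) & (res.bin_centers < 25)
        assert np.abs(res.g[sel].mean() - 1.0) < 0.05

    def test_raw_counts_conserve_pair_count(self):
        rng = np.random.default_rng(6)
        pos = rng.normal(scale=5, size=(60, 3))
        res = rdf(pos, bin_width=0.5, r_max=100.0)
        assert res.raw_counts.sum() == 60 * 59 // 2

    def test_bad_rmax_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            rdf(np.zeros((3, 3)), bin_width=0.5, r_max=0.25)

    def test_selection_modes_on_generated_assembly(self, small_config):
        from wdpu.generator import pack_assembly
        asm = pack_assembly(None, small_config)
        for sel in ("chains", "segments:PCL", "segments:PLA", "atoms"):
            res = rdf(asm.system, sel, bin_width=0.5)
            assert np.all(res.g >= 0)


class TestSummarize:
    def test_single_replicate_has_zero_sd(self, small_config):
        from wdpu.generator import pack_assembly
        rep = summarize([pack_assembly(None, small_config).system])
        assert rep.n_replicates == 1
        for mean, sd, values in rep.scalars.values():
            assert sd == 0.0

    def test_identical_replicates_collapse(self, small_config):
        from wdpu.generator import pack_assembly
        s = pack_assembly(None, small_config).system
        rep = summarize([s, s, s])
        for mean, sd, values in rep.scalars.values():
            assert sd == pytest.approx(0.0, abs=1e-12)
            assert mean == pytest.approx(values[0])

    def test_matches_per_replicate_recomputation(self, small_config):
        from wdpu.generator import pack_assembly
        systems = [pack_assembly(None, small_config.replace(seed=s)).system
                   for s in (1, 2, 3, 4, 5)]
        rep = summarize(systems)
        rgs = [radius_of_gyration(s) for s in systems]
        assert rep.scalars["rg"][0] == pytest.approx(np.mean(rgs), rel=1e-12)
        assert rep.scalars["rg"][1] == pytest.approx(np.std(rgs), rel=1e-9)

    def test_report_serializes(self, small_config):
        import json
        from wdpu.generator import pack_assembly
        rep = summarize([pack_assembly(None, small_config).system])
        json.dumps(rep.to_dict())
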