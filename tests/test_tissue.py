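"""Cleft splitting, the fib_max ladder and conductivity assignment."""

import numpy as np
import pytest

from scarwave.errors import ConfigError
from scarwave.mesh import LGEMap
from scarwave.synth import SyntheticSpec, generate_mesh
from scarwave.tissue import (CleftParams, DEFAULT_SIGMA_SM,
                             assign_cleft_conductivity,
                             assign_noncleft_regions, build_fibmax_ladder,
                             cleft_probabilities, default_fibmax_ladder,
                             split_clefts)

from conftest import uniform_lge


class TestSplitClefts:
    def test_zero_pmax_leaves_mesh_unchanged(self, sheet20):
        mesh, lge = sheet20
        cm = split_clefts(mesh, lge, CleftParams(p_max=0.0, seed=1))
        assert cm.n_severed == 0
        assert cm.n_removed == 0

    def test_zero_intensity_never_severs(self, sheet20):
        mesh, _ = sheet20
        cm = split_clefts(mesh, uniform_lge(mesh, 0.0),
                          CleftParams(p_max=1.0, seed=1))
        assert cm.n_severed == 0

    def test_removed_fraction_matches_binomial_expectation(self):
        # uniform I=1, alpha=0, p_max=0.3; Monte-Carlo over 100 seeds
        mesh = generate_mesh(SyntheticSpec(grid_shape=(72, 72)))
        lge = uniform_lge(mesh, 1.0)
        n_faces = mesh.faces.shape[0]
        assert n_faces >= 10_000
        p = 0.3
        n_seeds = 100
        total = sum(
            split_clefts(mesh, lge, CleftParams(p_max=p, alpha=0.0,
                                                seed=s)).n_severed
            for s in range(n_seeds))
        mean = total / n_seeds
        se = np.sqrt(n_faces * p * (1 - p) / n_seeds)
        assert abs(mean - p * n_faces) < 3 * se

    def test_expected_fraction_equals_mean_probability_nonuniform(self,
                                                                  sheet30):
        mesh, lge = sheet30
        params = CleftParams(p_max=0.8, alpha=2.0, seed=0)
        probs = cleft_probabilities(mesh, lge, params)
        n_seeds = 100
        total = sum(
            split_clefts(mesh, lge,
                         CleftParams(p_max=0.8, alpha=2.0, seed=s)).n_severed
            for s in range(n_seeds))
        mean = total / n_seeds
        se = np.sqrt(np.sum(probs * (1 - probs)) / n_seeds)
        assert abs(mean - probs.sum()) < 3 * se

    def test_anisotropy_concentrates_on_sheet_normal_faces(self):
        # fibers along x -> sheet normal along y -> only y-normal faces sever
        mesh = generate_mesh(SyntheticSpec(grid_shape=(30, 30),
                                           fiber_angle_deg=0.0))
        lge = uniform_lge(mesh, 1.0)
        cm = split_clefts(mesh, lge, CleftParams(p_max=0.8, alpha=8.0,
                                                 seed=2))
        sev_axes = mesh.face_axis[cm.severed]
        assert cm.n_severed > 100
        assert np.all(sev_axes == 1)

    def test_isolated_elements_are_pruned(self):
        mesh = generate_mesh(SyntheticSpec(grid_shape=(8, 8)))
        lge = uniform_lge(mesh, 1.0)
        cm = split_clefts(mesh, lge, CleftParams(p_max=1.0, alpha=0.0,
                                                 seed=0))
        # p = 1 severs every face: every element isolated and removed
        assert cm.n_severed == mesh.faces.shape[0]
        assert cm.n_removed == mesh.n_elements

    def test_seeded_split_reproducible(self, sheet20):
        mesh, lge = sheet20
        a = split_clefts(mesh, lge, CleftParams(p_max=0.5, seed=9))
        b = split_clefts(mesh, lge, CleftParams(p_max=0.5, seed=9))
        assert np.array_equal(a.severed, b.severed)


class TestFibmaxLadder:
    def test_severed_counts_nondecreasing_and_level0_unsplit(self, sheet30):
        mesh, lge = sheet30
        ladder = build_fibmax_ladder(mesh, lge, default_fibmax_ladder(seed=3))
        counts = [cm.n_severed for cm in ladder]
        assert counts == sorted(counts)
        assert counts[0] == 0
        assert counts[-1] > 0

    def test_deterministic_ordering(self, sheet30):
        mesh, lge = sheet30
        a = build_fibmax_ladder(mesh, lge, default_fibmax_ladder(seed=5))
        b = build_fibmax_ladder(mesh, lge, default_fibmax_ladder(seed=5))
        assert [x.params.p_max for x in a] == [x.params.p_max for x in b]

    def test_wrong_length_rejected(self, sheet20):
        mesh, lge = sheet20
        with pytest.raises(ConfigError):
            build_fibmax_ladder(mesh, lge, default_fibmax_ladder()[:5])


class TestCleftConductivity:
    def test_band_assignment_and_sigma_values(self, sheet20):
        mesh, _ = sheet20
        I = np.array([0.0, 0.1, 0.3, 0.6, 0.9] * (mesh.n_elements // 5))
        ra = assign_cleft_conductivity(LGEMap(I))
        tab = DEFAULT_SIGMA_SM
        assert ra.label_of(0) == "healthy"
        assert ra.sigma_l[0] == tab["healthy_l"]
        assert ra.sigma_t[0] == tab["healthy_t"]
        # 0-25 %: longitudinal kept, transverse reduced 40 %
        assert ra.sigma_l[1] == tab["healthy_l"]
        assert ra.sigma_t[1] == tab["reduced60_t"]
        # 25-50 %: transverse reduced 80 %
        assert ra.sigma_l[2] == tab["healthy_l"]
        assert ra.sigma_t[2] == tab["reduced20_t"]
        # 50-75 %: longitudinal reduced 40 %
        assert ra.sigma_l[3] == tab["reduced60_l"]
        assert ra.sigma_t[3] == tab["reduced20_t"]
        # 75-100 %: longitudinal reduced 80 %
        assert ra.sigma_l[4] == tab["reduced20_l"]
        assert ra.sigma_t[4] == tab["reduced20_t"]
        assert np.all(ra.sigma_l >= ra.sigma_t)

    def test_band_boundaries_are_half_open(self):
        ra = assign_cleft_conductivity(LGEMap(np.array([0.25, 0.5, 0.75,
                                                        1.0])))
        assert [ra.label_of(i) for i in range(4)] == [
            "band_25_50", "band_50_75", "band_75_100", "band_75_100"]


class TestNoncleftRegions:
    def test_cores_nested_across_sizes(self, sheet30):
        mesh, lge = sheet30
        cores = {}
        for cs in (25, 50, 75):
            ra = assign_noncleft_regions(lge, cs, "c")
            cores[cs] = set(np.flatnonzero(ra.labels == 2))
        assert cores[25] <= cores[50] <= cores[75]
        assert len(cores[25]) < len(cores[75])

    def test_threshold_uses_map_maximum(self):
        I = np.array([0.0, 0.2, 0.39, 0.41, 0.8])
        ra = assign_noncleft_regions(LGEMap(I), 50, "nc")
        # max = 0.8 -> core is I >= 0.4
        assert [ra.label_of(i) for i in range(5)] == [
            "healthy", "border_zone", "border_zone", "core", "core"]

    def test_core_conductivity_by_variant(self, sheet30):
        mesh, lge = sheet30
        nc = assign_noncleft_regions(lge, 50, "nc")
        c = assign_noncleft_regions(lge, 50, "c")
        core = nc.labels == 2
        assert np.all(nc.sigma_l[core] == 1e-7)
        assert np.all(c.sigma_l[core] == 0.01)
        bz = nc.labels == 1
        assert np.all(nc.sigma_l[bz] == DEFAULT_SIGMA_SM["bz_l"])
        assert np.all(nc.sigma_t[bz] == DEFAULT_SIGMA_SM["bz_t"])

    def test_all_zero_map_rejected(self, sheet20):
        mesh, _ = sheet20
        with pytest.raises(ConfigError):
            assign_noncleft_regions(uniform_lge(mesh, 0.0), 50, "c")

    def test_region_assignment_exhaustive_and_deterministic(self, sheet30):
        mesh, lge = sheet30
        a = assign_noncleft_regions(lge, 25, "c")
        b = assign_noncleft_regions(lge, 25, "c")
        assert np.array_equal(a.labels, b.labels)
        assert sum(a.counts().values()) == mesh.n_elements
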