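"""Voxel grids, margin expansion and derived planning structures."""

import numpy as np
import pytest

import prioplan as pp
from prioplan.grid import VoxelGrid
from prioplan.structures import GeometryError, cord_close_to_target

from oracles import margin_expansion_bruteforce


def small_grid(shape=(9, 9, 1), spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(shape, spacing)


class TestVoxelGrid:
    def test_rejects_invalid_dims_and_spacings(self):
        with pytest.raises(ValueError):
            VoxelGrid((0, 4, 4), (1, 1, 1))
        with pytest.raises(ValueError):
            VoxelGrid((4, 4, 4), (1, -1, 1))

    def test_voxel_centers_match_origin_and_spacing(self):
        g = VoxelGrid((2, 2, 1), (2.0, 3.0, 4.0), origin=(-2.0, -3.0, -2.0))
        centers = g.voxel_centers()
        assert centers.shape == (4, 3)
        np.testing.assert_allclose(centers[0], [-1.0, -1.5, 0.0])
        np.testing.assert_allclose(centers[-1], [1.0, 1.5, 0.0])


class TestExpandMargin:
    def test_zero_margin_is_identity(self):
        g = small_grid()
        mask = np.zeros(g.shape, bool)
        mask[4, 4, 0] = True
        out = pp.expand_margin(mask, 0.0, g)
        assert np.array_equal(out, mask)

    def test_negative_margin_rejected(self):
        g = small_grid()
        with pytest.raises(ValueError):
            pp.expand_margin(np.zeros(g.shape, bool), -1.0, g)

    def test_single_voxel_isotropic_margin_gives_digital_ball(self):
        g = VoxelGrid((11, 11, 1), (1.0, 1.0, 1.0))
        mask = np.zeros(g.shape, bool)
        mask[5, 5, 0] = True
        out = pp.expand_margin(mask, 5.0, g)
        # digital ball: voxel centers within 5 mm of the seed center
        ii, jj = np.meshgrid(np.arange(11), np.arange(11), indexing="ij")
        ball = (ii - 5) ** 2 + (jj - 5) ** 2 <= 25.0 + 1e-9
        assert np.array_equal(out[:, :, 0], ball)

    @pytest.mark.parametrize("margins", [3.0, (4.0, 2.0, 1.0), (5.0, 5.0, 0.0)])
    def test_matches_bruteforce_scaled_euclidean_oracle(self, margins):
        rng = np.random.default_rng(42)
        g = VoxelGrid((8, 7, 3), (2.0, 3.0, 4.0))
        mask = rng.random(g.shape) < 0.1
        mask[3, 3, 1] = True
        got = pp.expand_margin(mask, margins, g)
        want = margin_expansion_bruteforce(mask, margins, g)
        assert np.array_equal(got, want)

    def test_monotone_in_margin(self):
        rng = np.random.default_rng(3)
        g = small_grid((10, 10, 1))
        mask = rng.random(g.shape) < 0.08
        mask[5, 5, 0] = True
        prev = pp.expand_margin(mask, 1.0, g)
        for m in (2.0, 3.5, 6.0):
            cur = pp.expand_margin(mask, m, g)
            assert np.all(prev <= cur)
            prev = cur


class TestPhantom:
    def test_same_config_same_seed_bit_identical(self):
        a = pp.build_phantom(pp.PhantomConfig(seed=11, anatomy_jitter_mm=2.0))
        b = pp.build_phantom(pp.PhantomConfig(seed=11, anatomy_jitter_mm=2.0))
        for name in a.names():
            assert np.array_equal(a[name], b[name]), name

    def test_zero_radius_tumor_raises(self):
        with pytest.raises(GeometryError):
            pp.build_phantom(pp.PhantomConfig(tumor_radius=0.0))

    def test_tumor_outside_patient_raises(self):
        with pytest.raises(GeometryError):
            pp.build_phantom(pp.PhantomConfig(tumor_center=(140.0, 0.0, 0.0)))

    def test_target_chain_and_patient_containment(self, default_phantom):
        ss = default_phantom
        assert not np.any(ss["gtv"] & ~ss["ctv"])
        assert not np.any(ss["ctv"] & ~ss["ptv"])
        for name in ss.names():
            assert not np.any(ss[name] & ~ss["patient"]), name

    def test_cohort_of_seeds_has_distinct_gtv_centroids(self):
        # finer grid so continuous parameter draws stay distinct after
        # voxelization
        members = pp.generate_cohort(pp.CohortSpec(
            n_patients=10, seed=5, shape=(76, 64, 1), spacing=(3.0, 3.0, 3.0)))
        centroids = []
        for m in members:
            ss = m.build()
            # oracle: direct center-of-mass of the mask
            idx = np.argwhere(ss["gtv"])
            centroids.append(tuple(np.round(idx.mean(axis=0), 6)))
        assert len(set(centroids)) == len(centroids)


class TestDerivedStructures:
    def test_derived_masks_match_boolean_oracle(self, default_phantom):
        ss = default_phantom
        g = ss.grid
        assert np.array_equal(ss["lungs_minus_gtv"], ss["lungs"] & ~ss["gtv"])
        cord5 = pp.expand_margin(ss["spinal_cord"], 5.0, g) & ss["patient"]
        assert np.array_equal(ss["cord_plus_5mm"], cord5)
        assert np.array_equal(ss["ptv_minus_cord5"], ss["ptv"] & ~cord5)
        shell1 = pp.expand_margin(ss["ptv"], 10.0, g) & ~ss["ptv"] & ss["patient"]
        assert np.array_equal(ss["shell_ptv_1cm"], shell1)
        named = np.zeros(g.shape, bool)
        for n in ("gtv", "ctv", "ptv", "lungs", "heart", "esophagus",
                  "spinal_cord", "plexus"):
            named |= ss[n]
        assert np.array_equal(ss["unspecified_tissue"], ss["patient"] & ~named)

    def test_shells_are_disjoint_from_ptv(self, default_phantom):
        ss = default_phantom
        assert not np.any(ss["shell_ptv_1cm"] & ss["ptv"])
        assert not np.any(ss["shell_ptv_3cm"] & ss["ptv"])

    def test_missing_base_structure_is_reported_by_name(self):
        ss = pp.build_phantom(pp.PhantomConfig(), derive=False)
        del ss.masks["esophagus"]
        with pytest.raises(GeometryError, match="esophagus"):
            pp.derive_planning_structures(ss)

    def test_cord_proximity_predicate(self, default_phantom):
        # default tumor is lateral: cord far from target
        assert not cord_close_to_target(default_phantom)
        near = pp.build_phantom(pp.PhantomConfig(
            tumor_radius=14.0, tumor_center=(14.0, -44.0, 0.0)))
        assert cord_close_to_target(near)
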