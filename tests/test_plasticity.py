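"""Occupancy grids, Gaussian smoothing, plasticity scoring and localization."""

import numpy as np
import pytest

from voxflex import (
    GridSpec,
    OccupancyGrid,
    SyntheticSpec,
    frame_occupancy,
    gauss_filter,
    generate_ensemble,
    global_plasticity,
    localize_plasticity,
    make_grid_spec,
    mean_structure,
    occupancy_stats,
    pair_align,
    plasticity_difference,
)
from voxflex.io_formats import Atom, Topology
from voxflex import Ensemble


def single_atom_ensemble(positions):
    """One atom (C, r=1.7 Å) whose position varies over frames."""
    atoms = (Atom(serial=1, name="CA", element="C", vdw_radius=1.7,
                  residue_index=0, residue_name="GLY", residue_seq="1",
                  chain_id="A"),)
    topo = Topology(atoms=atoms, residues=(("A", "1", "GLY"),))
    coords = np.asarray(positions, dtype=float)[:, None, :]
    return Ensemble(topology=topo, coords=coords)


class TestMakeGridSpec:
    def test_single_atom_extent(self):
        ens = single_atom_ensemble([[0.0, 0.0, 0.0]])
        spec = make_grid_spec(ens, spacing=1.0, padding=4.0)
        # 2*(padding + vdw radius) = 11.4 Å -> 12 voxels per axis
        assert spec.dims == (12, 12, 12)
        np.testing.assert_allclose(spec.origin, -5.7)

    def test_two_ensembles_cover_union(self):
        a = single_atom_ensemble([[0.0, 0.0, 0.0]])
        b = single_atom_ensemble([[10.0, 0.0, 0.0]])
        spec = make_grid_spec([a, b], spacing=1.0, padding=4.0)
        assert spec.dims[0] == 22
        assert spec.dims[1] == 12

    def test_nonpositive_spacing_rejected(self):
        ens = single_atom_ensemble([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="spacing"):
            make_grid_spec(ens, spacing=0.0)


class TestOccupancyStats:
    def test_static_ensemble_zero_sd_binary_mean(self, static_ensemble):
        spec = make_grid_spec(static_ensemble)
        mean, sd = occupancy_stats(static_ensemble, spec)
        np.testing.assert_allclose(sd.values, 0.0, atol=1e-15)
        assert set(np.unique(mean.values)) <= {0.0, 1.0}

    def test_half_occupied_voxel_is_sd_maximum(self):
        # atom sits at a site in half the frames, 20 Å away otherwise
        ens = single_atom_ensemble([[0, 0, 0], [20, 0, 0], [0, 0, 0], [20, 0, 0]])
        spec = make_grid_spec(ens)
        mean, sd = occupancy_stats(ens, spec)
        # the voxel nearest the first site
        centers = [spec.centers_1d(a) for a in range(3)]
        idx = tuple(int(np.argmin(np.abs(c))) for c in centers)
        assert mean.values[idx] == pytest.approx(0.5)
        assert sd.values[idx] == pytest.approx(0.5)
        assert sd.values.max() == pytest.approx(0.5)

    def test_sd_equals_population_std_oracle(self):
        """The SD grid must equal np.std over the per-frame binary grids."""
        ens = generate_ensemble(SyntheticSpec(
            n_residues_scaffold=4, n_residues_loop=3, n_frames=6, seed=5,
            sigma_loop=1.0, two_state=True))
        spec = make_grid_spec(ens)
        mean, sd = occupancy_stats(ens, spec)
        stack = np.stack([
            frame_occupancy(ens, f, spec).astype(float) for f in range(6)
        ])
        np.testing.assert_allclose(mean.values, stack.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(sd.values, stack.std(axis=0), atol=1e-12)

    def test_binary_identity_sd_from_mean(self, small_pair):
        naive, _ = small_pair
        sub = Ensemble(topology=naive.topology, coords=naive.coords[:12])
        spec = make_grid_spec(sub)
        mean, sd = occupancy_stats(sub, spec)
        np.testing.assert_allclose(
            sd.values, np.sqrt(mean.values * (1 - mean.values)), atol=1e-12
        )

    def test_frame_order_invariance(self):
        ens = generate_ensemble(SyntheticSpec(
            n_residues_scaffold=3, n_residues_loop=2, n_frames=5, seed=8))
        spec = make_grid_spec(ens)
        mean, sd = occupancy_stats(ens, spec)
        shuffled = Ensemble(topology=ens.topology, coords=ens.coords[::-1].copy())
        mean2, sd2 = occupancy_stats(shuffled, spec)
        np.testing.assert_allclose(mean.values, mean2.values, atol=1e-15)
        np.testing.assert_allclose(sd.values, sd2.values, atol=1e-15)

    def test_atom_outside_grid_raises(self):
        ens = single_atom_ensemble([[0, 0, 0], [50, 0, 0]])
        spec = make_grid_spec(single_atom_ensemble([[0, 0, 0]]))
        with pytest.raises(ValueError, match="frame 1.*outside"):
            occupancy_stats(ens, spec)


class TestGaussFilter:
    def make(self, values, kind="sd", spacing=1.0):
        values = np.asarray(values, dtype=float)
        spec = GridSpec(origin=np.zeros(3), spacing=spacing, dims=values.shape)
        return OccupancyGrid(spec=spec, values=values, kind=kind, n_frames=1)

    def test_sigma_zero_is_identity(self, rng):
        grid = self.make(rng.random((4, 4, 4)))
        out = gauss_filter(grid, sigma=0.0)
        np.testing.assert_array_equal(out.values, grid.values)
        assert out.kind == "sd_smoothed"

    def test_delta_matches_sampled_gaussian(self):
        n = 25
        values = np.zeros((n, n, n))
        values[n // 2, n // 2, n // 2] = 1.0
        sigma = 1.5
        out = gauss_filter(self.make(values), sigma=sigma)
        # direct evaluation of the normalized separable kernel
        r = int(4 * sigma)
        x = np.arange(-r, r + 1)
        k = np.exp(-x**2 / (2 * sigma**2))
        k /= k.sum()
        expected = (
            k[:, None, None] * k[None, :, None] * k[None, None, :]
        )
        sl = slice(n // 2 - r, n // 2 + r + 1)
        np.testing.assert_allclose(out.values[sl, sl, sl], expected, atol=1e-9)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_grid_unchanged(self):
        grid = self.make(np.full((5, 5, 5), 0.3))
        out = gauss_filter(grid, sigma=2.0)
        np.testing.assert_allclose(out.values, 0.3, atol=1e-12)

    def test_mass_preserved_for_interior_support(self, rng):
        values = np.zeros((20, 20, 20))
        values[8:12, 8:12, 8:12] = rng.random((4, 4, 4))
        grid = self.make(values)
        out = gauss_filter(grid, sigma=1.0)
        assert out.values.sum() == pytest.approx(values.sum(), abs=1e-9)

    def test_sigma_in_angstrom_not_voxels(self):
        # same physical sigma on a finer grid must spread over more voxels
        n = 41
        coarse = np.zeros((21, 21, 21)); coarse[10, 10, 10] = 1.0
        fine = np.zeros((n, n, n)); fine[20, 20, 20] = 1.0
        out_c = gauss_filter(self.make(coarse, spacing=1.0), sigma=1.5)
        out_f = gauss_filter(self.make(fine, spacing=0.5), sigma=1.5)
        assert out_f.values.max() < out_c.values.max()


class TestGlobalPlasticity:
    def test_zero_grid_zero_score(self):
        spec = GridSpec(origin=np.zeros(3), spacing=1.0, dims=(4, 4, 4))
        grid = OccupancyGrid(spec=spec, values=np.zeros((4, 4, 4)), kind="sd")
        assert global_plasticity(grid) == 0.0

    def test_single_voxel_direct_formula(self):
        spec = GridSpec(origin=np.zeros(3), spacing=1.0, dims=(3, 3, 3))
        values = np.zeros((3, 3, 3))
        values[1, 1, 1] = 0.5
        grid = OccupancyGrid(spec=spec, values=values, kind="sd")
        assert global_plasticity(grid, threshold=0.05) == pytest.approx(0.5)

    def test_spacing_cubed_scaling(self):
        spec = GridSpec(origin=np.zeros(3), spacing=0.5, dims=(3, 3, 3))
        values = np.zeros((3, 3, 3))
        values[0, 0, 0] = 0.4
        grid = OccupancyGrid(spec=spec, values=values, kind="sd")
        assert global_plasticity(grid) == pytest.approx(0.4 * 0.125)

    def test_threshold_range_enforced(self):
        spec = GridSpec(origin=np.zeros(3), spacing=1.0, dims=(2, 2, 2))
        grid = OccupancyGrid(spec=spec, values=np.zeros((2, 2, 2)), kind="sd")
        with pytest.raises(ValueError, match="threshold"):
            global_plasticity(grid, threshold=0.7)

    def test_flexible_exceeds_rigid(self, small_pair):
        naive, matured = small_pair
        a, b = pair_align(naive, matured, "chain S name CA")
        spec = make_grid_spec([a, b])
        scores = []
        for ens in (a, b):
            _, sd = occupancy_stats(ens, spec)
            scores.append(global_plasticity(gauss_filter(sd, 1.5)))
        assert scores[0] > scores[1]


class TestLocalizePlasticity:
    def test_zero_grid_all_zero_scores(self, static_ensemble):
        spec = make_grid_spec(static_ensemble)
        grid = OccupancyGrid(spec=spec, values=np.zeros(spec.dims), kind="sd")
        profile = localize_plasticity(grid, static_ensemble.topology,
                                      mean_structure(static_ensemble))
        assert profile.global_score == 0.0
        assert all(v == 0.0 for v in profile.per_residue.values())

    def test_mass_near_one_residue_scores_only_it(self, static_ensemble):
        ens = static_ensemble
        spec = make_grid_spec(ens)
        ref = mean_structure(ens)
        # place SD mass at the CA of loop residue 98, 1 Å off the atom
        from voxflex import resolve_selection
        ca98 = resolve_selection(ens.topology, "chain H resid 98-98 name CA").indices[0]
        target = ref[ca98] + np.array([0.4, 0.0, 0.0])
        idx = tuple(
            int(np.argmin(np.abs(spec.centers_1d(a) - target[a]))) for a in range(3)
        )
        values = np.zeros(spec.dims)
        values[idx] = 0.5
        grid = OccupancyGrid(spec=spec, values=values, kind="sd")
        profile = localize_plasticity(grid, ens.topology, ref)
        nonzero = {k: v for k, v in profile.per_residue.items() if v > 0}
        assert set(nonzero) == {("H", "98")}
        assert profile.unassigned == 0.0

    def test_partition_conserves_global_integral(self, small_pair):
        naive, _ = small_pair
        sub = Ensemble(topology=naive.topology, coords=naive.coords[:15])
        spec = make_grid_spec(sub)
        _, sd = occupancy_stats(sub, spec)
        sd_s = gauss_filter(sd, 1.5)
        profile = localize_plasticity(sd_s, sub.topology, mean_structure(sub))
        total = global_plasticity(sd_s, profile.threshold_used)
        assert profile.global_score == pytest.approx(total, abs=1e-9)
        assert sum(profile.per_residue.values()) + profile.unassigned == pytest.approx(
            total, abs=1e-9
        )


class TestPlasticityDifference:
    def test_identical_grids_zero(self, rng):
        spec = GridSpec(origin=np.zeros(3), spacing=1.0, dims=(3, 3, 3))
        g = OccupancyGrid(spec=spec, values=rng.random((3, 3, 3)), kind="sd")
        diff = plasticity_difference(g, g)
        np.testing.assert_array_equal(diff.values, 0.0)
        assert diff.kind == "difference"

    def test_mismatched_origin_raises(self, rng):
        v = rng.random((3, 3, 3))
        g1 = OccupancyGrid(spec=GridSpec(np.zeros(3), 1.0, (3, 3, 3)), values=v, kind="sd")
        g2 = OccupancyGrid(spec=GridSpec(np.array([1.0, 0, 0]), 1.0, (3, 3, 3)),
                           values=v, kind="sd")
        with pytest.raises(ValueError, match="specs differ"):
            plasticity_difference(g1, g2)

    def test_naive_minus_matured_skews_positive(self, small_pair):
        naive, matured = small_pair
        a, b = pair_align(naive, matured, "chain S name CA")
        spec = make_grid_spec([a, b])
        grids = []
        for ens in (a, b):
            _, sd = occupancy_stats(ens, spec)
            grids.append(gauss_filter(sd, 1.5))
        diff = plasticity_difference(grids[0], grids[1])
        assert diff.values[diff.values > 0].sum() > -diff.values[diff.values < 0].sum()


class TestMonotoneResponse:
    def test_plasticity_orders_with_fluctuation(self):
        scores = []
        for sigma in (0.3, 0.6, 1.0):
            ens = generate_ensemble(SyntheticSpec(
                sigma_loop=sigma, n_frames=40, seed=21, two_state=False))
            spec = make_grid_spec(ens)
            _, sd = occupancy_stats(ens, spec)
            scores.append(global_plasticity(gauss_filter(sd, 1.5)))
        assert scores[0] < scores[1] < scores[2]
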