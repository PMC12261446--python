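"""Silver-standard simulator: clamped-NB sampling, grid/zone geometry, spot assembly."""

import numpy as np
import pytest
from scipy.stats import chisquare

import spotbench as sb
from spotbench.silver import SimulationConfig

from conftest import clamped_nb_moments, coupled_cells_moments


class TestSampleCompositionSize:
    def test_lower_clamped_mean_matches_closed_form(self):
        # E[max(1, NB(5, 20))] = 5 + P(X=0) = 5 + 0.8^20
        draws = sb.sample_composition_size(5.0, 20.0, lower=1, n=100_000, seed=0)
        m, v = clamped_nb_moments(5.0, 20.0, lower=1)
        assert m == pytest.approx(5.0115292, abs=1e-6)
        assert abs(draws.mean() - m) < 3 * np.sqrt(v / len(draws))

    def test_upper_clamped_mean_matches_closed_form(self):
        draws = sb.sample_composition_size(3.0, 20.0, lower=1, upper=12, n=100_000, seed=1)
        m, v = clamped_nb_moments(3.0, 20.0, lower=1, upper=12)
        assert m == pytest.approx(3.0609631, abs=1e-6)
        assert abs(draws.mean() - m) < 3 * np.sqrt(v / len(draws))

    def test_large_shape_approaches_poisson(self):
        # mean far enough from the clamp that P(X=0) is negligible
        draws = sb.sample_composition_size(8.0, 1e6, lower=1, n=100_000, seed=2)
        assert draws.mean() == pytest.approx(draws.var(), rel=0.03)

    def test_nb_mean_variance_at_theta_20(self):
        # unclamped moments: use a mean large enough that the clamp never binds
        mu, theta = 30.0, 20.0
        draws = sb.sample_composition_size(mu, theta, lower=1, n=200_000, seed=3)
        target_var = mu + mu**2 / theta
        assert draws.mean() == pytest.approx(mu, rel=0.01)
        assert draws.var() == pytest.approx(target_var, rel=0.03)

    @pytest.mark.parametrize("kwargs", [
        dict(mean=0.0, overdispersion=20.0),
        dict(mean=3.0, overdispersion=0.0),
        dict(mean=3.0, overdispersion=20.0, lower=2, upper=1),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sb.sample_composition_size(n=10, seed=0, **kwargs)


class TestLaySpotGrid:
    def test_four_spots_form_2x2_grid(self):
        coords = sb.lay_spot_grid(4)
        assert sorted(map(tuple, coords)) == [(0.25, 0.25), (0.25, 0.75),
                                              (0.75, 0.25), (0.75, 0.75)]

    def test_five_spots_fill_three_columns_row_major(self):
        coords = sb.lay_spot_grid(5)
        assert len(coords) == 5
        xs = np.unique(np.round(coords[:, 0], 12))
        assert len(xs) == 3  # 3-column grid, second row partial
        assert np.allclose(coords[:3, 1], coords[0, 1])  # first row filled first

    def test_thousand_spots_inside_unit_square(self):
        coords = sb.lay_spot_grid(1000)
        assert coords.shape == (1000, 2)
        assert coords.min() > 0 and coords.max() < 1


class TestAssignZones:
    def test_uniform_gives_single_zone(self):
        coords = sb.lay_spot_grid(50)
        assert np.all(sb.assign_zones(coords, "uniform", 1) == 0)

    def test_stripes_split_grid_evenly(self):
        coords = sb.lay_spot_grid(1000)
        zones = sb.assign_zones(coords, "stripes", 4)
        counts = np.bincount(zones, minlength=4)
        # 32-column grid: each of 4 bands holds 8 columns +- one column of spots
        assert np.all(np.abs(counts - 250) <= 32)
        # band index equals x-coordinate bin
        assert np.array_equal(zones, np.minimum((coords[:, 0] * 4).astype(int), 3))

    def test_circle_zones_are_discs_on_diagonal(self):
        coords = sb.lay_spot_grid(2500)
        n_regions = 4
        zones = sb.assign_zones(coords, "circles", n_regions)
        radius = 1 / (2 * n_regions)
        for i in range(1, n_regions):
            c = i / n_regions
            inside = (coords[:, 0] - c) ** 2 + (coords[:, 1] - c) ** 2 <= radius**2
            assert np.all(zones[inside & (zones != 0)] >= 1)
            # points outside every disc are background
        dist_any = np.min([np.hypot(coords[:, 0] - i / n_regions, coords[:, 1] - i / n_regions)
                           for i in range(1, n_regions)], axis=0)
        assert np.all(zones[dist_any > radius] == 0)
        assert len(np.unique(zones)) == n_regions

    def test_unknown_zonation_rejected(self):
        with pytest.raises(ValueError, match="zonation"):
            sb.assign_zones(sb.lay_spot_grid(4), "swirls", 2)


class TestSampleSpotMembers:
    def test_single_type_spot_is_pure(self, four_type_reference):
        ref = four_type_reference
        members = sb.sample_spot_members(ref, k_types=1, n_cells=6, seed=0)
        assert len(set(ref.cell_types[members])) == 1
        assert len(members) == 6

    def test_pigeonhole_one_cell_per_type(self, four_type_reference):
        ref = four_type_reference
        members = sb.sample_spot_members(ref, k_types=3, n_cells=3, seed=1)
        assert len(members) == 3
        assert len(set(ref.cell_types[members])) == 3

    def test_type_pairs_chosen_uniformly(self, four_type_reference):
        ref = four_type_reference
        from collections import Counter
        rng = np.random.default_rng(7)
        pairs = Counter()
        for _ in range(3000):
            members = sb.sample_spot_members(ref, k_types=2, n_cells=2, rng=rng)
            pairs[tuple(sorted(set(ref.cell_types[members])))] += 1
        counts = np.array(list(pairs.values()))
        assert len(counts) == 6  # C(4,2) unordered pairs
        assert chisquare(counts).pvalue > 1e-3

    def test_excess_k_types_rejected(self, four_type_reference):
        with pytest.raises(ValueError):
            sb.sample_spot_members(four_type_reference, k_types=5, n_cells=5, seed=0)


@pytest.fixture(scope="module")
def hb1_spots(small_reference):
    cfg = SimulationConfig(n_spots=1000, zonation="uniform", n_regions=1,
                           mean_cell_types=3, mean_cells=5, overdispersion=20, seed=17)
    return sb.simulate_spots(small_reference, cfg)


class TestSimulateSpots:
    def test_heart_brain_1_shape_and_zone(self, hb1_spots):
        assert hb1_spots.n_spots == 1000
        assert np.all(hb1_spots.zone == 0)

    def test_count_conservation_exact(self, hb1_spots, small_reference):
        ref = small_reference
        for s in [0, 17, 999]:
            members = hb1_spots.member_cells[s]
            assert (hb1_spots.rna[s] != ref.rna[members].sum(axis=0)).sum() == 0
            assert (hb1_spots.atac[s] != ref.atac[members].sum(axis=0)).sum() == 0
        # totals across all spots equal totals across all member draws
        total_members = np.concatenate(hb1_spots.member_cells)
        assert hb1_spots.rna.sum() == ref.rna[total_members].sum()
        assert hb1_spots.atac.sum() == ref.atac[total_members].sum()

    def test_proportion_rows_sum_to_one(self, hb1_spots):
        assert np.allclose(hb1_spots.true_proportions.values.sum(axis=1), 1.0, atol=1e-9)

    def test_member_cell_mean_matches_clamped_nb_oracle(self, hb1_spots):
        m, v = coupled_cells_moments(3.0, 20.0, k_upper=12, mean_n=5.0)
        observed = np.mean([len(mm) for mm in hb1_spots.member_cells])
        assert abs(observed - m) < 3 * np.sqrt(v / hb1_spots.n_spots)

    def test_distinct_type_mean_matches_clamped_nb_oracle(self, hb1_spots):
        m, v = clamped_nb_moments(3.0, 20.0, lower=1, upper=12)
        observed = (hb1_spots.true_proportions.values > 0).sum(axis=1).mean()
        assert abs(observed - m) < 3 * np.sqrt(v / hb1_spots.n_spots)

    def test_zone_fidelity_heart_brain_3(self, small_reference):
        cfg = SimulationConfig(n_spots=1000, zonation="stripes", n_regions=4,
                               mean_cell_types=(10, 5, 10, 5), mean_cells=(15, 10, 15, 5),
                               overdispersion=20, seed=23)
        spots = sb.simulate_spots(small_reference, cfg)
        assert set(np.unique(spots.zone)) == {0, 1, 2, 3}
        per_zone_cells = [np.mean([len(spots.member_cells[i])
                                   for i in np.flatnonzero(spots.zone == z)])
                          for z in range(4)]
        # zones configured with mean 15 cells exceed zones with mean 10 and 5
        assert per_zone_cells[0] > per_zone_cells[1] > per_zone_cells[3]
        assert per_zone_cells[2] > per_zone_cells[1]
        per_zone_types = [np.mean([(spots.true_proportions.values[i] > 0).sum()
                                   for i in np.flatnonzero(spots.zone == z)])
                          for z in range(4)]
        assert per_zone_types[0] > per_zone_types[1] and per_zone_types[2] > per_zone_types[3]

    def test_end_to_end_seed_determinism(self, small_reference):
        cfg = SimulationConfig(n_spots=60, mean_cell_types=3, mean_cells=5, seed=5)
        a = sb.simulate_spots(small_reference, cfg)
        b = sb.simulate_spots(small_reference, cfg)
        assert (a.rna != b.rna).nnz == 0 and (a.atac != b.atac).nnz == 0
        assert np.array_equal(a.true_proportions.values, b.true_proportions.values)
        assert all(np.array_equal(x, y) for x, y in zip(a.member_cells, b.member_cells))

    def test_forced_single_type_spots_are_one_hot(self):
        # a type-count mean near zero clamps every draw to k = 1, so every
        # spot is pure regardless of its cell count
        ref = sb.generate_reference(sb.ReferenceConfig(
            n_cells=100, n_genes=50, n_peaks=50, n_cell_types=2, markers_per_type=5, seed=1))
        cfg = SimulationConfig(n_spots=40, mean_cell_types=0.01, mean_cells=4, seed=2)
        spots = sb.simulate_spots(ref, cfg)
        assert np.all(spots.true_proportions.values.max(axis=1) == 1.0)

    @pytest.mark.parametrize("kwargs", [
        dict(zonation="uniform", n_regions=2),
        dict(zonation="stripes", n_regions=1),
        dict(zonation="stripes", n_regions=3, mean_cells=(5, 5)),
        dict(overdispersion=0),
        dict(n_spots=0),
    ])
    def test_invalid_simulation_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**{**dict(n_spots=10, mean_cell_types=3, mean_cells=5), **kwargs})
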