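"""Generator contracts: correlation structure, determinism, sampling laws."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from skimage.measure import label as cc_label

from invaniche.raster import GridRaster
from invaniche.synthetic import (
    VirtualSpeciesTruth,
    generate_climate,
    generate_habitat,
    make_landscape,
    sample_occurrences_equilibrium,
    simulate_invasion,
    true_suitability,
)


def _truth(**kw):
    base = dict(
        a0=0.0,
        a1={"clim1": 0.0, "clim2": 0.0},
        a2={"clim1": 0.0, "clim2": 0.0},
        host_dependent=False,
        standardize={"clim1": (0.0, 1.0), "clim2": (0.0, 1.0)},
    )
    base.update(kw)
    return VirtualSpeciesTruth(**base)


class TestGenerateClimate:
    def test_identity_target_gives_uncorrelated_layers(self):
        stack = generate_climate(300, 300, 1.0, 2, np.eye(2), 5.0, seed=3)
        a = stack["clim1"].values.ravel()
        b = stack["clim2"].values.ravel()
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.05

    def test_unit_correlation_gives_affine_copies(self):
        target = np.array([[1.0, 1.0], [1.0, 1.0]])
        stack = generate_climate(100, 100, 1.0, 2, target, 4.0, seed=0)
        r = np.corrcoef(
            stack["clim1"].values.ravel(), stack["clim2"].values.ravel()
        )[0, 1]
        assert r > 0.999

    def test_target_correlation_achieved(self):
        target = np.array([[1.0, 0.6], [0.6, 1.0]])
        stack = generate_climate(200, 200, 1.0, 2, target, 5.0, seed=5)
        r = np.corrcoef(
            stack["clim1"].values.ravel(), stack["clim2"].values.ravel()
        )[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)

    def test_same_seed_bit_identical(self):
        s1 = generate_climate(60, 60, 1.0, 3, np.eye(3), 3.0, seed=9)
        s2 = generate_climate(60, 60, 1.0, 3, np.eye(3), 3.0, seed=9)
        for k in s1:
            assert np.array_equal(s1[k].values, s2[k].values)

    def test_non_positive_definite_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues -1, 3
        with pytest.raises(ValueError, match="positive"):
            generate_climate(50, 50, 1.0, 2, bad, 3.0, seed=0)


class TestGenerateHabitat:
    def test_host_prevalence_matches(self):
        _, host, _, _ = generate_habitat((300, 300), 4, 0.2, 5.0, seed=2)
        frac = host.values.mean()
        assert 0.17 <= frac <= 0.23

    def test_clustering_reduces_patch_count(self):
        hab_iid, _, _, _ = generate_habitat((150, 150), 4, 0.3, 0.0, seed=4)
        hab_smooth, _, _, _ = generate_habitat((150, 150), 4, 0.3, 10.0, seed=4)

        def n_patches(hab):
            total = 0
            for cls in np.unique(hab.values):
                total += cc_label((hab.values == cls).astype(int), connectivity=1).max()
            return total

        assert n_patches(hab_iid) > 5 * n_patches(hab_smooth)

    def test_full_prevalence_host_everywhere(self):
        _, host, _, _ = generate_habitat((40, 40), 3, 1.0, 2.0, seed=0)
        assert np.all(host.values == 1.0)

    def test_invalid_class_count_rejected(self):
        with pytest.raises(ValueError):
            generate_habitat((10, 10), 0, 0.5, 1.0, seed=0)


class TestTrueSuitability:
    def test_zero_coefficients_give_constant_half(self):
        land = make_landscape(30, 30, n_climate=2, seed=0,
                              climate_names=["clim1", "clim2"])
        s = true_suitability(_truth(), land.climate)
        assert np.allclose(s.values, 0.5)

    def test_hand_evaluated_cell(self):
        # z = (1, -1), a0=1, a1=(1,0), a2=(-1,0) -> expit(1 + 1 - 1) = expit(1)
        clim = {
            "clim1": GridRaster(np.array([[1.0]]), cell_km=1.0),
            "clim2": GridRaster(np.array([[-1.0]]), cell_km=1.0),
        }
        truth = _truth(a0=1.0, a1={"clim1": 1.0, "clim2": 0.0},
                       a2={"clim1": -1.0, "clim2": 0.0})
        s = true_suitability(truth, clim)
        assert s.values[0, 0] == pytest.approx(expit(1.0), abs=1e-12)

    def test_missing_layer_named_in_error(self):
        land = make_landscape(10, 10, n_climate=1, seed=0, climate_names=["clim1"])
        with pytest.raises(KeyError, match="clim2"):
            true_suitability(_truth(), land.climate)


class TestEquilibriumSampling:
    def test_sampled_cells_have_above_average_suitability(self):
        land = make_landscape(100, 100, seed=3)
        truth = _truth(
            a1={"clim1": 0.0, "clim2": 0.0},
            a2={"clim1": -2.0, "clim2": 0.0},
            a0=1.0,
        )
        occ = sample_occurrences_equilibrium(truth, land, 2000, seed=5)
        s = true_suitability(truth, land.climate)
        row, col = land.host.cell_of(occ["x"].to_numpy(), occ["y"].to_numpy())
        assert s.values[row, col].mean() > s.values.mean()

    def test_host_dependence_with_empty_host_raises(self):
        land = make_landscape(20, 20, host_prevalence=0.3, seed=1)
        land.host.values[:] = 0.0
        truth = _truth(host_dependent=True)
        with pytest.raises(ValueError, match="positive sampling weight"):
            sample_occurrences_equilibrium(truth, land, 10, seed=0)

    def test_determinism(self):
        land = make_landscape(50, 50, seed=2)
        truth = _truth(a2={"clim1": -1.0, "clim2": 0.0})
        a = sample_occurrences_equilibrium(truth, land, 100, seed=7)
        b = sample_occurrences_equilibrium(truth, land, 100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_severity_gradient_nondecreasing_in_suitability(self):
        land = make_landscape(100, 100, seed=11)
        truth = _truth(a0=2.0, a2={"clim1": -3.0, "clim2": -1.0})
        occ = sample_occurrences_equilibrium(truth, land, 1500, seed=13)
        s = true_suitability(truth, land.climate)
        row, col = land.host.cell_of(occ["x"].to_numpy(), occ["y"].to_numpy())
        svals = s.values[row, col]
        q = np.quantile(svals, [0.25, 0.5, 0.75])
        bins = np.digitize(svals, q)
        high_frac = [
            (occ["severity"].to_numpy()[bins == b] >= 3).mean() for b in range(4)
        ]
        assert all(high_frac[i] <= high_frac[i + 1] + 1e-9 for i in range(3))


class TestInvasionSimulation:
    def _setup(self, radius=8.0, seed=0):
        land = make_landscape(80, 80, seed=seed)
        truth = _truth(
            a0=2.0, a2={"clim1": -2.0, "clim2": 0.0},
            dispersal_radius_km=radius,
        )
        return land, truth

    def test_zero_radius_stays_at_introduction(self):
        land, truth = self._setup(radius=0.0)
        occ = simulate_invasion(truth, land, [(40.0, 40.0)], n_years=4, seed=1)
        assert len(occ) >= 1
        assert (occ["x"].nunique() == 1) and (occ["y"].nunique() == 1)

    def test_yearly_spread_respects_dispersal_radius(self):
        land, truth = self._setup(radius=8.0)
        occ = simulate_invasion(
            truth, land, [(40.0, 40.0)], n_years=5, per_year_intensity=60, seed=3
        )
        for year in sorted(occ["year"].unique())[1:]:
            prev = occ[occ["year"] < year][["x", "y"]].to_numpy()
            new = occ[occ["year"] == year][["x", "y"]].to_numpy()
            for p in new:
                d = np.sqrt(((prev - p) ** 2).sum(axis=1)).min()
                assert d <= truth.dispersal_radius_km + 1e-9

    def test_huge_radius_reaches_positive_support(self):
        land, truth = self._setup(radius=1000.0)
        occ = simulate_invasion(
            truth, land, [(40.0, 40.0)], n_years=2, per_year_intensity=10**6, seed=2
        )
        # year-2 candidates cover the entire positive-weight support
        from invaniche.synthetic import _sampling_weights

        weight, _ = _sampling_weights(truth, land)
        n_positive = int((weight > 0).sum())
        assert occ["year"].max() == 2
        assert len(occ) == min(n_positive, 10**6)

    def test_invasion_climate_range_truncated_versus_equilibrium(self):
        # niche optimum far from the introduction corner: the spreading
        # population sees only part of the climate range the equilibrium
        # sample covers
        land = make_landscape(100, 100, seed=21)
        truth = _truth(a0=2.0, a2={"clim1": -3.0, "clim2": 0.0},
                       dispersal_radius_km=4.0)
        eq = sample_occurrences_equilibrium(truth, land, 800, seed=5)
        inv = simulate_invasion(
            truth, land, [(5.0, 5.0)], n_years=4, per_year_intensity=50, seed=5
        )
        from invaniche.pipeline import extract_covariates

        eq_c = extract_covariates(eq, land.climate)["clim1"]
        inv_c = extract_covariates(inv, land.climate)["clim1"]
        assert inv_c.max() - inv_c.min() < eq_c.max() - eq_c.min()
        assert inv_c.min() >= eq_c.min() - 1e-9 or inv_c.max() <= eq_c.max() + 1e-9

    def test_determinism(self):
        land, truth = self._setup()
        a = simulate_invasion(truth, land, [(40.0, 40.0)], 3, 30, seed=9)
        b = simulate_invasion(truth, land, [(40.0, 40.0)], 3, 30, seed=9)
        pd.testing.assert_frame_equal(a, b)
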