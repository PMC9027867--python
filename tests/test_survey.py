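import numpy as np
import pandas as pd
import pytest

from cacyreus import (TruthParams, simulate_counts, simulate_opportunistic,
                      stratified_design)
from cacyreus.survey import DEFAULT_BANDS, default_truth

from conftest import flat_grid


class TestStratifiedDesign:
    def test_study_arithmetic(self, study_grid):
        """3 bands x 25 cells x 3 visits = 75 cells and 225 site-visits."""
        design = stratified_design(study_grid, n_per_band=25, visits=3, seed=5)
        assert design.n_sites == 75
        assert design.n_site_visits == 225
        counts = design.selected_cells["band"].value_counts()
        assert (counts == 25).all()
        design.validate(study_grid)

    def test_minimal_design(self, study_grid):
        design = stratified_design(study_grid, bands=[(500.0, 2000.0)],
                                   n_per_band=1, visits=1, seed=0)
        assert design.n_site_visits == 1

    def test_cells_fall_in_their_band(self, study_grid):
        design = stratified_design(study_grid, n_per_band=20, visits=2, seed=2)
        lut = study_grid.cells.set_index("cell_id")["elevation"]
        for b, (lo, hi) in enumerate(DEFAULT_BANDS):
            sub = design.selected_cells.query("band == @b")
            elev = lut.loc[sub["cell_id"]]
            assert elev.between(lo, hi).all()

    def test_insufficient_band_names_the_band(self, study_grid):
        with pytest.raises(ValueError, match=r"band 0 .*3000.*4000"):
            stratified_design(study_grid, bands=[(3000.0, 4000.0)],
                              n_per_band=5, visits=1, seed=0)

    def test_sampling_without_replacement(self, study_grid):
        design = stratified_design(study_grid, n_per_band=25, visits=3, seed=8)
        assert design.selected_cells["cell_id"].is_unique


def _uniform_design(grid, visits=1):
    from cacyreus.survey import SurveyDesign
    return SurveyDesign(bands=[(0.0, 5000.0)], cells_per_band=len(grid.cells),
                        visits_per_cell=visits,
                        selected_cells=pd.DataFrame(
                            {"cell_id": grid.cells["cell_id"], "band": 0}),
                        seed=0)


class TestSimulateCounts:
    def test_perfect_detection_yields_latent_counts(self):
        """With p clamped to 1 and one visit, observed counts are the
        latent draws: their mean matches lambda within MC error."""
        grid = flat_grid(100, 100)
        design = _uniform_design(grid)
        lam = 5.0
        truth = TruthParams(beta={"intercept": np.log(lam)},
                            alpha={"intercept": 40.0}, mixture="P")
        data = simulate_counts(grid, design, truth, seed=0)
        y = data.y.to_numpy().ravel()
        se = np.sqrt(lam / len(y))
        assert abs(y.mean() - lam) < 3 * se

    def test_total_zero_inflation_gives_all_zeros(self):
        grid = flat_grid(10, 10)
        truth = TruthParams(beta={"intercept": 2.0}, alpha={"intercept": 0.0},
                            psi=1.0, mixture="ZIP")
        data = simulate_counts(grid, _uniform_design(grid, visits=3), truth,
                               seed=1)
        assert (data.y.to_numpy() == 0).all()

    def test_thinned_mean_matches_lambda_p(self):
        """E[y] = lambda p: lambda=5, p=0.4 over 10,000 sites -> mean ~ 2."""
        grid = flat_grid(100, 100)
        p = 0.4
        truth = TruthParams(beta={"intercept": np.log(5.0)},
                            alpha={"intercept": np.log(p / (1 - p))},
                            mixture="P")
        data = simulate_counts(grid, _uniform_design(grid), truth, seed=2)
        y = data.y.to_numpy().ravel()
        se = np.sqrt(5 * p * (1 + 5 * (1 - p)) / len(y))  # var of thinned Poisson
        assert abs(y.mean() - 2.0) < 3 * se + 0.05

    def test_zip_zero_fraction_matches_closed_form(self):
        """Visit-level zero fraction equals psi + (1-psi) exp(-lambda p)
        within 3 MC standard errors (n = 10,000 sites)."""
        grid = flat_grid(100, 100)
        psi, lam, p = 0.3, 4.0, 0.5
        truth = TruthParams(beta={"intercept": np.log(lam)},
                            alpha={"intercept": 0.0}, psi=psi, mixture="ZIP")
        data = simulate_counts(grid, _uniform_design(grid), truth, seed=3)
        y = data.y.to_numpy().ravel()
        p0 = psi + (1 - psi) * np.exp(-lam * p)
        se = np.sqrt(p0 * (1 - p0) / len(y))
        assert abs((y == 0).mean() - p0) < 3 * se

    def test_zip_mean_matches_closed_form(self):
        grid = flat_grid(100, 100)
        psi, lam, p = 0.4, 6.0, 0.5
        truth = TruthParams(beta={"intercept": np.log(lam)},
                            alpha={"intercept": 0.0}, psi=psi, mixture="ZIP")
        data = simulate_counts(grid, _uniform_design(grid), truth, seed=4)
        y = data.y.to_numpy().ravel()
        mean = (1 - psi) * lam * p
        se = np.sqrt(y.var() / len(y))
        assert abs(y.mean() - mean) < 3 * se

    def test_deterministic_given_seed(self, study_grid, study_design):
        a = simulate_counts(study_grid, study_design, default_truth(), seed=7)
        b = simulate_counts(study_grid, study_design, default_truth(), seed=7)
        pd.testing.assert_frame_equal(a.y, b.y)
        pd.testing.assert_frame_equal(a.obs_covariates, b.obs_covariates)

    def test_covariates_standardized_with_design_cells(self, study_grid,
                                                       study_design):
        """Raw covariates are returned; re-standardizing reproduces the
        scaling the generator applied internally (mean 0, sd 1)."""
        data = simulate_counts(study_grid, study_design, default_truth(), seed=7)
        scaled = data.standardize(["bio01"])
        assert scaled.site_covariates["bio01"].mean() == pytest.approx(0, abs=1e-9)


class TestSimulateOpportunistic:
    def test_reproducible(self, study_grid):
        a = simulate_opportunistic(study_grid, default_truth(), 50, 1.0, seed=9)
        b = simulate_opportunistic(study_grid, default_truth(), 50, 1.0, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_strong_host_effect_confines_points_to_pot_cells(self, study_grid):
        truth = default_truth()
        truth.beta = dict(truth.beta, pel_abu=25.0)
        pts = simulate_opportunistic(study_grid, truth, 100, 0.0, seed=10)
        lut = study_grid.cells.set_index("cell_id")["pel_abu"]
        assert (lut.loc[pts["cell_id"]] > 0).all()

    def test_no_bias_limit_follows_abundance(self, study_grid):
        """With bias 0, sampling is proportional to expected abundance:
        the mean abundance at sampled cells exceeds the landscape mean."""
        truth = default_truth()
        pts = simulate_opportunistic(study_grid, truth, 300, 0.0, seed=11)
        cells = study_grid.cells.set_index("cell_id")
        assert (cells.loc[pts["cell_id"], "pel_abu"].mean()
                > cells["pel_abu"].mean())

    def test_rejects_degenerate_inputs(self, study_grid):
        with pytest.raises(ValueError):
            simulate_opportunistic(study_grid, default_truth(), 0, 1.0, seed=0)
        dead = TruthParams(beta={"intercept": 0.0}, alpha={"intercept": 0.0},
                           psi=1.0, mixture="ZIP")
        with pytest.raises(ValueError, match="zero"):
            simulate_opportunistic(study_grid, dead, 10, 1.0, seed=0)

    def test_points_lie_in_their_cells(self, study_grid):
        pts = simulate_opportunistic(study_grid, default_truth(), 80, 1.0,
                                     seed=12)
        lut = study_grid.cells.set_index("cell_id")
        res = study_grid.resolution_m
        cx = (lut.loc[pts["cell_id"], "col"].to_numpy() + 0.5) * res
        assert (np.abs(pts["x"].to_numpy() - cx) <= res / 2 + 1e-9).all()
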