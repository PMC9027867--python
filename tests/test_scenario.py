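import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cacyreus import (ScenarioSpec, categorize_changes, elevation_profile,
                      project_map, summarize_by_group)
from cacyreus.nmixture import NMixtureResults
from cacyreus.scenario import round_half_up


def reference_results(psi=0.5, scaling=None):
    return NMixtureResults.from_coefficients(
        abundance={"intercept": 3.095, "bio01": 0.446, "pel_abu": 0.320,
                   "pel_neigh": -0.343, "pel_abu:bio01": 0.592},
        detection={"intercept": -2.632, "pel_ava": 0.399},
        mixture="ZIP", psi=psi,
        scaling_record=scaling if scaling is not None else {
            "bio01": (6.0, 2.0), "pel_abu": (5.0, 10.0),
            "pel_neigh": (20.0, 40.0), "pel_ava": (4.0, 8.0)})


@pytest.fixture(scope="module")
def fitted(study_grid):
    scaling = {c: (float(study_grid.cells[c].mean()),
                   float(study_grid.cells[c].std(ddof=1)))
               for c in ("bio01", "pel_abu", "pel_neigh")}
    scaling["pel_ava"] = (4.0, 8.0)
    return reference_results(scaling=scaling)


def as_map(values, cells=None):
    cells = cells or [f"c{i}" for i in range(len(values))]
    return pd.DataFrame({"cell_id": cells, "E_N": np.asarray(values, float)})


class TestProjectMap:
    def test_null_scenario_is_identity(self, fitted, study_grid):
        base = project_map(fitted, study_grid, None)
        null = project_map(fitted, study_grid, ScenarioSpec(0.0, 1.0, "null"))
        np.testing.assert_array_equal(base["E_N"], null["E_N"])
        chg = categorize_changes(base, null)
        assert (chg.per_cell["category"] == "no_change").all()

    def test_restricted_to_host_plant_cells_by_default(self, fitted,
                                                       study_grid):
        base = project_map(fitted, study_grid, None)
        lut = study_grid.cells.set_index("cell_id")["pel_abu"]
        assert (lut.loc[base["cell_id"]] > 0).all()
        everywhere = project_map(fitted, study_grid, None, cells="all")
        assert len(everywhere) == len(study_grid)

    def test_removing_all_pots_flags_host_free(self, fitted, study_grid):
        gone = project_map(fitted, study_grid, ScenarioSpec(0.0, 0.0, "erad"))
        assert gone["host_free"].all()
        assert np.isfinite(gone["E_N"]).all()

    def test_warming_increases_cells_passing_sign_condition(self, fitted,
                                                            study_grid):
        """+1.5 degC strictly raises E[N] in every projected cell whose
        scaled pot count exceeds -beta_bio01/beta_int = -0.446/0.592."""
        base = project_map(fitted, study_grid, None)
        warm = project_map(fitted, study_grid, ScenarioSpec(1.5, 1.0, "warm"))
        mean, sd = fitted.scaling_record["pel_abu"]
        lut = study_grid.cells.set_index("cell_id")["pel_abu"]
        z = (lut.loc[base["cell_id"]].to_numpy() - mean) / sd
        passing = z > -0.446 / 0.592
        assert passing.any()
        assert (warm["E_N"].to_numpy()[passing]
                > base["E_N"].to_numpy()[passing]).all()
        failing = z < -0.446 / 0.592
        if failing.any():
            assert (warm["E_N"].to_numpy()[failing]
                    <= base["E_N"].to_numpy()[failing]).all()

    def test_pot_reduction_recomputes_neighbours(self, fitted, study_grid):
        direct = project_map(fitted, study_grid, ScenarioSpec(0.0, 0.5, "m"),
                             recompute_neigh=False)
        recomputed = project_map(fitted, study_grid,
                                 ScenarioSpec(0.0, 0.5, "m"),
                                 recompute_neigh=True)
        np.testing.assert_allclose(direct["E_N"], recomputed["E_N"],
                                   rtol=1e-9)  # halving commutes with the sum

    def test_requires_scaling_record(self, study_grid):
        bare = reference_results(scaling={})
        with pytest.raises(ValueError, match="scaling"):
            project_map(bare, study_grid, None)


class TestCategorize:
    def test_identical_maps_are_all_no_change(self):
        m = as_map([1.2, 3.4, 0.4])
        out = categorize_changes(m, m).summary()
        assert out.loc[out["category"].str.contains("no changes"),
                       "percent"].iloc[0] == 100.0

    def test_new_infestation_counts_as_increase(self):
        base = as_map([0.3] + [1.0] * 9)
        scen = as_map([2.6] + [1.0] * 9)
        res = categorize_changes(base, scen)
        c = res.counts()
        assert c["new_infestation"] == 1 and c["increase"] == 1
        s = res.summary().set_index("category")
        assert s.loc["cells with new egg infestations", "percent"] == 10.0
        assert s.loc["cells with egg increases", "percent"] == 10.0

    def test_rounding_rule(self):
        """Baseline [1.2, 3.6] vs scenario [1.4, 2.1] rounds to (1,4) vs
        (1,2): half the cells unchanged, half decreased."""
        res = categorize_changes(as_map([1.2, 3.6]), as_map([1.4, 2.1]))
        cats = res.per_cell["category"].tolist()
        assert cats == ["no_change", "decrease"]

    def test_half_up_rounding(self):
        np.testing.assert_array_equal(round_half_up([0.5, 1.5, 2.4, 2.5]),
                                      [1.0, 2.0, 2.0, 3.0])

    def test_mismatched_cells_rejected(self):
        with pytest.raises(ValueError):
            categorize_changes(as_map([1.0], ["a"]), as_map([1.0], ["b"]))

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 50), st.floats(0, 50)),
                    min_size=1, max_size=30))
    def test_categories_partition(self, pairs):
        base = as_map([p[0] for p in pairs])
        scen = as_map([p[1] for p in pairs])
        c = categorize_changes(base, scen).counts()
        assert c["increase"] + c["decrease"] + c["no_change"] == c["total"]
        assert c["new_infestation"] <= c["increase"]


class TestGroupSummaries:
    def test_partition_and_sorting(self, fitted, study_grid):
        base = project_map(fitted, study_grid, None)
        mit = project_map(fitted, study_grid, ScenarioSpec(1.5, 0.5, "m"))
        res = categorize_changes(base, mit)
        tab = summarize_by_group(res, study_grid)
        assert tab["n_cells"].sum() == len(res.per_cell)
        assert (tab["mean_elevation"].diff().dropna() >= 0).all()
        assert (tab["n_decrease"].sum()
                == (res.per_cell["category"] == "decrease").sum())

    def test_single_group_equals_global(self, fitted, study_grid):
        grid = study_grid
        cells = grid.cells.copy()
        cells["municipality"] = "ALL"
        single = type(grid)(cells=cells, n_rows=grid.n_rows,
                            n_cols=grid.n_cols)
        base = project_map(fitted, single, None)
        warm = project_map(fitted, single, ScenarioSpec(1.5, 1.0, "w"))
        res = categorize_changes(base, warm)
        tab = summarize_by_group(res, single)
        assert len(tab) == 1
        c = res.counts()
        assert tab["n_increase"].iloc[0] == c["increase"]

    def test_group_without_projected_cells_gets_zero_row(self, fitted,
                                                         study_grid):
        base = project_map(fitted, study_grid, None)
        warm = project_map(fitted, study_grid, ScenarioSpec(1.5, 1.0, "w"))
        res = categorize_changes(base, warm)
        tab = summarize_by_group(res, study_grid)
        munis_in_grid = set(study_grid.cells["municipality"])
        assert set(tab["municipality"]) == munis_in_grid
        empty = tab[tab["n_cells"] == 0]
        assert (empty[["pct_decrease", "pct_increase"]] == 0).all().all()


class TestElevationProfile:
    def test_constant_map_is_flat(self, study_grid):
        cells = study_grid.cells["cell_id"].tolist()
        prof = elevation_profile([("c", as_map([2.0] * len(cells), cells))],
                                 study_grid, 5)
        filled = prof.dropna(subset=["mean_E"])
        assert (filled["mean_E"] == 2.0).all()

    def test_decreasing_map_gives_non_increasing_profile(self, study_grid):
        cells = study_grid.cells
        values = 100.0 - 0.04 * cells["elevation"].to_numpy()
        prof = elevation_profile(
            [("d", as_map(values, cells["cell_id"].tolist()))],
            study_grid, 6)
        means = prof.dropna(subset=["mean_E"])["mean_E"].to_numpy()
        assert (np.diff(means) <= 1e-9).all()

    def test_requires_bins_and_maps(self, study_grid):
        m = as_map([1.0], [study_grid.cells["cell_id"].iloc[0]])
        with pytest.raises(ValueError):
            elevation_profile([("m", m)], study_grid, 1)
        with pytest.raises(ValueError):
            elevation_profile([], study_grid, 5)
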