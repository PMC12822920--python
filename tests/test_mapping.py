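import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import herdgrid as hg
from herdgrid.mapping import RunReport, _compact_letters

from conftest import census_from_rects, square_grid


def layer(grid, values, name="counts"):
    return hg.RasterLayer(grid, name, np.asarray(values, dtype=float))


class TestDensityToCounts:
    def test_half_head_per_ha_at_225m(self):
        grid = square_grid(2)
        out = hg.density_to_counts(layer(grid, np.full((2, 2), 0.5), "density"))
        np.testing.assert_allclose(out.values, 2.53125)

    def test_zero_and_linearity(self):
        grid = square_grid(2)
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1, (2, 2))
        one = hg.density_to_counts(layer(grid, d, "density")).values
        three = hg.density_to_counts(layer(grid, 3 * d, "density")).values
        np.testing.assert_allclose(three, 3 * one)
        assert hg.density_to_counts(layer(grid, np.zeros((2, 2)), "d")).values.sum() == 0


class TestAggregateToMunicipality:
    def test_two_pixels_sum(self):
        grid = square_grid(2)
        counts = layer(grid, [[1.0, 1.0], [0.0, 0.0]])
        census = census_from_rects([(0, 225, 450, 450)], [0], [False])
        out = hg.aggregate_to_municipality(counts, census)
        assert out[0] == pytest.approx(2.0)

    def test_matches_bruteforce_assignment(self):
        grid = square_grid(5)
        rng = np.random.default_rng(1)
        counts = layer(grid, rng.uniform(0, 2, (5, 5)))
        rects = [(0, 0, 560, 1125), (560, 0, 1125, 1125)]
        census = census_from_rects(rects, [0, 0], [False, False])
        out = hg.aggregate_to_municipality(counts, census)
        xx, yy = grid.centre_coords()
        brute = np.zeros(2)
        for r in range(5):
            for c in range(5):
                for k, rect in enumerate(rects):
                    if shapely.contains_xy(shapely.box(*rect), xx[r, c], yy[r, c]):
                        brute[k] += counts.values[r, c]
        np.testing.assert_allclose(out, brute, rtol=1e-12)

    def test_partition_conservation(self, tiny_scene):
        grid = tiny_scene.grid
        rng = np.random.default_rng(2)
        counts = layer(grid, rng.uniform(0, 1, grid.shape))
        out = hg.aggregate_to_municipality(counts, tiny_scene.municipalities)
        # Voronoi municipalities cover the whole grid
        assert out.sum() == pytest.approx(counts.values.sum(), rel=1e-12)


class TestGOF:
    def test_perfect_prediction(self):
        rmse, pcc = hg.gof([1.0, 2, 3], [1.0, 2, 3])
        assert rmse == 0.0
        assert pcc == pytest.approx(1.0)

    def test_constant_prediction_hand_example(self):
        rmse, pcc = hg.gof([0.0, 1, 2], [1.0, 1, 1])
        assert rmse == pytest.approx(np.sqrt(2 / 3))
        assert np.isnan(pcc)

    def test_pcc_affine_invariance(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(0, 10, 8)
        pred = rng.uniform(0, 10, 8)
        _, p1 = hg.gof(obs, pred)
        _, p2 = hg.gof(obs, 3.2 * pred + 7)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hg.gof([1.0, 2], [1.0, 2])


class TestMinMax:
    def test_endpoints_and_midpoint(self):
        np.testing.assert_allclose(
            hg.minmax_standardise([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0]
        )

    def test_order_preserved(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=20)
        s = hg.minmax_standardise(v)
        np.testing.assert_array_equal(np.argsort(v), np.argsort(s))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            hg.minmax_standardise([5.0, 5.0])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(v=hnp.arrays(float, 10, elements=st.floats(-1e6, 1e6)))
    def test_bounds_property(self, v):
        if np.max(v) == np.min(v):
            return
        s = hg.minmax_standardise(v)
        assert s.min() == 0.0 and s.max() == 1.0
        assert ((s >= 0) & (s <= 1)).all()


class TestEnsemble:
    def test_identical_maps_have_zero_sd(self):
        grid = square_grid(3)
        m = layer(grid, np.arange(9.0).reshape(3, 3))
        mean, sd = hg.ensemble([m, m, m])
        np.testing.assert_allclose(mean.values, m.values)
        np.testing.assert_allclose(sd.values, 0.0)

    def test_population_sd_of_two_maps(self):
        grid = square_grid(1)
        mean, sd = hg.ensemble([layer(grid, [[0.0]]), layer(grid, [[2.0]])])
        assert mean.values[0, 0] == 1.0
        assert sd.values[0, 0] == 1.0

    def test_permutation_invariance(self):
        grid = square_grid(2)
        rng = np.random.default_rng(5)
        maps = [layer(grid, rng.uniform(size=(2, 2))) for _ in range(4)]
        a, _ = hg.ensemble(maps)
        b, _ = hg.ensemble(maps[::-1])
        np.testing.assert_allclose(a.values, b.values)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hg.ensemble([layer(square_grid(2), np.zeros((2, 2))),
                         layer(square_grid(3), np.zeros((3, 3)))])


class TestAdjustCounts:
    def test_hand_example(self):
        grid = hg.GridSpec(0, 225, 225.0, 1, 2, "t")
        out = hg.adjust_counts(layer(grid, [[1.0, 3.0]]), 8)
        np.testing.assert_allclose(out.values, [[2.0, 6.0]])

    def test_already_matching_total_unchanged(self):
        grid = square_grid(2)
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = hg.adjust_counts(layer(grid, vals), 10.0)
        np.testing.assert_allclose(out.values, vals)

    def test_scale_invariance_and_zeros_stay_zero(self):
        grid = square_grid(3)
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 5, (3, 3))
        vals[0, 0] = 0.0
        a = hg.adjust_counts(layer(grid, vals), 42.0)
        b = hg.adjust_counts(layer(grid, 7.5 * vals), 42.0)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)
        assert a.values[0, 0] == 0.0

    def test_conserves_total_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(2, 12))
            grid = square_grid(n)
            vals = rng.uniform(0, 3, (n, n)) * rng.integers(0, 2, (n, n))
            if vals.sum() == 0:
                vals[0, 0] = 1.0
            total = float(rng.integers(1, 100_000))
            out = hg.adjust_counts(layer(grid, vals), total)
            assert out.values.sum() == pytest.approx(total, rel=1e-6)

    def test_all_zero_map_with_positive_total_rejected(self):
        grid = square_grid(2)
        with pytest.raises(ValueError):
            hg.adjust_counts(layer(grid, np.zeros((2, 2))), 5)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        vals=hnp.arrays(float, (4, 4), elements=st.floats(0, 1e6)),
        total=st.floats(0.1, 1e9),
    )
    def test_conservation_and_nonnegativity_property(self, vals, total):
        if vals.sum() <= 0:
            return
        out = hg.adjust_counts(layer(square_grid(4), vals), total)
        assert out.values.sum() == pytest.approx(total, rel=1e-6)
        assert (out.values >= 0).all()
        assert ((vals == 0) <= (out.values == 0)).all()


def reports_from(groups_values, metric="pcc"):
    reports = []
    for g, values in groups_values.items():
        strategy, model_type = g.split("-")
        for r, v in enumerate(values):
            reports.append(RunReport(r, strategy, model_type, "model_I",
                                     rmse=v, pcc=v))
    return reports


class TestCompareRuns:
    def test_identical_groups_single_letter(self):
        vals = [1.0, 1.1, 0.9, 1.05]
        res = hg.compare_runs(reports_from({"a-rf": vals, "a-grf": vals}))
        letters = set(res["pcc"]["letters"].values())
        assert len(letters) == 1
        assert res["pcc"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_strongly_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 10)
        b = rng.normal(10 * a.std() + 10, 1, 10)
        res = hg.compare_runs(reports_from({"a-rf": list(a), "a-grf": list(b)}))
        la = res["pcc"]["letters"]["a-rf-model_I"]
        lb = res["pcc"]["letters"]["a-grf-model_I"]
        assert set(la).isdisjoint(set(lb))

    def test_f_statistic_matches_bruteforce_sums_of_squares(self):
        groups = {
            "a-rf": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
            "a-grf": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
            "b-rf": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0],
        }
        res = hg.compare_runs(reports_from(groups))
        data = [np.asarray(v) for v in groups.values()]
        grand = np.concatenate(data).mean()
        ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
        ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
        k, n = len(data), sum(len(d) for d in data)
        f_brute = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert res["pcc"]["F"] == pytest.approx(f_brute, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            hg.compare_runs(reports_from({"a-rf": [1.0, 2.0]}))

    def test_compact_letters_cover_all_groups(self):
        letters = _compact_letters(["g1", "g2", "g3"], {frozenset(("g1", "g2"))})
        assert all(letters[g] for g in ("g1", "g2", "g3"))
        assert set(letters["g1"]) & set(letters["g2"])
        assert not set(letters["g1"]) & set(letters["g3"])


@pytest.fixture(scope="module")
def outcome(tiny_stack, tiny_prepared, tiny_scene):
    cen, _ = tiny_prepared
    config = hg.ExperimentConfig(n_replicates=2, base_seed=0, bandwidth=9)
    return hg.run_experiment(tiny_stack, cen, tiny_scene.suitability, config), cen


class TestRunExperiment:
    def test_eight_report_groups(self, outcome):
        (table, ensembles, reports), _ = outcome
        assert len(ensembles) == 8
        groups = table.groupby(["strategy", "model_type", "predictor_set"]).size()
        assert len(groups) == 8
        assert (groups == 2).all()

    def test_adjusted_totals_equal_census_total(self, outcome):
        (table, ensembles, _), cen = outcome
        for prod in ensembles.values():
            assert prod.adjusted_map.values.sum() == pytest.approx(
                cen.total_count(), rel=1e-6
            )

    def test_deterministic_given_seed(self, tiny_stack, tiny_prepared, tiny_scene):
        cen, _ = tiny_prepared
        config = hg.ExperimentConfig(
            n_replicates=2, base_seed=1, bandwidth=9,
            strategies=("average",), predictor_sets=("model_II",),
        )
        t1, e1, _ = hg.run_experiment(tiny_stack, cen, tiny_scene.suitability, config)
        t2, e2, _ = hg.run_experiment(tiny_stack, cen, tiny_scene.suitability, config)
        pd.testing.assert_frame_equal(t1, t2)
        for key in e1:
            np.testing.assert_array_equal(
                e1[key].adjusted_map.values, e2[key].adjusted_map.values
            )

    def test_uniform_densities_allocate_by_suitable_area(self, tiny_stack,
                                                         tiny_prepared, tiny_scene):
        """With spatially uniform municipal densities the adjusted ensemble
        must distribute counts proportionally to suitable pixel area."""
        cen, _ = tiny_prepared
        uniform = cen.copy()
        uniform.table["adjusted_density"] = 0.3
        area = uniform.table["suitable_area"].to_numpy(dtype=float)
        uniform.table["adjusted_count"] = 0.3 * area
        uniform.table["count"] = uniform.table["adjusted_count"]
        config = hg.ExperimentConfig(
            n_replicates=2, base_seed=0, bandwidth=9,
            strategies=("average",), model_types=("rf",),
            predictor_sets=("model_I",),
        )
        _, ensembles, _ = hg.run_experiment(
            tiny_stack, uniform, tiny_scene.suitability, config
        )
        prod = ensembles["average-rf-model_I"]
        predicted = hg.aggregate_to_municipality(prod.adjusted_map, uniform)
        _, pcc = hg.gof(area, predicted)
        assert pcc > 0.95

    def test_unprepared_census_rejected(self, tiny_stack, tiny_scene):
        with pytest.raises(ValueError):
            hg.run_experiment(
                tiny_stack, tiny_scene.municipalities, tiny_scene.suitability,
                hg.ExperimentConfig(n_replicates=2),
            )
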