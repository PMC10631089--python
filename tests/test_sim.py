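"""Synthetic geography, planted clusters, scenario data generation, scoring."""

import math

import numpy as np
import pytest

from mnscan import (
    Scenario,
    make_grid_geography,
    performance_measures,
    plant_true_clusters,
    run_simulation_study,
    simulate_dataset,
    table1_scenarios,
)
from mnscan.sim import ALTERNATIVE_HYPOTHESES, NULL_PROBS, _is_connected


class TestGridGeography:
    def test_corner_has_two_neighbors(self):
        rm = make_grid_geography(3)
        assert rm.n_regions == 9
        degree = {i: 0 for i in range(9)}
        for a, b in rm.adjacency:
            degree[a] += 1
            degree[b] += 1
        assert degree[0] == 2  # corner region

    @pytest.mark.parametrize("n_side", [3, 5, 8])
    def test_lattice_edge_count(self, n_side):
        rm = make_grid_geography(n_side)
        assert rm.n_regions == n_side**2
        assert len(rm.adjacency) == 2 * n_side * (n_side - 1)

    def test_minimum_side(self):
        with pytest.raises(ValueError):
            make_grid_geography(2)


class TestPlantTrueClusters:
    def test_circular_8pct_is_five_regions(self):
        rm = make_grid_geography(8)
        (cl,) = plant_true_clusters(rm, "circular", 0.08, count=1)
        assert len(cl) == 5
        assert _is_connected(set(cl), rm.adjacency)

    def test_two_clusters_disjoint_and_connected(self):
        rm = make_grid_geography(8)
        c1, c2 = plant_true_clusters(rm, "elliptic", 0.08, count=2)
        assert not (c1 & c2)
        assert _is_connected(set(c1), rm.adjacency)
        assert _is_connected(set(c2), rm.adjacency)

    def test_irregular_15pct_is_ten_connected_regions(self):
        rm = make_grid_geography(8)
        rng = np.random.default_rng(0)
        (cl,) = plant_true_clusters(rm, "irregular", 0.15, count=1, rng=rng)
        assert len(cl) == 10
        assert _is_connected(set(cl), rm.adjacency)

    def test_elliptic_is_elongated(self):
        rm = make_grid_geography(8)
        (cl,) = plant_true_clusters(rm, "elliptic", 0.08, count=1)
        xs = rm.coords[sorted(cl), 0]
        ys = rm.coords[sorted(cl), 1]
        assert np.ptp(xs) > np.ptp(ys)  # long axis horizontal


class TestSimulateDataset:
    def _scenario(self, p1=None):
        rm = make_grid_geography(8)
        (cl,) = plant_true_clusters(rm, "circular", 0.08, count=1)
        p1 = p1 if p1 is not None else ALTERNATIVE_HYPOTHESES[1]
        return Scenario(rm, (cl,), p_list=(p1,))

    def test_exact_case_total(self):
        scn = self._scenario()
        for seed in range(3):
            assert simulate_dataset(scn, seed=seed).total == 1000

    def test_null_effect_is_exchangeable_with_null_draw(self):
        scn = self._scenario(p1=NULL_PROBS)
        ct = simulate_dataset(scn, seed=1)
        # every region, cluster or not, draws categories from the same vector
        assert np.allclose(scn.region_probs(), 0.25)
        assert ct.total == 1000

    def test_category_frequencies_within_binomial_tolerance(self):
        scn = self._scenario()
        ct = simulate_dataset(scn, seed=2)
        w_in = len(scn.truth_union) / scn.region_map.n_regions
        expected = (1 - w_in) * np.asarray(NULL_PROBS) + w_in * np.asarray(
            ALTERNATIVE_HYPOTHESES[1]
        )
        freq = ct.category_totals / ct.total
        se = np.sqrt(expected * (1 - expected) / 1000)
        assert np.all(np.abs(freq - expected) <= 3 * se)

    def test_table1_hypothesis_vectors(self):
        assert ALTERNATIVE_HYPOTHESES[1] == (0.05, 0.15, 0.35, 0.45)
        assert ALTERNATIVE_HYPOTHESES[2] == (0.05, 0.25, 0.25, 0.45)
        assert ALTERNATIVE_HYPOTHESES[3] == (0.10, 0.10, 0.40, 0.40)
        assert ALTERNATIVE_HYPOTHESES[4] == (0.15, 0.15, 0.15, 0.55)


class TestPerformanceMeasures:
    def test_perfect_detection(self):
        assert performance_measures({1, 2}, {1, 2}, 69) == (1.0, 1.0, 0.0)

    def test_disjoint_detection(self):
        d, t = set(range(5)), set(range(10, 15))
        sen, ppv, mis = performance_measures(d, t, 69)
        assert (sen, ppv) == (0.0, 0.0)
        assert mis == pytest.approx(10 / 69)

    def test_partial_overlap(self):
        t = set(range(1, 6))
        d = set(range(4, 10))
        sen, ppv, mis = performance_measures(d, t, 69)
        assert sen == pytest.approx(0.4)
        assert ppv == pytest.approx(1 / 3)
        assert mis == pytest.approx(7 / 69)

    def test_union_denominator_option(self):
        t = set(range(1, 6))
        d = set(range(4, 10))
        _, _, mis = performance_measures(d, t, 69, denominator="union")
        assert mis == pytest.approx(7 / 9)

    def test_empty_detection_gives_nan_ppv(self):
        sen, ppv, mis = performance_measures(set(), {1, 2}, 10)
        assert sen == 0.0 and math.isnan(ppv)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            performance_measures({1}, set(), 10)


class TestScenarioDesign:
    def test_crossed_design_yields_26_scenarios(self):
        scenarios = table1_scenarios()
        assert len(scenarios) == 26
        names = [s.name for s in scenarios]
        assert len(set(names)) == 26
        singles = [s for s in scenarios if len(s.true_clusters) == 1]
        doubles = [s for s in scenarios if len(s.true_clusters) == 2]
        assert len(singles) == 12  # 3 models x 4 hypotheses
        assert len(doubles) == 14  # 2 models x (4 homogeneous + 3 heterogeneous)

    def test_heterogeneous_settings_have_distinct_vectors(self):
        for s in table1_scenarios():
            if s.name[1] in "567":
                assert s.p_list[0] != s.p_list[1]

    def test_invalid_scenarios_rejected(self):
        rm = make_grid_geography(4)
        with pytest.raises(ValueError):
            Scenario(rm, (frozenset({0}),), p_list=((0.5, 0.4),))  # doesn't sum to 1
        with pytest.raises(ValueError):
            Scenario(rm, (frozenset({0}), frozenset({0})), p_list=(NULL_PROBS, NULL_PROBS))


class TestRunSimulationStudy:
    def _tiny_study(self, seed):
        rm = make_grid_geography(5)
        (cl,) = plant_true_clusters(rm, "circular", 0.12, count=1)
        scn = Scenario(rm, (cl,), p_list=((0.02, 0.08, 0.40, 0.50),), n_cases=400)
        return run_simulation_study(
            scn, n_reps=3, replications=19, seed=seed,
            shapes=(1,), angles_per_shape=(1,), grid=(5, 10, 15, 25, 50),
        )

    def test_bytewise_identical_summaries(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        self._tiny_study(123).to_csv(p1)
        self._tiny_study(123).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_frequencies_sum_to_significant_count(self):
        summ = self._tiny_study(7)
        frame = summ.to_frame()
        freq = frame[frame["stat"] == "Freq"]
        for _, row in freq.iterrows():
            assert sum(row[m] for m in summ.grid) <= summ.n_with_significant
        assert summ.n_with_significant <= summ.n_datasets

    def test_measures_in_unit_interval(self):
        summ = self._tiny_study(7)
        rec = summ.records
        for col in rec.columns:
            if col.endswith(("_sen", "_ppv", "_mis")):
                vals = rec[col].dropna()
                assert ((vals >= 0) & (vals <= 1)).all()
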