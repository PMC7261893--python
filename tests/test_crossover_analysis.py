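import numpy as np
import pandas as pd
import pytest

import pollenscan as ps
from pollenscan import datasets
from pollenscan.crossover_analysis import Switch, _assign_arm
from pollenscan.origin_phasing import OriginMatrix, phase_from_parents, swap_phase


def origin_matrix(rows: dict[str, list[str]], loci: list[str]) -> OriginMatrix:
    return OriginMatrix(origins=pd.DataFrame.from_dict(rows, orient="index", columns=loci))


@pytest.fixture()
def chr1_loci(lemon_map):
    return lemon_map.loci


class TestDetectSwitches:
    def test_single_switch(self, lemon_map, chr1_loci):
        om = origin_matrix(
            {"g1": ["P1", "P1", "P2", "P2"] + ["P2"] * 8}, chr1_loci
        )
        sw = ps.detect_switches(om, lemon_map, 1)
        assert len(sw.switches["g1"]) == 1
        s = sw.switches["g1"][0]
        assert (s.left_locus, s.right_locus) == ("CIBE6147", "CiC4827-01")

    def test_missing_marker_skipped_no_switch(self, lemon_map, chr1_loci):
        om = origin_matrix(
            {"g1": ["P1", "MISSING", "P1"] + ["P1"] * 9}, chr1_loci
        )
        sw = ps.detect_switches(om, lemon_map, 1)
        assert sw.switches["g1"] == []

    def test_missing_marker_skipped_merged_interval(self, lemon_map, chr1_loci):
        om = origin_matrix(
            {"g1": ["P1", "MISSING", "P2"] + ["P2"] * 9}, chr1_loci
        )
        sw = ps.detect_switches(om, lemon_map, 1)
        s = sw.switches["g1"][0]
        assert (s.left_locus, s.right_locus) == ("CIBE6126", "CiC4827-01")

    def test_ambiguous_and_off_ladder_treated_as_uninformative(
        self, lemon_map, chr1_loci
    ):
        om = origin_matrix(
            {"g1": ["P1", "AMBIGUOUS", "OFF_LADDER", "P2"] + ["P2"] * 8},
            chr1_loci,
        )
        sw = ps.detect_switches(om, lemon_map, 1)
        s = sw.switches["g1"][0]
        assert (s.left_locus, s.right_locus) == ("CIBE6126", "1P3705568")

    def test_too_few_informative_markers_excludes_gamete(
        self, lemon_map, chr1_loci
    ):
        om = origin_matrix(
            {"g1": ["P1"] + ["MISSING"] * 11, "g2": ["P1"] * 12}, chr1_loci
        )
        sw = ps.detect_switches(om, lemon_map, 1)
        assert "g1" in sw.excluded
        assert "g1" not in sw.switches
        assert sw.switches["g2"] == []

    def test_switch_count_bounded_by_informative_markers(self, lemon_map):
        cfg = datasets.lemon_pollen_config(seed=31, dropout_rate=0.25)
        gm, _ = ps.simulate_gametes(cfg)
        om = ps.assign_origin(gm, lemon_map, phase_from_parents(lemon_map))
        sw = ps.detect_switches(om, lemon_map, 1)
        for unit in sw.analyzed_units:
            assert len(sw.switches[unit]) <= len(sw.informative_idx[unit]) - 1

    def test_label_swap_leaves_counts_unchanged(self, lemon_map):
        cfg = datasets.lemon_pollen_config(seed=32, dropout_rate=0.15)
        gm, _ = ps.simulate_gametes(cfg)
        phase = phase_from_parents(lemon_map)
        om_a = ps.assign_origin(gm, lemon_map, phase)
        om_b = ps.assign_origin(gm, lemon_map, swap_phase(phase))
        sw_a = ps.detect_switches(om_a, lemon_map, 1)
        sw_b = ps.detect_switches(om_b, lemon_map, 1)
        assert {u: len(v) for u, v in sw_a.switches.items()} == {
            u: len(v) for u, v in sw_b.switches.items()
        }


class TestArmAssignment:
    def test_interval_on_each_side(self):
        # centromere at 25
        left = Switch(0, 1, "a", "b", 5.0, 20.0)
        right = Switch(2, 3, "c", "d", 30.0, 40.0)
        assert _assign_arm(left, 25.0) == 1
        assert _assign_arm(right, 25.0) == 2

    def test_spanning_interval_goes_to_larger_share(self):
        mostly_left = Switch(0, 1, "a", "b", 5.0, 26.0)  # 20 vs 1
        mostly_right = Switch(0, 1, "a", "b", 24.0, 45.0)  # 1 vs 20
        assert _assign_arm(mostly_left, 25.0) == 1
        assert _assign_arm(mostly_right, 25.0) == 2

    def test_exact_tie_goes_to_arm_one(self):
        tie = Switch(0, 1, "a", "b", 20.0, 30.0)
        assert _assign_arm(tie, 25.0) == 1


class TestCountPerArm:
    def test_published_distribution_statistics(self):
        dist = datasets.load_crossover_distribution()
        summary = ps.CrossoverSummary.from_distribution(dist, chromosome=1)
        assert summary.n_gametes_analyzed == 34
        assert summary.mean_co_per_chromosome == pytest.approx(67 / 34)
        assert summary.zero_co_fraction == pytest.approx(5 / 34)
        assert ps.max_crossovers(summary) == (5, 4)
        table = summary.distribution_table()
        assert table.loc[0, 0] == 5
        assert table.to_numpy().sum() == 34

    def test_single_gamete_no_switch(self, lemon_map):
        om = origin_matrix({"g1": ["P1"] * 12}, lemon_map.loci)
        sw = ps.detect_switches(om, lemon_map, 1)
        summary = ps.count_per_arm(sw, lemon_map)
        assert summary.distribution == {(0, 0): 1}
        assert summary.mean_co_per_chromosome == 0.0

    def test_missing_centromere_raises(self, lemon_map):
        om = origin_matrix({"g1": ["P1"] * 12}, lemon_map.loci)
        sw = ps.detect_switches(om, lemon_map, 1)
        bare = ps.MarkerMap(markers=list(lemon_map.markers))
        with pytest.raises(Exception, match="centromere"):
            ps.count_per_arm(sw, bare)

    def test_empty_summary_rejects_statistics(self):
        summary = ps.CrossoverSummary(per_gamete_arm_counts={})
        with pytest.raises(ValueError):
            ps.max_crossovers(summary)
        with pytest.raises(ValueError):
            _ = summary.mean_co_per_chromosome


class TestIntervalRecombination:
    def test_simple_ratio(self, lemon_map):
        rows = {f"g{i}": ["P1"] * 12 for i in range(34)}
        rows["g0"] = ["P1", "P2"] + ["P2"] * 10
        om = origin_matrix(rows, lemon_map.loci)
        iv = ps.interval_recombination(om, lemon_map, 1)
        assert iv.loc[0, "n_co"] == 1
        assert iv.loc[0, "n_informative"] == 34
        assert iv.loc[0, "co_ratio"] == pytest.approx(1 / 34)

    def test_zero_informative_interval_is_nan(self, lemon_map):
        rows = {"g1": ["P1", "MISSING", "P1"] + ["MISSING"] * 9}
        om = origin_matrix(rows, lemon_map.loci)
        iv = ps.interval_recombination(om, lemon_map, 1)
        # intervals 0 and 1 are covered by the merged observation
        assert iv.loc[0, "n_informative"] == 1
        assert iv.loc[1, "n_informative"] == 1
        # beyond locus 3 nothing is observed: undefined ratio, never 0
        assert iv.loc[2:, "n_informative"].eq(0).all()
        assert iv.loc[2:, "co_ratio"].isna().all()

    def test_conservation_of_switches(self, lemon_map):
        cfg = datasets.lemon_pollen_config(seed=33, dropout_rate=0.2)
        gm, _ = ps.simulate_gametes(cfg)
        om = ps.assign_origin(gm, lemon_map, phase_from_parents(lemon_map))
        sw = ps.detect_switches(om, lemon_map, 1)
        for rule in ("elementary", "merged"):
            iv = ps.interval_recombination(om, lemon_map, 1, denominator=rule)
            assert iv["n_co"].sum() == sw.total_switches()

    def test_merged_observation_counts_every_spanned_interval(self, lemon_map):
        rows = {"g1": ["P1", "MISSING", "P2"] + ["MISSING"] * 9}
        om = origin_matrix(rows, lemon_map.loci)
        iv = ps.interval_recombination(om, lemon_map, 1)
        assert list(iv["n_informative"][:2]) == [1, 1]
        assert iv["n_co"].sum() == 1
        # the switch lands on the single widest elementary sub-interval
        assert iv.loc[0, "n_co"] + iv.loc[1, "n_co"] == 1


class TestParityOracle:
    def test_detected_switches_equal_truth_parity(self, lemon_map):
        """With no dropout, the detected switch pattern must equal, per
        elementary interval, the parity of the true crossover count (an
        even number of crossovers between markers is invisible)."""
        cfg = datasets.lemon_pollen_config(seed=34, n_gametes=200, dropout_rate=0.0)
        gm, truths = ps.simulate_gametes(cfg)
        om = ps.assign_origin(gm, lemon_map, phase_from_parents(lemon_map))
        sw = ps.detect_switches(om, lemon_map, 1)
        positions = [m.position_cm for m in lemon_map.chromosome(1)]
        for unit, truth in zip(gm.unit_ids, truths):
            xo = np.array(truth.crossover_positions[1])
            detected = {(s.left, s.right) for s in sw.switches[unit]}
            for k in range(len(positions) - 1):
                n_true = np.sum((xo >= positions[k]) & (xo < positions[k + 1]))
                assert ((k, k + 1) in detected) == bool(n_true % 2)


class TestRecoveryAtScale:
    def test_co_ratio_recovers_haldane_fraction(self, lemon_map):
        cfg = ps.SimulationConfig(
            marker_map=lemon_map, n_gametes=5000, seed=35, parent="cross"
        )
        gm, _ = ps.simulate_gametes(cfg)
        om = ps.assign_origin(gm, lemon_map, phase_from_parents(lemon_map))
        iv = ps.interval_recombination(om, lemon_map, 1)
        for _, row in iv.iterrows():
            r = ps.recomb_fraction(row["right_cm"] - row["left_cm"], "haldane")
            sd = np.sqrt(r * (1 - r) / row["n_informative"])
            assert abs(row["co_ratio"] - r) < 3 * sd + 1e-12
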