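"""Ratio/threshold trend analysis: sums, changes, switches, extrema."""

import numpy as np
import pandas as pd
import pytest

from archolimb.phylo import MAIN_LINE_NODES, STUDY_NODES
from archolimb.trends import (
    HYPOTHESES,
    detect_extrema,
    detect_switches,
    hypothesis_ratio,
    hypothesis_report,
    internodal_changes,
    ratio_series,
    sum_by_action,
)

NODES = list(STUDY_NODES)


def table(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame(rows, index=NODES).T
    df.index.name = "MTU"
    return df


class TestSumByAction:
    def test_signs_split_into_directions(self):
        df = pd.DataFrame(
            {"n1": [0.1, -0.2, -0.3]}, index=["a", "b", "c"]
        ).rename_axis("MTU")
        sums = sum_by_action(df, "hip", "FLEXEX")
        assert sums.loc["n1", "flexion"] == pytest.approx(0.1)
        assert sums.loc["n1", "extension"] == pytest.approx(0.5)

    def test_all_zero_column(self):
        df = pd.DataFrame({"n1": [0.0, 0.0]}, index=["a", "b"])
        sums = sum_by_action(df, "knee", "FLEXEX")
        assert (sums.loc["n1"] == 0).all()

    def test_random_table_matches_double_loop_and_conserves(self, rng):
        vals = rng.normal(size=(20, 12))
        df = pd.DataFrame(vals, index=[f"m{i}" for i in range(20)], columns=NODES)
        sums = sum_by_action(df, "hip", "LAR")
        for j, node in enumerate(NODES):
            pos = sum(v for v in vals[:, j] if v > 0)
            neg = sum(-v for v in vals[:, j] if v < 0)
            assert sums.loc[node, "medial_rotation"] == pytest.approx(pos)
            assert sums.loc[node, "lateral_rotation"] == pytest.approx(neg)
            # conservation: the two directions partition sum(|ACE|)
            assert sums.loc[node].sum() == pytest.approx(
                np.abs(vals[:, j]).sum(), abs=1e-12
            )


class TestRatioSeries:
    def test_simple_ratio(self):
        sums = pd.DataFrame(
            {"extension": [2.0, 1.0], "flexion": [1.0, 1.0]}, index=["n1", "n2"]
        )
        r = ratio_series(sums, sums, "extension", "flexion")
        assert r["n1"] == pytest.approx(2.0)
        assert r["n2"] == pytest.approx(1.0)

    def test_zero_denominator_flagged_undefined(self):
        sums = pd.DataFrame(
            {"extension": [2.0], "flexion": [0.0]}, index=["n1"]
        )
        r = ratio_series(sums, sums, "extension", "flexion")
        assert np.isnan(r["n1"])

    def test_h3_uses_abduction_denominator(self, synthetic_ace_tables):
        from archolimb.tables import estimates_by_joint_dof

        est = {f"{j}_{d}": synthetic_ace_tables[f]
               for f, (j, d) in
               __import__("archolimb").tables.FAMILIES.items()}
        r = hypothesis_ratio(est, "H3")
        med = sum_by_action(est["hip_LAR"], "hip", "LAR")["medial_rotation"]
        abd = sum_by_action(est["hip_ABAD"], "hip", "ABAD")["abduction"]
        assert np.allclose(r.to_numpy(), (med / abd).to_numpy())


class TestInternodalChanges:
    def test_constant_series_has_no_flags(self):
        s = pd.Series(2.0, index=NODES, name="flat")
        rep = internodal_changes(s)
        assert (rep.internodal["pct_change"] == 0).all()
        assert not rep.internodal["reliable"].any()
        assert rep.overall_pct == 0.0

    def test_25_percent_drop_is_reliable(self):
        s = pd.Series(2.0, index=NODES, name="x")
        s["Dinosauromorpha"] = 1.5
        rep = internodal_changes(s)
        step = rep.internodal.set_index("to").loc["Dinosauromorpha"]
        assert step["pct_change"] == pytest.approx(-25.0)
        assert step["reliable"] and step["notable"]

    def test_single_engineered_reliable_step(self):
        vals = np.full(len(NODES), 1.0)
        i = NODES.index("Coelurosauria")
        vals[i:] = 0.78  # one -22% step, then flat
        s = pd.Series(vals, index=NODES, name="x")
        rep = internodal_changes(s)
        reliable = rep.internodal[rep.internodal["reliable"]]
        assert len(reliable) == 1
        assert reliable.iloc[0]["to"] == "Coelurosauria"
        assert reliable.iloc[0]["pct_change"] == pytest.approx(-22.0)

    def test_ten_percent_is_notable_not_reliable(self):
        s = pd.Series(1.0, index=NODES, name="x")
        for n in NODES[NODES.index("Avialae"):]:
            s[n] = 1.10
        rep = internodal_changes(s)
        step = rep.internodal.set_index("to").loc["Avialae"]
        assert step["notable"] and not step["reliable"]

    def test_side_branch_reported_separately(self):
        s = pd.Series(np.linspace(1, 2, len(NODES)), index=NODES, name="x")
        rep = internodal_changes(s)
        assert list(rep.off_line["to"]) == ["Dromaeosauridae"]
        assert rep.off_line.iloc[0]["from"] == "Eumaniraptora"
        assert "Dromaeosauridae" not in set(rep.internodal["to"])

    def test_overall_change_is_first_to_last(self):
        s = pd.Series(1.0, index=NODES, name="x")
        s["Archosauria"], s["Phasianidae"] = 2.0, 1.0
        assert internodal_changes(s).overall_pct == pytest.approx(-50.0)


class TestSwitches:
    def test_constant_sign_no_events(self):
        df = table({"m": -np.ones(len(NODES))})
        assert detect_switches(df).empty

    def test_double_switch(self):
        vals = np.ones(len(NODES))
        vals[3:6] = -1
        df = table({"m": vals})
        events = detect_switches(df)
        assert len(events) == 2
        assert list(events["node"]) == [NODES[3], NODES[6]]

    def test_zero_takes_nearer_nonzero_sign(self):
        vals = np.array([1.0, 1.0, 0.0, -1.0, -1.0] + [-1.0] * (len(NODES) - 5))
        df = table({"m": vals})
        events = detect_switches(df)
        # zero at index 2 inherits an adjacent sign; exactly one switch
        assert len(events) == 1

    def test_scale_invariance(self, rng):
        vals = rng.normal(size=(5, len(NODES)))
        df = pd.DataFrame(vals, index=list("abcde"), columns=NODES)
        e1 = detect_switches(df)
        e2 = detect_switches(df * 7.3)
        pd.testing.assert_frame_equal(e1, e2)


class TestExtrema:
    def test_monotone_series_peaks_at_ends(self):
        df = table({"m": np.linspace(-1.0, -0.1, len(NODES))})
        row = detect_extrema(df).iloc[0]
        assert row["peak_node"] == NODES[0]
        assert row["min_node"] == NODES[-1]
        assert not row["switches"]

    def test_constant_series_ties_to_first_node(self):
        df = table({"m": np.full(len(NODES), 0.4)})
        row = detect_extrema(df).iloc[0]
        assert row["peak_node"] == NODES[0] and row["peak_tie"]
        assert row["min_node"] == NODES[0] and row["min_tie"]

    def test_switching_muscle_reports_both_peaks_no_minimum(self):
        vals = np.linspace(-1.0, 1.0, len(NODES))
        df = table({"m": vals})
        row = detect_extrema(df).iloc[0]
        assert row["switches"]
        assert row["min_node"] is None
        assert row["peak_node_negative"] == NODES[0]
        assert row["peak_node_positive"] == NODES[-1]

    def test_random_matches_argmax_brute_force(self, rng):
        vals = rng.normal(size=(8, len(NODES)))
        df = pd.DataFrame(vals, index=[f"m{i}" for i in range(8)], columns=NODES)
        out = detect_extrema(df).set_index("mtu")
        for i in range(8):
            assert out.loc[f"m{i}", "peak_node"] == NODES[
                int(np.argmax(np.abs(vals[i])))
            ]


class TestHypothesisReport:
    @staticmethod
    def _tables(h1_flat=True, h2_drop=True, h3_rise=True):
        k = np.linspace(0, 1, len(NODES))
        hip_fe = {"ext": -np.full(len(NODES), 0.5), "flx": np.full(len(NODES), 0.25)}
        if not h1_flat:
            hip_fe["ext"] = -0.5 * (1 - 0.45 * (k > 0.3))
        knee = {"flx": -0.4 * (1 - (0.6 if h2_drop else 0.0) * (k > 0.35)),
                "ext": np.full(len(NODES), 0.4)}
        lar = {"med": 0.1 * (1 + (1.5 if h3_rise else 0.0) * (k > 0.35)),
               "lat": -np.full(len(NODES), 0.2)}
        abad = {"abd": -np.full(len(NODES), 0.3), "add": np.full(len(NODES), 0.2)}
        return {
            "hip_FLEXEX": table(hip_fe),
            "knee_FLEXEX": table(knee),
            "hip_LAR": table(lar),
            "hip_ABAD": table(abad),
        }

    def test_flat_ratios_keep_h1_constant(self):
        rep = hypothesis_report(self._tables())
        assert rep["H1"] == "constant"

    def test_engineered_knee_drop_supports_h2(self):
        rep = hypothesis_report(self._tables())
        assert rep["H2"] == "supported"
        assert rep.reports["H2"].overall_pct < -20

    def test_engineered_medial_rise_supports_h3(self):
        rep = hypothesis_report(self._tables())
        assert rep["H3"] == "supported"

    def test_h1_rejected_on_reliable_step(self):
        rep = hypothesis_report(self._tables(h1_flat=False))
        assert rep["H1"] == "rejected"

    def test_no_change_fails_h2_h3(self):
        rep = hypothesis_report(self._tables(h2_drop=False, h3_rise=False))
        assert rep["H2"] == "not supported"
        assert rep["H3"] == "not supported"

    def test_scale_invariance_of_verdicts_and_flags(self):
        t1 = self._tables(h1_flat=False)
        t2 = {k: v * 3.7 for k, v in t1.items()}
        r1, r2 = hypothesis_report(t1), hypothesis_report(t2)
        assert r1.verdicts == r2.verdicts
        for h in HYPOTHESES:
            pd.testing.assert_frame_equal(
                r1.reports[h].internodal, r2.reports[h].internodal
            )
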