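"""IQR culling, node-support filter, calibration selection, full screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronoscreen.pl import SmoothingConfig
from chronoscreen.registry import FossilRecord
from chronoscreen.screening import (
    ReferenceNodeSet,
    ScreeningError,
    apply_node_support_filter,
    iqr_bounds,
    iqr_survivor_flags,
    load_node_definitions,
    load_reference_nodes,
    run_per_fossil_screen,
    select_calibrations,
)
from chronoscreen.simulate import (
    SimulationConfig,
    default_reference_nodes,
    simulate_fossils,
    simulate_tree,
)
from chronoscreen.trees import NodeQuery


def _sort_interpolate_quartiles(values):
    """Independent quantile oracle: sort + linear interpolation."""
    s = sorted(values)
    n = len(s)

    def q(p):
        pos = p * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return s[lo] + (pos - lo) * (s[hi] - s[lo])

    return q(0.25), q(0.75)


class TestIqrBounds:
    def test_hand_computed_example(self):
        assert iqr_bounds([1, 2, 3, 4]) == (1.75, 3.25)

    def test_identical_ages_collapse(self):
        q1, q3 = iqr_bounds([7.0] * 6)
        assert q1 == q3 == 7.0

    def test_fewer_than_four_ages_instructs_to_skip(self):
        with pytest.raises(ValueError, match="skip culling"):
            iqr_bounds([1.0, 2.0, 3.0])

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=4,
            max_size=60,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_sort_and_interpolate_oracle(self, values):
        assert iqr_bounds(values) == pytest.approx(
            _sort_interpolate_quartiles(values), abs=1e-7
        )

    def test_tukey_hinges_on_odd_length(self):
        # halves share the median: hinges are medians of [1,2,3] and [3,4,5]
        assert iqr_bounds([1, 2, 3, 4, 5], method="tukey") == (2.0, 4.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            iqr_bounds([1, 2, 3, 4], method="magic")


class TestSurvivorFlags:
    def _table(self, ages):
        return pd.DataFrame(
            {
                "record_id": [f"f{i}" for i in range(len(ages))],
                "status": "ok",
                "age_r": ages,
            }
        )

    def test_boundary_values_survive(self):
        """A run exactly at Q1 or Q3 is inside the interquartile region."""
        # five values: the quartile positions land exactly on members
        df = self._table([1.0, 2.0, 3.0, 4.0, 5.0])
        flags, iqr, reasons = iqr_survivor_flags(df, ["r"])
        assert iqr["r"] == (2.0, 4.0)
        by_age = dict(zip(df["age_r"], flags))
        assert by_age[2.0] and by_age[3.0] and by_age[4.0]
        assert not by_age[1.0] and not by_age[5.0]

    def test_strictly_outside_is_culled_with_reason(self):
        df = self._table([1.0, 2.0, 2.5, 3.0, 4.0])
        flags, _, reasons = iqr_survivor_flags(df, ["r"])
        assert reasons[~flags].str.contains("OUTLIER_AT_r").all()

    def test_failed_runs_excluded_from_quartiles_and_flagged(self):
        df = self._table([1.0, 2.0, 2.5, 3.0, 4.0])
        df.loc[5] = {"record_id": "bad", "status": "failed", "age_r": np.nan}
        flags, iqr, reasons = iqr_survivor_flags(df, ["r"])
        assert not flags.loc[5]
        assert reasons.loc[5] == "RUN_FAILED"
        # quartiles identical to the all-ok table
        assert iqr == iqr_survivor_flags(self._table([1, 2, 2.5, 3, 4]), ["r"])[1]


class TestNodeSupportFilter:
    def _fossils(self, node_counts):
        out = []
        k = 0
        for node, n in node_counts.items():
            for _ in range(n):
                out.append(FossilRecord(f"f{k}", "t", assigned_node=node, min_age=10, max_age=20))
                k += 1
        return out

    def test_four_survivors_all_kept(self):
        kept, removed = apply_node_support_filter(self._fossils({"node2": 4}))
        assert len(kept) == 4 and not removed

    def test_exactly_three_survivors_all_removed(self):
        kept, removed = apply_node_support_filter(self._fossils({"node2": 3}))
        assert not kept and len(removed) == 3

    def test_mixed_nodes_filtered_independently(self):
        kept, removed = apply_node_support_filter(
            self._fossils({"node2": 5, "node3": 2, "node4": 4})
        )
        assert {r.assigned_node for r in removed} == {"node3"}
        assert len(kept) == 9


class TestSelectCalibrations:
    defs = {
        f"node{k}": NodeQuery(f"A{k}", f"B{k}", f"node{k}") for k in (2, 3, 4)
    }

    def test_single_fossil_yields_its_own_minimum(self):
        recs = [FossilRecord("1", "t", assigned_node="node2", min_age=66.0, max_age=72.0)]
        (cal,) = select_calibrations(recs, self.defs)
        assert cal.min_age == 66.0 and np.isinf(cal.max_age)

    def test_max_of_mins_matches_brute_force(self):
        rng = np.random.default_rng(5)
        recs = [
            FossilRecord(
                f"f{i}", "t",
                assigned_node=f"node{rng.integers(2, 5)}",
                min_age=float(rng.uniform(10, 150)),
                max_age=200.0,
            )
            for i in range(12)
        ]
        cals = {c.node.label: c.min_age for c in select_calibrations(recs, self.defs)}
        brute = {}
        for r in recs:
            brute[r.assigned_node] = max(brute.get(r.assigned_node, 0), r.min_age)
        assert cals == brute

    def test_empty_survivor_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_calibrations([], self.defs)


class TestFullScreen:
    @pytest.fixture(scope="class")
    def screen_inputs(self):
        cfg = SimulationConfig(n_tips=8, seed=21, n_fossils=16)
        truth, obs = simulate_tree(cfg)
        fossils = simulate_fossils(truth, cfg)
        refs = ReferenceNodeSet(queries=default_reference_nodes(truth))
        return obs, fossils, refs

    def test_order_independence(self, screen_inputs):
        """Permuting the fossil input changes nothing in the report."""
        obs, fossils, refs = screen_inputs
        cfg = SmoothingConfig(restarts=1, seed=3)
        rep1 = run_per_fossil_screen(obs, fossils.records, fossils.node_defs, refs, cfg)
        shuffled = list(fossils.records)
        np.random.default_rng(0).shuffle(shuffled)
        rep2 = run_per_fossil_screen(obs, shuffled, fossils.node_defs, refs, cfg)
        pd.testing.assert_frame_equal(rep1.per_fossil, rep2.per_fossil)
        assert [(c.node.label, c.min_age) for c in rep1.selected] == [
            (c.node.label, c.min_age) for c in rep2.selected
        ]

    def test_expected_intervals_never_affect_survivors(self, screen_inputs):
        """Absurd expected intervals leave the survivor set untouched."""
        obs, fossils, refs = screen_inputs
        cfg = SmoothingConfig(restarts=1, seed=3)
        rep_plain = run_per_fossil_screen(obs, fossils.records, fossils.node_defs, refs, cfg)
        absurd = ReferenceNodeSet(
            queries=list(refs.queries),
            expected={lab: (1e6, 2e6) for lab in refs.labels},
        )
        rep_absurd = run_per_fossil_screen(obs, fossils.records, fossils.node_defs, absurd, cfg)
        pd.testing.assert_series_equal(
            rep_plain.per_fossil["survivor"], rep_absurd.per_fossil["survivor"]
        )

    def test_every_excluded_fossil_carries_a_reason(self, screen_inputs):
        obs, fossils, refs = screen_inputs
        rep = run_per_fossil_screen(
            obs, fossils.records, fossils.node_defs, refs, SmoothingConfig(restarts=1, seed=3)
        )
        excluded = rep.per_fossil[~rep.per_fossil["survivor"]]
        assert (excluded["reasons"] != "").all()
        assert rep.metadata["n_attempted"] == len(fossils.records)

    def test_single_fossil_population_skips_culling(self, screen_inputs, caplog):
        obs, fossils, refs = screen_inputs
        with caplog.at_level("WARNING"):
            rep = run_per_fossil_screen(
                obs, fossils.records[:1], fossils.node_defs, refs,
                SmoothingConfig(restarts=1, seed=3),
            )
        assert len(rep.per_fossil) == 1
        assert not rep.metadata["culling_applied"]
        assert "culling" in caplog.text.lower()

    def test_unassigned_fossils_rejected(self, screen_inputs):
        obs, fossils, refs = screen_inputs
        bad = [FossilRecord("u1", "t", min_age=10, max_age=20)]
        with pytest.raises(ScreeningError, match="unassigned"):
            run_per_fossil_screen(obs, bad, fossils.node_defs, refs)

    def test_all_runs_failing_raises_with_diagnostics(self, screen_inputs):
        obs, fossils, refs = screen_inputs
        # min > max makes every per-fossil constraint unconstructible
        bad = [
            FossilRecord(f"b{i}", "t", assigned_node="node2", min_age=50, max_age=10)
            for i in range(3)
        ]
        with pytest.raises(ScreeningError, match="failed"):
            run_per_fossil_screen(obs, bad, fossils.node_defs, refs)


def test_reference_node_set_requires_exactly_three():
    q = NodeQuery("A", "B", "x")
    with pytest.raises(ValueError, match="three"):
        ReferenceNodeSet(queries=[q, q])


def test_config_table_loaders(tmp_path):
    nodes = tmp_path / "nodes.csv"
    pd.DataFrame(
        {"node_label": ["node2"], "taxonA": ["A"], "taxonB": ["B"]}
    ).to_csv(nodes, index=False)
    defs = load_node_definitions(nodes)
    assert defs["node2"].taxon_a == "A"

    refs = tmp_path / "refs.csv"
    pd.DataFrame(
        {
            "node_label": ["r1", "r2", "r3"],
            "taxonA": ["A", "C", "E"],
            "taxonB": ["B", "D", "F"],
            "expected_min": [1.0, np.nan, 3.0],
            "expected_max": [2.0, np.nan, 4.0],
        }
    ).to_csv(refs, index=False)
    rs = load_reference_nodes(refs)
    assert rs.labels == ["r1", "r2", "r3"]
    assert rs.expected == {"r1": (1.0, 2.0), "r3": (3.0, 4.0)}
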