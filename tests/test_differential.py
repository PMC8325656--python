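"""Group-consensus differential abundance, concordance, and Venn set logic."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, strategies as st

from evcargo.config import AnalysisThresholds
from evcargo.differential import (
    BiomarkerReport,
    concordance,
    differential_group,
    differential_pairwise,
    venn_proteins,
)

from conftest import make_ratio_matrix


def ev_matrix(values: dict[str, dict[str, float]], fractions=("EV",)):
    """Merged ratio matrix from {line: {protein: value}} replicated per fraction."""
    return make_ratio_matrix(
        {(line, fr): vals for line, vals in values.items() for fr in fractions}
    )


class TestPairwise:
    @pytest.mark.parametrize(
        "delta, direction",
        [(1.2, "increased"), (-0.58, "neither"), (0.59, "increased"),
         (-0.6, "decreased"), (0.0, "neither"), (np.nan, "neither")],
    )
    def test_threshold_and_boundary(self, delta, direction):
        rm = ev_matrix({"A": {"p": float(delta) if not np.isnan(delta) else np.nan},
                        "B": {"p": 0.0}})
        res = differential_pairwise(rm, "A", "B")
        assert res.table.loc["p", "direction"] == direction
        assert bool(res.table.loc["p", "missing"]) == bool(np.isnan(delta))

    def test_toy_pair_matches_sign_threshold_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 5)
        b = rng.normal(0, 1, 5)
        rm = ev_matrix(
            {"A": {f"p{i}": a[i] for i in range(5)}, "B": {f"p{i}": b[i] for i in range(5)}}
        )
        res = differential_pairwise(rm, "A", "B")
        for i in range(5):
            d = a[i] - b[i]
            expected = "increased" if d > 0.58 else "decreased" if d < -0.58 else "neither"
            assert res.table.loc[f"p{i}", "direction"] == expected

    def test_unknown_line_rejected(self):
        rm = ev_matrix({"A": {"p": 1.0}, "B": {"p": 0.0}})
        with pytest.raises(KeyError):
            differential_pairwise(rm, "A", "Z")


class TestGroupConsensus:
    def test_all_six_pairs_passing_gives_increased(self):
        rm = ev_matrix(
            {"a1": {"p": 2.0}, "a2": {"p": 1.8}, "b1": {"p": 0.5}, "b2": {"p": 0.3},
             "b3": {"p": 0.0}}
        )
        res = differential_group(rm, ["a1", "a2"], ["b1", "b2", "b3"])
        assert res.table.loc["p", "direction"] == "increased"

    def test_one_failing_pair_breaks_consensus(self):
        # five of six pairwise deltas pass; a1 vs b1 is only +0.1
        rm = ev_matrix(
            {"a1": {"p": 1.0}, "a2": {"p": 3.0}, "b1": {"p": 0.9}, "b2": {"p": 0.0},
             "b3": {"p": -0.5}}
        )
        res = differential_group(rm, ["a1", "a2"], ["b1", "b2", "b3"])
        assert res.table.loc["p", "direction"] == "neither"

    def test_any_missing_pairwise_value_gives_neither(self):
        rm = ev_matrix({"a1": {"p": 5.0}, "b1": {"p": 0.0}, "b2": {"p": np.nan}})
        res = differential_group(rm, ["a1"], ["b1", "b2"])
        assert res.table.loc["p", "direction"] == "neither"
        assert bool(res.table.loc["p", "missing"])

    def test_matches_brute_force_conjunction_oracle(self):
        rng = np.random.default_rng(9)
        lines = ["a1", "a2", "b1", "b2", "b3"]
        vals = {l: {f"p{i}": rng.normal(0, 1.2) for i in range(40)} for l in lines}
        rm = ev_matrix(vals)
        res = differential_group(rm, ["a1", "a2"], ["b1", "b2", "b3"])
        thr = AnalysisThresholds()
        for i in range(40):
            deltas = [vals[a][f"p{i}"] - vals[b][f"p{i}"]
                      for a, b in product(["a1", "a2"], ["b1", "b2", "b3"])]
            if all(d > thr.fc_log2 for d in deltas):
                expected = "increased"
            elif all(d < -thr.fc_log2 for d in deltas):
                expected = "decreased"
            else:
                expected = "neither"
            assert res.table.loc[f"p{i}", "direction"] == expected

    def test_antisymmetry_and_subset_of_pairwise(self):
        rng = np.random.default_rng(13)
        lines = ["a1", "a2", "b1", "b2"]
        rm = ev_matrix({l: {f"p{i}": rng.normal(0, 1.5) for i in range(60)} for l in lines})
        ab = differential_group(rm, ["a1", "a2"], ["b1", "b2"])
        ba = differential_group(rm, ["b1", "b2"], ["a1", "a2"])
        assert ab.proteins_with("increased") == ba.proteins_with("decreased")
        assert ab.proteins_with("decreased") == ba.proteins_with("increased")
        for a, b in product(["a1", "a2"], ["b1", "b2"]):
            pairwise = differential_pairwise(rm, a, b)
            assert ab.proteins_with("increased") <= pairwise.proteins_with("increased")

    def test_group_mean_alternative(self):
        rm = ev_matrix({"a1": {"p": 1.0}, "a2": {"p": 0.4}, "b1": {"p": 0.0}})
        # all-pairs fails (0.4 delta below threshold) but the mean (0.7) passes
        assert differential_group(rm, ["a1", "a2"], ["b1"]).table.loc["p", "direction"] == "neither"
        mean_res = differential_group(rm, ["a1", "a2"], ["b1"], method="group_mean")
        assert mean_res.table.loc["p", "direction"] == "increased"

    def test_overlapping_or_empty_groups_rejected(self):
        rm = ev_matrix({"a1": {"p": 1.0}, "b1": {"p": 0.0}})
        with pytest.raises(ValueError, match="overlap"):
            differential_group(rm, ["a1"], ["a1", "b1"])
        with pytest.raises(ValueError, match="non-empty"):
            differential_group(rm, [], ["b1"])


class TestConcordance:
    @pytest.mark.parametrize(
        "cl_delta, ev_delta, concordant",
        [(1.0, 1.0, True), (-1.0, -1.0, True), (1.0, 0.0, False),
         (1.0, -1.0, False), (0.0, 0.0, False)],
    )
    def test_direction_matching(self, cl_delta, ev_delta, concordant):
        rm = make_ratio_matrix(
            {
                ("A", "CL"): {"p": cl_delta}, ("A", "EV"): {"p": ev_delta},
                ("HK2", "CL"): {"p": 0.0}, ("HK2", "EV"): {"p": 0.0},
            }
        )
        assert ("p" in concordance(rm, "A")) == concordant

    def test_equals_intersection_of_direction_matched_calls(self):
        rng = np.random.default_rng(21)
        cols = {}
        for line in ("A", "HK2"):
            for fr in ("CL", "EV"):
                cols[(line, fr)] = {f"p{i}": rng.normal(0, 1.2) for i in range(30)}
        rm = make_ratio_matrix(cols)
        got = concordance(rm, "A")
        cl = differential_pairwise(rm, "A", "HK2", "CL").table["direction"]
        ev = differential_pairwise(rm, "A", "HK2", "EV").table["direction"]
        expected = frozenset(
            p for p in cl.index if cl[p] == ev[p] and cl[p] != "neither"
        )
        assert got == expected


class TestVennProteins:
    def test_hand_worked_three_set_example(self):
        report = BiomarkerReport(
            {
                "benign": frozenset("abc"),
                "ccRCC": frozenset("bcd"),
                "pRCC": frozenset("ce"),
            }
        )
        assert report.unique_to("benign") == frozenset("a")
        assert report.unique_to("ccRCC") == frozenset("d")
        assert report.unique_to("pRCC") == frozenset("e")
        assert report.shared_by_all() == frozenset("c")

    def test_identical_sets_all_shared_and_disjoint_sets_all_unique(self):
        same = BiomarkerReport({"x": frozenset("ab"), "y": frozenset("ab")})
        assert same.shared_by_all() == frozenset("ab")
        assert same.unique_to("x") == frozenset()
        disjoint = BiomarkerReport({"x": frozenset("ab"), "y": frozenset("cd")})
        assert disjoint.unique_to("x") == frozenset("ab")
        assert disjoint.regions[frozenset(["x", "y"])] == frozenset()

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans()), min_size=1, max_size=40
        )
    )
    def test_regions_partition_the_union(self, memberships):
        detected = {
            h: frozenset(f"p{i}" for i, row in enumerate(memberships) if row[j])
            for j, h in enumerate(("benign", "ccRCC", "pRCC"))
        }
        report = BiomarkerReport(detected)
        regions = list(report.regions.values())
        union = frozenset().union(*detected.values())
        assert frozenset().union(*regions) == union
        assert sum(len(r) for r in regions) == len(union)  # pairwise disjoint

    def test_per_histology_intersection_over_lines(self):
        detection = {
            "l1": frozenset("abc"), "l2": frozenset("ab"),  # benign -> {a, b}
            "l3": frozenset("bc"),                            # ccRCC -> {b, c}
        }
        histology = {"l1": "benign", "l2": "benign", "l3": "ccRCC"}
        report = venn_proteins(detection, histology)
        assert report.detected["benign"] == frozenset("ab")
        assert report.unique_to("benign") == frozenset("a")
        assert report.unique_to("ccRCC") == frozenset("c")

    def test_histology_without_lines_rejected(self):
        with pytest.raises(ValueError, match="no cell line"):
            venn_proteins({"l1": frozenset("a")}, {"l1": "benign", "l2": "ccRCC"})
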