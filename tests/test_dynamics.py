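"""Clonotype tracking, Fisher-exact expansion calls, clonal space and flow."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from tcrtme.dynamics import (
    circulating_itcs,
    classify_dynamics,
    clonal_space,
    clonotype_fraction,
    fisher_exact_two_sided,
    flow_summary,
    frequency_rank_bins,
    identify_itcs,
    make_clone_pairs,
    subset_circulating,
    summarize_circulating,
)
from tcrtme.errors import ConsistencyError, DataError, UsageError
from tcrtme.synthetic import CohortConfig, generate_paired_tumor_repertoires

from conftest import make_table


def _tables(pre_counts, post_counts, pre_cdr3, post_cdr3):
    pre = make_table(pre_counts, cdr3=pre_cdr3, patient="P01",
                     compartment="tumor", timepoint="baseline")
    post = make_table(post_counts, cdr3=post_cdr3, patient="P01",
                      compartment="tumor", timepoint="post_surgery")
    return pre, post


class TestItcIdentification:
    def test_disjoint_tables_empty(self):
        pre, post = _tables([1, 1], [1, 1], ["CASSAF", "CASSBF"], ["CASSCF", "CASSDF"])
        assert identify_itcs(pre, post) == set()

    def test_identity(self):
        pre, post = _tables([2, 3], [5, 1], ["CASSAF", "CASSBF"], ["CASSAF", "CASSBF"])
        assert identify_itcs(pre, post) == pre.key_set()

    def test_partial_overlap(self):
        pre, post = _tables(
            [1, 1, 1], [1, 1, 1],
            ["CASSAF", "CASSBF", "CASSCF"], ["CASSBF", "CASSCF", "CASSDF"],
        )
        keys = identify_itcs(pre, post)
        assert {k[0] for k in keys} == {"CASSBF", "CASSCF"}

    def test_mismatched_patients_rejected(self):
        pre = make_table([1], patient="P01")
        post = make_table([1], patient="P02")
        with pytest.raises(UsageError, match="patient"):
            identify_itcs(pre, post)


class TestClonalSpace:
    def test_full_and_empty_key_sets(self):
        table = make_table([5, 3, 2])
        assert clonal_space(table.key_set(), table) == pytest.approx(1.0)
        assert clonotype_fraction(table.key_set(), table) == pytest.approx(1.0)
        assert clonal_space(set(), table) == 0.0
        assert clonotype_fraction(set(), table) == 0.0

    def test_hand_sum(self):
        table = make_table([5, 3, 2], cdr3=["CASSAF", "CASSBF", "CASSCF"])
        keys = {("CASSAF", "TRBV1", "TRBJ1"), ("CASSBF", "TRBV1", "TRBJ1")}
        assert clonal_space(keys, table) == pytest.approx(0.8)
        assert clonotype_fraction(keys, table) == pytest.approx(2 / 3)


class TestFisher:
    def test_identical_margins_p_one(self):
        assert fisher_exact_two_sided(10, 1000, 10, 1000) == pytest.approx(1.0)

    def test_strong_expansion_significant(self):
        p = fisher_exact_two_sided(5, 1000, 50, 1000)
        assert p < 1e-6

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(150):
            n1, n2 = rng.integers(5, 200, size=2)
            a = int(rng.integers(0, n1 + 1))
            b = int(rng.integers(0, n2 + 1))
            ours = fisher_exact_two_sided(a, n1, b, n2)
            ref = scipy_fisher([[a, n1 - a], [b, n2 - b]])[1]
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            fisher_exact_two_sided(5, 3, 1, 10)


class TestClassifyDynamics:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["clonotype", "count_pre", "total_pre",
                                           "count_post", "total_post"])

    def test_unchanged_new_lost_and_differential(self):
        pairs = self._pairs([
            ("A", 10, 1000, 10, 1000),
            ("B", 5, 1000, 50, 1000),
            ("C", 0, 1000, 7, 1000),
            ("D", 7, 1000, 0, 1000),
        ])
        out = classify_dynamics(pairs).set_index("clonotype")
        assert out.loc["A", "category"] == "unchanged"
        assert out.loc["A", "p_value"] == pytest.approx(1.0)
        assert not out.loc["A", "differential"]
        assert out.loc["B", "category"] == "expanded"
        assert out.loc["B", "differential"]
        assert out.loc["C", "category"] == "new" and np.isnan(out.loc["C", "p_value"])
        assert out.loc["D", "category"] == "lost"
        assert not out.loc[["C", "D"], "differential"].any()

    def test_direction_without_significance(self):
        out = classify_dynamics(self._pairs([("A", 10, 1000, 12, 1000)]))
        assert out.loc[0, "category"] == "expanded"
        assert not out.loc[0, "differential"]

    def test_bh_adjustment_is_more_conservative(self):
        rows = [(f"c{i}", 10 + i, 5000, 14 + i, 5000) for i in range(40)]
        rows.append(("hit", 10, 5000, 60, 5000))
        raw = classify_dynamics(self._pairs(rows))
        adj = classify_dynamics(self._pairs(rows), adjust=True)
        assert adj["differential"].sum() <= raw["differential"].sum()
        assert adj.set_index("clonotype").loc["hit", "differential"]

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            classify_dynamics(self._pairs([("A", -1, 10, 2, 10)]))


class TestRankBins:
    def test_examples_and_partition(self):
        assert frequency_rank_bins(make_table([10])) == {0: 1}
        table = make_table([3, 97], cdr3=["CASSAF", "CASSBF"])  # freqs 0.03, 0.97
        bins = frequency_rank_bins(table)
        assert bins == {-2: 1, -1: 1}
        big = make_table(list(range(1, 30)))
        assert sum(frequency_rank_bins(big).values()) == 29


class TestCirculating:
    def test_absent_everywhere(self):
        blood = [make_table([1], cdr3=["CASSZF"], compartment="blood", timepoint=tp)
                 for tp in ("baseline", "W3", "W6")]
        out = circulating_itcs({("CASSAF", "TRBV1", "TRBJ1")}, blood)
        assert (out["n_circulating"] == 0).all()
        assert (out["clonal_space"] == 0.0).all()

    def test_single_itc_at_w6_only(self):
        itc = ("CASSAF", "TRBV1", "TRBJ1")
        blood = [
            make_table([10], cdr3=["CASSZF"], compartment="blood", timepoint="baseline"),
            make_table([10], cdr3=["CASSYF"], compartment="blood", timepoint="W3"),
            make_table([1, 9], cdr3=["CASSAF", "CASSZF"], compartment="blood", timepoint="W6"),
        ]
        out = circulating_itcs({itc}, blood)
        assert out["clonal_space"].tolist() == pytest.approx([0.0, 0.0, 0.1])

    def test_empty_series_rejected(self):
        with pytest.raises(UsageError):
            circulating_itcs(set(), [])

    def test_cohort_summary_mean_sem(self):
        per_patient = {
            "P01": pd.DataFrame({"timepoint": ["baseline", "W6"],
                                 "n_circulating": [1, 3], "clonal_space": [0.1, 0.3]}),
            "P02": pd.DataFrame({"timepoint": ["baseline", "W6"],
                                 "n_circulating": [1, 1], "clonal_space": [0.2, 0.4]}),
        }
        out = summarize_circulating(per_patient).set_index("timepoint")
        assert out.loc["W6", "mean_space"] == pytest.approx(0.35)
        assert out.loc["W6", "sem_space"] == pytest.approx(np.std([0.3, 0.4], ddof=1) / np.sqrt(2))

    def test_subset_circulating_set_algebra(self):
        classified = pd.DataFrame({
            "clonotype": [("CASSAF", "TRBV1", "TRBJ1"), ("CASSBF", "TRBV1", "TRBJ1")],
            "category": ["expanded", "contracted"],
        })
        blood = [make_table([1, 1], cdr3=["CASSAF", "CASSXF"],
                            compartment="blood", timepoint="baseline")]
        out = subset_circulating(classified, blood)
        assert out["expanded"]["n_circulating"].tolist() == [1]
        assert out["contracted"]["n_circulating"].tolist() == [0]
        assert out["new"]["n_circulating"].tolist() == [0]


class TestFlowSummary:
    def test_all_new(self):
        pre, post = _tables([1], [1, 1], ["CASSAF"], ["CASSBF", "CASSCF"])
        classified = classify_dynamics(make_clone_pairs(pre, post))
        out = flow_summary(post, classified).set_index("category")
        assert out.loc["new", "clonotype_fraction"] == pytest.approx(1.0)
        assert out.loc["new", "clonal_space"] == pytest.approx(1.0)

    def test_fractions_partition_on_synthetic_pair(self):
        cfg = CohortConfig(n_clones=120, repertoire_depth=20_000)
        pre, post, _ = generate_paired_tumor_repertoires(cfg, "well", seed=6)
        classified = classify_dynamics(make_clone_pairs(pre, post))
        out = flow_summary(post, classified)
        assert out["clonotype_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert out["clonal_space"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_uncovered_keys_rejected(self):
        pre, post = _tables([1], [1, 1], ["CASSAF"], ["CASSAF", "CASSBF"])
        classified = classify_dynamics(make_clone_pairs(pre, post)).iloc[:1]
        with pytest.raises(ConsistencyError):
            flow_summary(post, classified)

    def test_planted_fractions_recovered(self):
        # ITC categories + new clones should recover the planted composition
        cfg = CohortConfig(n_clones=200, repertoire_depth=100_000)
        pre, post, truth = generate_paired_tumor_repertoires(cfg, "well", seed=17)
        classified = classify_dynamics(make_clone_pairs(pre, post))
        out = flow_summary(post, classified).set_index("category")
        truth_new = sum(1 for k in post.key_set() if truth.clone_category[k] == "new")
        assert out.loc["new", "clonotype_fraction"] == pytest.approx(
            truth_new / len(post.key_set()), abs=1e-9
        )
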