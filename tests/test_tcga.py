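"""Isoform aggregation, RPM, zero-replacement log2 and group testing."""

import numpy as np
import pandas as pd
import pytest

from _oracles import kruskal_h
from mirmeta.tcga import (
    aggregate_isoforms,
    kruskal_wallis,
    log2_with_zero_replacement,
    pairwise_strata_tests,
    rpm_normalize,
    two_group_validation,
)
from mirmeta.diffexpr import rank_sum_test


def _records(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "mature_accession", "read_count"]
    )


IDENTITY = {"MIMAT-A": "MIMAT-A", "MIMAT-B": "MIMAT-B"}


class TestAggregateIsoforms:
    def test_isoform_records_sum_per_accession(self):
        rec = _records([("S1", "MIMAT-A", 10), ("S1", "MIMAT-A", 5)])
        matrix, unmapped = aggregate_isoforms(rec, IDENTITY)
        assert matrix.at["MIMAT-A", "S1"] == 15
        assert len(unmapped) == 0

    def test_unmapped_accessions_excluded_and_reported(self):
        rec = _records(
            [("S1", "MIMAT-A", 10), ("S1", "MIMAT-OLD", 7),
             ("S2", "MIMAT-OLD", 3)]
        )
        matrix, unmapped = aggregate_isoforms(rec, IDENTITY)
        assert "MIMAT-OLD" not in matrix.index
        row = unmapped.set_index("accession").loc["MIMAT-OLD"]
        assert row["n_records"] == 2 and row["total_reads"] == 10

    def test_release_map_translates_old_ids(self):
        rec = _records([("S1", "MIMAT-OLD", 4), ("S1", "MIMAT-A", 6)])
        matrix, _ = aggregate_isoforms(rec, {"MIMAT-OLD": "MIMAT-A",
                                             "MIMAT-A": "MIMAT-A"})
        assert matrix.at["MIMAT-A", "S1"] == 10

    def test_empty_records(self):
        matrix, unmapped = aggregate_isoforms(_records([]), {})
        assert matrix.empty and unmapped.empty

    def test_negative_count_errors(self):
        with pytest.raises(ValueError, match="negative"):
            aggregate_isoforms(_records([("S1", "MIMAT-A", -1)]), IDENTITY)

    def test_read_conservation_per_sample(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"S{s}", f"MIMAT-{i}", int(rng.integers(0, 50)))
            for s in range(4)
            for i in range(10)
            for _ in range(int(rng.integers(1, 4)))
        ]
        rec = _records(rows)
        rel = {f"MIMAT-{i}": f"MIMAT-{i}" for i in range(10)}
        matrix, _ = aggregate_isoforms(rec, rel)
        expected = rec.groupby("sample_id")["read_count"].sum()
        np.testing.assert_array_equal(
            matrix.sum(axis=0).loc[expected.index].to_numpy(),
            expected.to_numpy(),
        )


class TestRPM:
    def test_simple_ratio(self):
        counts = pd.DataFrame({"S1": [2000.0, 1998000.0]}, index=["a", "b"])
        rpm = rpm_normalize(counts)
        assert rpm.at["a", "S1"] == pytest.approx(1000.0)

    def test_single_mirna_sample(self):
        counts = pd.DataFrame({"S1": [123.0]}, index=["a"])
        assert rpm_normalize(counts).at["a", "S1"] == pytest.approx(1e6)

    def test_column_sums_are_one_million(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(50, 8)).astype(float))
        counts.iloc[0] += 1  # no zero-total column
        np.testing.assert_allclose(
            rpm_normalize(counts).sum(axis=0), 1e6, atol=1e-6
        )

    def test_zero_total_sample_named(self):
        counts = pd.DataFrame({"GOOD": [5.0], "BAD": [0.0]}, index=["a"])
        with pytest.raises(ValueError, match="BAD"):
            rpm_normalize(counts)


class TestLog2ZeroReplacement:
    def test_global_minimum_replacement(self):
        rpm = pd.DataFrame([[0.0, 4.0], [2.0, 8.0]])
        out = log2_with_zero_replacement(rpm)
        np.testing.assert_allclose(out.to_numpy(), [[1.0, 2.0], [1.0, 3.0]])

    def test_no_zeros_is_plain_log2(self):
        rpm = pd.DataFrame([[1.0, 4.0], [2.0, 8.0]])
        out = log2_with_zero_replacement(rpm)
        np.testing.assert_allclose(out.to_numpy(), np.log2(rpm.to_numpy()))

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            log2_with_zero_replacement(pd.DataFrame([[0.0]]))

    def test_per_mirna_mode_uses_row_minimum(self):
        rpm = pd.DataFrame([[0.0, 4.0], [2.0, 8.0]])
        out = log2_with_zero_replacement(rpm, per_mirna=True)
        np.testing.assert_allclose(out.to_numpy(), [[2.0, 2.0], [1.0, 3.0]])

    def test_output_always_finite(self):
        rng = np.random.default_rng(9)
        rpm = pd.DataFrame(rng.poisson(2, size=(30, 10)).astype(float))
        rpm.iloc[0, 0] = 1.0
        out = log2_with_zero_replacement(rpm)
        assert np.isfinite(out.to_numpy()).all()


class TestTwoGroupValidation:
    def test_subset_of_one_gives_q_equal_p(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(5, 1, size=(3, 12)),
                         index=["a", "b", "c"],
                         columns=[f"s{i}" for i in range(12)])
        groups = {f"s{i}": ("tumor" if i < 8 else "normal") for i in range(12)}
        res = two_group_validation(m, groups, ["a"])
        assert res.at["a", "q"] == pytest.approx(res.at["a", "p"])

    def test_missing_subset_accession_named(self):
        m = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["a"])
        with pytest.raises(ValueError, match="missing-acc"):
            two_group_validation(
                m, {"s1": "tumor", "s2": "normal"}, ["missing-acc"]
            )

    def test_direction_follows_median_difference(self):
        cols = [f"s{i}" for i in range(10)]
        groups = {c: ("tumor" if i < 6 else "normal")
                  for i, c in enumerate(cols)}
        m = pd.DataFrame(
            [[1, 1, 1, 1, 1, 1, 5, 5, 5, 5], [9, 9, 9, 9, 9, 9, 2, 2, 2, 2]],
            index=["dn", "up"], columns=cols, dtype=float,
        )
        res = two_group_validation(m, groups, ["dn", "up"])
        assert res.at["dn", "direction"] == "down"
        assert res.at["up", "direction"] == "up"


class TestKruskalWallis:
    def test_all_identical_values(self):
        values = {f"s{i}": 3.0 for i in range(6)}
        strata = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        h, p = kruskal_wallis(values, strata)
        assert h == 0.0 and p == 1.0

    def test_three_strata_matches_rank_formula(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        values, strata = {}, {}
        for g, vals in enumerate(groups):
            for k, v in enumerate(vals):
                values[f"s{g}{k}"] = v
                strata[f"s{g}{k}"] = f"g{g}"
        h, _ = kruskal_wallis(values, strata)
        assert h == pytest.approx(kruskal_h(groups), abs=1e-10)

    def test_two_groups_agree_with_wilcoxon_approximation(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n1, n2 = rng.integers(25, 60, size=2)
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.3, 1, n2)
            values = {f"a{i}": v for i, v in enumerate(x)}
            values.update({f"b{i}": v for i, v in enumerate(y)})
            strata = {k: k[0] for k in values}
            _, p_kw = kruskal_wallis(values, strata)
            p_w = rank_sum_test(x, y)
            assert abs(p_kw - p_w) < 0.01

    def test_single_stratum_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            kruskal_wallis({"s1": 1.0, "s2": 2.0}, {"s1": "a", "s2": "a"})


class TestPairwiseStrata:
    def _data(self, shift_by_stratum, n_per=12, seed=0):
        rng = np.random.default_rng(seed)
        values, strata = {}, {}
        for stratum, shift in shift_by_stratum.items():
            for i in range(n_per):
                s = f"{stratum}-{i}"
                values[s] = shift + rng.normal(0, 0.5)
                strata[s] = stratum
        return values, strata

    def test_identical_strata_all_p_one(self):
        values = {f"{g}{i}": 1.0 for g in "abc" for i in range(4)}
        strata = {k: k[0] for k in values}
        out = pairwise_strata_tests(values, strata, "a")
        assert (out["p"] == 1.0).all()

    def test_two_strata_reduce_to_rank_sum(self):
        values, strata = self._data({"normal": 8.0, "t1": 6.0}, seed=4)
        out = pairwise_strata_tests(values, strata, "normal")
        assert len(out) == 1
        x = [v for k, v in values.items() if strata[k] == "normal"]
        y = [v for k, v in values.items() if strata[k] == "t1"]
        assert out.iloc[0]["p"] == pytest.approx(rank_sum_test(x, y))

    def test_reference_absent_errors(self):
        values, strata = self._data({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="reference"):
            pairwise_strata_tests(values, strata, "normal")

    def test_shifted_stratum_detected(self):
        # normal high, one stratum shifted -2, the others -1
        hits = 0
        for seed in range(20):
            values, strata = self._data(
                {"normal": 8.0, "shifted": 6.0, "o1": 7.0, "o2": 7.0},
                seed=seed,
            )
            out = pairwise_strata_tests(values, strata, "normal").set_index(
                ["stratum_a", "stratum_b"]
            )
            if (
                out.loc[("o1", "shifted"), "p"] < 0.05
                and out.loc[("o2", "shifted"), "p"] < 0.05
            ):
                hits += 1
        assert hits >= 18
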