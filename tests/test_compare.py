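"""Permutation testing, nodal difference maps, demographic t-tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import scnet.compare as compare_mod
from scnet import (
    Cohort,
    CohortSpec,
    betweenness_difference_map,
    demographics_ttest,
    generate_cohort,
    permutation_test,
)


def duplicated_group_cohort(n=12, p=10, seed=0) -> Cohort:
    """Group B is literally group A's data under different subject ids."""
    base = generate_cohort(
        CohortSpec(n_subjects_per_group=n, n_regions=p, n_blocks=2, seed=seed)
    )
    a_rows = base.data[base.data["group"] == "A"].copy()
    b_rows = a_rows.copy()
    b_rows["group"] = "B"
    b_rows["subject_id"] = [f"B{i:02d}" for i in range(n)]
    return Cohort(pd.concat([a_rows, b_rows], ignore_index=True), base.regions)


class TestPermutationTest:
    def test_identical_groups_yield_zero_observed_and_no_flags(self):
        cohort = duplicated_group_cohort()
        results = permutation_test(
            cohort, (0.2,), ("C_p", "L_p"), n_perm=50, seed=1
        )
        for r in results:
            assert r.observed == pytest.approx(0.0, abs=1e-12)
            assert not r.significant_increase and not r.significant_decrease

    def test_null_distribution_reproducible(self, null_cohort):
        r1 = permutation_test(null_cohort, (0.15,), ("C_p",), n_perm=30, seed=9)
        r2 = permutation_test(null_cohort, (0.15,), ("C_p",), n_perm=30, seed=9)
        assert np.array_equal(r1[0].null, r2[0].null)
        assert r1[0].observed == r2[0].observed

    def test_observed_and_null_share_one_code_path(self, null_cohort, monkeypatch):
        calls = {"n": 0}
        real = compare_mod.network_statistics

        def counting(*args, **kwargs):
            calls["n"] += 1
            return real(*args, **kwargs)

        monkeypatch.setattr(compare_mod, "network_statistics", counting)
        permutation_test(null_cohort, (0.15,), ("C_p",), n_perm=25, seed=0)
        assert calls["n"] == 26  # observed + every permutation

    def test_small_n_perm_refused(self, null_cohort):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(null_cohort, (0.15,), ("C_p",), n_perm=10, seed=0)

    def test_null_length_and_percentile_contract(self, null_cohort):
        r = permutation_test(null_cohort, (0.15,), ("C_p",), n_perm=40, seed=2)[0]
        assert r.null.shape == (40,)
        assert r.crit_low == np.percentile(r.null, 5)
        assert r.crit_high == np.percentile(r.null, 95)
        assert r.significant_increase == (r.observed > r.crit_high)
        assert r.significant_decrease == (r.observed < r.crit_low)

    def test_fast_permute_agrees_on_observed(self, null_cohort):
        slow = permutation_test(null_cohort, (0.15,), ("C_p",), 25, seed=3)[0]
        fast = permutation_test(
            null_cohort, (0.15,), ("C_p",), 25, seed=3, fast_permute=True
        )[0]
        assert np.isclose(slow.observed, fast.observed)
        assert fast.null.shape == (25,)

    def test_unknown_metric_rejected(self, null_cohort):
        with pytest.raises(ValueError, match="unknown metric"):
            permutation_test(null_cohort, (0.15,), ("eigenvector",), 25, seed=0)

    def test_permutation_pvalues_uniform_under_null(self):
        """Exchangeability: over repeated null cohorts the rank of the
        observed statistic in its own null is uniform (KS check)."""
        ranks = []
        for rep in range(40):
            cohort = generate_cohort(
                CohortSpec(n_subjects_per_group=14, n_regions=16, n_blocks=2,
                           seed=1000 + rep)
            )
            r = permutation_test(cohort, (0.2,), ("C_p",), n_perm=40,
                                 seed=rep)[0]
            ranks.append((r.null < r.observed).mean())
        _, p = sps.kstest(ranks, "uniform")
        assert p > 0.01


class TestBetweennessMap:
    def test_identical_groups_flag_nothing(self):
        cohort = duplicated_group_cohort()
        results = permutation_test(cohort, (0.2,), ("bc",), n_perm=40, seed=4)
        table = betweenness_difference_map(results, 0.2)
        assert set(table.columns) >= {"node", "observed_diff", "direction"}
        assert (table["direction"] == "none").all()

    def test_missing_sparsity_raises(self, null_cohort):
        results = permutation_test(null_cohort, (0.2,), ("bc",), n_perm=25, seed=5)
        with pytest.raises(ValueError, match="no 'bc'"):
            betweenness_difference_map(results, 0.11)

    def test_nodes_match_regions(self, null_cohort):
        results = permutation_test(null_cohort, (0.2,), ("bc",), n_perm=25, seed=6)
        table = betweenness_difference_map(results, 0.2)
        assert list(table["node"]) == null_cohort.regions


class TestDemographicsTTest:
    def test_gender_split_reference_value(self):
        """Dummy-coded 14/22 vs 15/21 must give p = 0.813 to 3 decimals."""
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(72)],
                "group": ["A"] * 36 + ["B"] * 36,
                "gender": [1] * 14 + [0] * 22 + [1] * 15 + [0] * 21,
            }
        )
        t, p = demographics_ttest(df, "gender")
        assert round(p, 3) == 0.813

    def test_identical_columns_give_t0_p1(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "group": ["A"] * 4 + ["B"] * 4,
                "age": [60, 61, 62, 63] * 2,
            }
        )
        t, p = demographics_ttest(df, "age")
        assert t == 0.0 and p == 1.0

    def test_hand_computed_pooled_t(self):
        """Pooled-variance oracle: A={1,2,3}, B={2,3,4} gives t=-1.2247."""
        df = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "group": ["A"] * 3 + ["B"] * 3,
                "x": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0],
            }
        )
        t, p = demographics_ttest(df, "x")
        assert np.isclose(t, -1.224744871391589)
        assert np.isclose(p, 2 * sps.t.sf(1.224744871391589, df=4))

    def test_categorical_column_dummy_coded(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "group": ["A"] * 4 + ["B"] * 4,
                "sex": ["M", "F", "M", "F", "M", "M", "M", "F"],
            }
        )
        t, _ = demographics_ttest(df, "sex")
        coded = df.assign(sex=(df["sex"] == "M").astype(float))
        t2, _ = demographics_ttest(coded, "sex")
        assert np.isclose(abs(t), abs(t2))

    def test_tiny_group_rejected(self):
        df = pd.DataFrame(
            {"subject_id": list("abc"), "group": ["A", "B", "B"], "x": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="at least 2"):
            demographics_ttest(df, "x")
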