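"""Triplicate QC, relative quantification, normalization and group tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beevr.errors import InputError, OrderingError
from beevr.qpcr import (
    DEFAULT_POLICY,
    TABLE_PRIMERS,
    compare_all,
    compare_groups,
    normalization_factor,
    normalized_expression_table,
    reference_stability_test,
    relative_quantity,
    triplicate_qc,
)

cq_values = st.floats(10, 40, allow_nan=False)


class TestTriplicateQC:
    def test_tight_triplicate_passes(self):
        res = triplicate_qc((20.0, 20.1, 20.2))
        assert res.status == "PASS" and res.retained == (20.0, 20.1, 20.2)

    def test_outlier_dropped(self):
        # triplicate SD 0.839 > 0.3; remaining pair SD 0.071 <= 0.3
        res = triplicate_qc((20.0, 20.1, 21.5))
        assert res.status == "OUTLIER_DROPPED"
        assert res.retained == (20.0, 20.1)

    def test_spread_triplicate_discarded_with_tie_rule(self):
        # SD = 1.0; 20 and 22 tie in distance from the mean, the larger is
        # dropped, and the remaining pair SD 0.707 still fails
        res = triplicate_qc((20.0, 21.0, 22.0))
        assert res.status == "DISCARDED" and res.retained == ()

    def test_wrong_arity_rejected(self):
        with pytest.raises(InputError):
            triplicate_qc((20.0, 20.1))

    @given(vals=st.tuples(cq_values, cq_values, cq_values))
    @settings(derandomize=True, max_examples=100)
    def test_idempotent_and_permutation_stable(self, vals):
        import itertools

        res = triplicate_qc(vals)
        if res.status == "PASS":
            # QC of already-passing values changes nothing
            assert triplicate_qc(res.retained) == res
        if res.retained:
            # retained values always satisfy the SD rule
            assert np.std(res.retained, ddof=1) <= 0.3 + 1e-12
        # permutations agree on status and retained multiset
        for perm in itertools.permutations(vals):
            other = triplicate_qc(perm)
            assert other.status == res.status
            assert sorted(other.retained) == sorted(res.retained)


class TestRelativeQuantity:
    def test_batch_max_sample_is_unity(self):
        assert relative_quantity(25.0, 25.0, 1.06) == pytest.approx(1.0)

    def test_perfect_doubling(self):
        assert relative_quantity(22.0, 25.0, 1.0) == pytest.approx(8.0)

    def test_printed_efficiency_one_cycle(self):
        e = TABLE_PRIMERS["Hr38"].efficiency
        assert relative_quantity(24.0, 25.0, e) == pytest.approx(2.06)

    def test_ordering_violation_raises(self):
        with pytest.raises(OrderingError):
            relative_quantity(26.0, 25.0, 1.0)

    @given(cq1=cq_values, cq2=cq_values, e=st.floats(0.9, 1.2))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_decreasing_in_cq(self, cq1, cq2, e):
        lo, hi = sorted((cq1, cq2))
        if lo == hi:
            return
        assert relative_quantity(lo, 40.0, e) > relative_quantity(hi, 40.0, e)


class TestNormalizationFactor:
    def test_geometric_mean(self):
        assert normalization_factor([4.0, 9.0]) == pytest.approx(6.0)

    def test_single_reference_identity(self):
        assert normalization_factor([3.7]) == pytest.approx(3.7)
        assert normalization_factor([1.0, 1.0]) == pytest.approx(1.0)

    def test_product_variant(self):
        assert normalization_factor([4.0, 9.0], method="product") == pytest.approx(36.0)

    def test_non_positive_rejected(self):
        with pytest.raises(InputError):
            normalization_factor([2.0, 0.0])
        with pytest.raises(InputError):
            normalization_factor([])


def _cq_frame(levels, tech_noise=0.0, rng=None):
    """Build a long Cq table from {(bee, group, region, gene): mean_cq}."""
    rows = []
    for (bee, group, region, gene), mu in levels.items():
        for j in range(3):
            noise = rng.normal(0, tech_noise) if (rng is not None and tech_noise) else 0.0
            rows.append(
                {"bee_id": bee, "group": group, "region": region, "gene": gene,
                 "replicate": j + 1, "cq": mu + noise}
            )
    return pd.DataFrame(rows)


def _flat_levels(n_per_group=3, genes=("Egr1", "Ef1a", "Actin"), regions=("MB", "OL")):
    base = {"Egr1": 26.0, "Ef1a": 20.0, "Actin": 19.0}
    levels = {}
    for g in ("LEARNER", "NON_LEARNER"):
        for i in range(n_per_group):
            bee = f"{g[0]}{i}"
            for region in regions:
                for gene in genes:
                    levels[(bee, g, region, gene)] = base[gene]
    return levels


class TestExpressionTable:
    def test_zero_noise_no_effect_all_equal(self):
        cq = _cq_frame(_flat_levels())
        expr, _ = normalized_expression_table(cq)
        vals = expr.loc[~expr.is_reference, "normalized_expression"]
        assert np.allclose(vals, vals.iloc[0], atol=1e-9)

    def test_policy_references_used_per_region(self):
        levels = _flat_levels()
        # shift one bee's Ef1a everywhere; OL (Actin-only policy) must not react
        shifted = {k: (v - 1.0 if k[3] == "Ef1a" and k[0] == "L0" else v)
                   for k, v in levels.items()}
        expr, _ = normalized_expression_table(_cq_frame(shifted))
        mb = expr[(expr.gene == "Egr1") & (expr.region == "MB")]
        ol = expr[(expr.gene == "Egr1") & (expr.region == "OL")]
        l0_mb = mb.loc[mb.bee_id == "L0", "normalized_expression"].iloc[0]
        rest_mb = mb.loc[mb.bee_id != "L0", "normalized_expression"]
        assert not np.isclose(l0_mb, rest_mb.iloc[0])  # Ef1a is in the MB factor
        assert np.allclose(ol["normalized_expression"], ol["normalized_expression"].iloc[0])

    def test_batch_shift_invariance(self):
        cq = _cq_frame(_flat_levels())
        expr1, _ = normalized_expression_table(cq)
        shifted = cq.copy()
        mask = (shifted.gene == "Egr1") & (shifted.region == "MB")
        shifted.loc[mask, "cq"] += 3.5  # constant shift of a whole batch
        expr2, _ = normalized_expression_table(shifted)
        a = expr1[(expr1.gene == "Egr1") & (expr1.region == "MB")]["normalized_expression"]
        b = expr2[(expr2.gene == "Egr1") & (expr2.region == "MB")]["normalized_expression"]
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_discarded_sample_flagged_not_dropped(self):
        levels = _flat_levels()
        cq = _cq_frame(levels)
        mask = (cq.bee_id == "L0") & (cq.gene == "Egr1") & (cq.region == "MB")
        cq.loc[mask, "cq"] = [24.0, 26.0, 28.0]  # irrecoverably spread triplicate
        expr, qc_log = normalized_expression_table(cq)
        row = expr[(expr.bee_id == "L0") & (expr.gene == "Egr1") & (expr.region == "MB")]
        assert row["flag"].iloc[0] == "discarded_qc"
        assert np.isnan(row["normalized_expression"].iloc[0])
        assert (qc_log.qc_status == "DISCARDED").sum() == 1

    def test_missing_reference_flagged(self):
        levels = _flat_levels()
        cq = _cq_frame(levels)
        mask = (cq.bee_id == "L0") & (cq.gene == "Actin") & (cq.region == "OL")
        cq.loc[mask, "cq"] = [24.0, 26.0, 28.0]  # OL has Actin as its only reference
        expr, _ = normalized_expression_table(cq)
        row = expr[(expr.bee_id == "L0") & (expr.gene == "Egr1") & (expr.region == "OL")]
        assert row["flag"].iloc[0] == "missing_reference"
        assert np.isnan(row["normalized_expression"].iloc[0])

    def test_known_fold_change_recovered_exactly_without_noise(self):
        levels = _flat_levels()
        shifted = {
            k: (v - 1.0 if k[3] == "Egr1" and k[2] == "MB" and k[1] == "LEARNER" else v)
            for k, v in levels.items()
        }
        expr, _ = normalized_expression_table(_cq_frame(shifted))
        mb = expr[(expr.gene == "Egr1") & (expr.region == "MB")]
        ratio = (
            mb.loc[mb.group == "LEARNER", "normalized_expression"].mean()
            / mb.loc[mb.group == "NON_LEARNER", "normalized_expression"].mean()
        )
        e = TABLE_PRIMERS["Egr1"].efficiency
        assert ratio == pytest.approx((1 + e) ** 1.0, rel=1e-9)  # 2.09


class TestReferenceStability:
    def test_identical_groups_keep_policy(self):
        cq = _cq_frame(_flat_levels())
        report, policy = reference_stability_test(cq, {"MB": frozenset({"Ef1a", "Actin"})})
        assert policy["MB"] == frozenset({"Ef1a", "Actin"})
        assert len(report) == 2 and report["stable"].all()

    def test_shifted_reference_removed(self):
        rng = np.random.default_rng(0)
        levels = _flat_levels(n_per_group=8, regions=("OL",))
        shifted = {
            k: (v + 1.0 if k[3] == "Ef1a" and k[1] == "LEARNER" else v)
            for k, v in levels.items()
        }
        cq = _cq_frame(shifted, tech_noise=0.05, rng=rng)
        # add tiny bee scatter so the t-test denominator is nonzero
        for bee in cq.bee_id.unique():
            cq.loc[cq.bee_id == bee, "cq"] += rng.normal(0, 0.1)
        report, policy = reference_stability_test(cq, {"OL": frozenset({"Ef1a", "Actin"})})
        assert policy["OL"] == frozenset({"Actin"})
        assert len(report[report.region == "OL"]) == 2

    def test_never_leaves_region_empty(self):
        rng = np.random.default_rng(1)
        levels = _flat_levels(n_per_group=8, regions=("MB",))
        shifted = {
            k: (v + 2.0 if k[3] in ("Ef1a", "Actin") and k[1] == "LEARNER" else v)
            for k, v in levels.items()
        }
        cq = _cq_frame(shifted, tech_noise=0.05, rng=rng)
        for bee in cq.bee_id.unique():
            cq.loc[cq.bee_id == bee, "cq"] += rng.normal(0, 0.1)
        with pytest.warns(UserWarning, match="no stable reference"):
            report, policy = reference_stability_test(
                cq, {"MB": frozenset({"Ef1a", "Actin"})}
            )
        assert len(policy["MB"]) == 1


class TestCompareGroups:
    def test_printed_sample_sizes_give_df_29(self):
        rng = np.random.default_rng(0)
        cmp = compare_groups(rng.normal(size=17), rng.normal(size=14))
        assert cmp.df == 29

    def test_identical_samples(self):
        cmp = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0])
        assert cmp.t_statistic == 0.0 and cmp.p_value == 1.0

    def test_hand_computed_pooled_t(self):
        cmp = compare_groups([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert cmp.t_statistic == pytest.approx(-1.2247, abs=1e-4)
        assert cmp.df == 4

    def test_zero_variance_unequal_means_flagged(self):
        cmp = compare_groups([2.0, 2.0], [1.0, 1.0])
        assert cmp.infinite_t and math.isinf(cmp.t_statistic) and cmp.p_value == 0.0

    def test_tiny_groups_rejected(self):
        with pytest.raises(InputError):
            compare_groups([1.0], [1.0, 2.0])
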