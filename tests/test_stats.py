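"""Statistical layer against enumeration and formula oracles."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from fintrace.kinematics import SpeedSeries
from fintrace.profiles import classify_sap
from fintrace.stats import (
    ContingencyTable,
    GroupSample,
    StatsError,
    chi_square_sap,
    fisher_exact_rxc,
    fisher_table_probabilities,
    holm_adjust,
    mann_whitney,
    type_i_error_study,
)


def permutation_two_sided_p(a, b):
    """Exhaustive label-permutation p for the Mann-Whitney U (no ties)."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    mu = na * (n - na) / 2.0

    def u_stat(av, bv):
        return sum(float(x > y) for x in av for y in bv)

    u_obs = u_stat(a, b)
    hits = total = 0
    for idx in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        g = GroupSample("a", [1.0, 2.0, 3.0, 4.0])
        assert mann_whitney(g, GroupSample("b", [1.0, 2.0, 3.0, 4.0])).p_value == 1.0

    def test_fully_separated_small_groups_match_enumeration(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = mann_whitney(GroupSample("a", a), GroupSample("b", b))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(permutation_two_sided_p(a, b))
        assert res.p_value == pytest.approx(2 / 20)

    @pytest.mark.parametrize("na,nb", [(3, 3), (2, 8), (4, 5), (5, 5)])
    def test_exact_p_matches_permutation_oracle(self, na, nb, rng):
        for _ in range(5):
            a = rng.standard_normal(na)
            b = rng.standard_normal(nb) + rng.uniform(-1, 1)
            res = mann_whitney(GroupSample("a", a), GroupSample("b", b))
            assert res.p_value == pytest.approx(permutation_two_sided_p(a, b), abs=1e-12)

    def test_symmetric_in_group_order(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(12) + 0.5
        pab = mann_whitney(GroupSample("a", a), GroupSample("b", b)).p_value
        pba = mann_whitney(GroupSample("b", b), GroupSample("a", a)).p_value
        assert pab == pytest.approx(pba)

    def test_u_reported_for_first_group(self):
        res = mann_whitney(GroupSample("a", [1.0, 2.0]), GroupSample("b", [3.0, 4.0]))
        assert res.u_statistic == 0.0

    def test_ties_fall_back_to_corrected_normal(self):
        a = GroupSample("a", [1.0, 2.0, 2.0])
        b = GroupSample("b", [2.0, 3.0, 4.0])
        assert mann_whitney(a, b).method == "asymptotic"

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            GroupSample("a", [])


def _profiles(seconds_rows):
    from fintrace.profiles import SAPProfile

    return [
        SAPProfile("f%d" % i, (2.0, 12.0), tuple(map(float, row)),
                   tuple(100 * s / sum(row) for s in row))
        for i, row in enumerate(seconds_rows)
    ]


class TestChiSquareSAP:
    def test_identical_pooled_distributions_statistic_zero(self):
        a = _profiles([[100, 100, 100]])
        b = _profiles([[100, 100, 100]])
        res = chi_square_sap(a, b)
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.df == 2

    def test_statistic_matches_textbook_formula(self, rng):
        for _ in range(20):
            a = _profiles(rng.integers(1, 400, size=(5, 3)))
            b = _profiles(rng.integers(1, 400, size=(7, 3)))
            res = chi_square_sap(a, b)
            obs = res.table.astype(float)
            row = obs.sum(axis=1, keepdims=True)
            col = obs.sum(axis=0, keepdims=True)
            expected = row @ col / obs.sum()
            stat = ((obs - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(stat, rel=1e-12)
            assert res.df == 2
            assert res.p_value == pytest.approx(sps.chi2.sf(stat, 2), rel=1e-12)

    def test_low_expected_cell_flagged_not_fatal(self):
        a = _profiles([[3, 1, 0]])
        b = _profiles([[1, 3, 1]])
        res = chi_square_sap(a, b)
        assert res.low_expected is True and 0 <= res.p_value <= 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(StatsError):
            chi_square_sap([], _profiles([[1, 1, 1]]))


class TestFisherExact:
    def test_two_by_two_matches_hypergeometric_oracle(self):
        table = ContingencyTable(("r1", "r2"), ("c1", "c2"), [[1, 9], [11, 3]])
        assert fisher_exact_rxc(table) == pytest.approx(
            sps.fisher_exact([[1, 9], [11, 3]])[1], rel=1e-9
        )

    def test_random_two_by_two_agreement(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 12, size=(2, 2))
            table = ContingencyTable(("a", "b"), ("x", "y"), counts)
            assert fisher_exact_rxc(table) == pytest.approx(
                sps.fisher_exact(counts)[1], rel=1e-9
            )

    def test_enumeration_probabilities_sum_to_one(self, rng):
        for shape in [(2, 2), (2, 3), (3, 3)]:
            counts = rng.integers(0, 8, size=shape)
            counts[0, 0] += 1
            table = ContingencyTable(
                tuple("r%d" % i for i in range(shape[0])),
                tuple("c%d" % j for j in range(shape[1])),
                counts,
            )
            assert fisher_table_probabilities(table).sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_row_and_column_permutation(self, rng):
        counts = rng.integers(0, 10, size=(2, 3))
        base = fisher_exact_rxc(ContingencyTable(("a", "b"), ("x", "y", "z"), counts))
        perm = counts[::-1][:, [2, 0, 1]]
        assert fisher_exact_rxc(
            ContingencyTable(("b", "a"), ("z", "x", "y"), perm)
        ) == pytest.approx(base, rel=1e-12)

    def test_zero_row_forces_degenerate_p_one(self):
        table = ContingencyTable(("a", "b"), ("x", "y"), [[0, 0], [5, 7]])
        assert fisher_exact_rxc(table) == 1.0

    def test_enumeration_guard(self):
        table = ContingencyTable(("a", "b"), ("x", "y"), [[400, 200], [100, 300]])
        with pytest.raises(StatsError, match="chi-square"):
            fisher_exact_rxc(table)

    def test_table_validation(self):
        with pytest.raises(StatsError):
            ContingencyTable(("a",), ("x", "y"), [[1, 2]])
        with pytest.raises(StatsError):
            ContingencyTable(("a", "b"), ("x", "y"), [[1, -2], [0, 1]])


class TestHolm:
    def test_monotone_and_bounded(self):
        adj = holm_adjust([0.01, 0.04, 0.03, 0.9])
        assert (adj <= 1).all()
        assert adj[0] == pytest.approx(0.04)
        assert adj[3] == pytest.approx(0.9)


class TestRejectionStudies:
    def test_alpha_zero_never_rejects(self):
        rate = type_i_error_study("mann_whitney", 3, 5, 0.0, seed=0, duration_s=60)
        assert rate == 0.0

    def test_alpha_one_always_rejects(self):
        rate = type_i_error_study("mann_whitney", 3, 5, 1.0, seed=0, duration_s=60)
        assert rate == 1.0

    def test_unknown_test_rejected(self):
        with pytest.raises(StatsError):
            type_i_error_study("t_test", 3, 5, 0.05, seed=0)

    def test_mann_whitney_roughly_calibrated_smoke(self):
        # strict calibration is asserted by the acceptance suite
        rate = type_i_error_study("mann_whitney", 8, 60, 0.05, seed=4, duration_s=120)
        assert rate <= 0.15
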