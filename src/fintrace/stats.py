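"""Nonparametric group comparisons for behavioral cohorts.

Three tests cover the analysis layer: pairwise Mann–Whitney for per-fish
scalars (distance, max speed, class times, zone times, respiration),
Pearson chi-square on pooled speed-activity-profile (SAP) time tables,
and the Freeman–Halton (r×c) exact two-tailed Fisher test for small
count tables such as dose × mutation-positive screens.

The chi-square construction pools integer seconds per SAP class over the
fish of each genotype (a 2×3 table, df = 2).  Seconds within one fish
are serially dependent, so this test treats pseudo-replicated units as
independent and is anticonservative; the per-fish Mann–Whitney
comparisons do not share this caveat.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .kinematics import SpeedSeries
from .profiles import SAPProfile, classify_sap
from .simulate import GenotypeParams, simulate_speed_series


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSample:
    """Per-fish scalar observations for one group (genotype or dose)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) == 0:
            raise StatsError(f"group {self.label!r} is empty")


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float  # U of the first group
    p_value: float
    method: str  # "exact" | "asymptotic"


def mann_whitney(a: GroupSample, b: GroupSample) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when the smaller group has at most
    8 observations and the pooled sample is tie-free; otherwise the
    normal approximation with tie and continuity corrections.
    """
    pooled = np.concatenate([a.values, b.values])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(a.values), len(b.values)) <= 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a.values, b.values, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: np.ndarray  # pooled integer seconds, groups × classes
    low_expected: bool  # True when any expected cell < 5


def chi_square_sap(
    profiles_a: Sequence[SAPProfile], profiles_b: Sequence[SAPProfile]
) -> ChiSquareResult:
    """Pearson chi-square on pooled SAP time tables of two cohorts.

    Builds a 2×3 table of cumulated seconds per class summed over fish
    and rounded to integers.  Classes unused by both cohorts are dropped
    from the table (df adjusts accordingly).
    """
    if not profiles_a or not profiles_b:
        raise StatsError("both cohorts must be non-empty")
    table = np.array(
        [
            np.round([sum(p.seconds[k] for p in cohort) for k in range(3)]).astype(np.int64)
            for cohort in (profiles_a, profiles_b)
        ]
    )
    keep = table.sum(axis=0) > 0
    trimmed = table[:, keep]
    if trimmed.shape[1] < 2:
        # a single remaining class carries no distributional information
        return ChiSquareResult(0.0, 0, 1.0, table, True)
    stat, p, df, expected = sps.chi2_contingency(trimmed, correction=False)
    return ChiSquareResult(
        float(stat), int(df), float(p), table, bool((expected < 5).any())
    )


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise StatsError("contingency table must be at least 2x2")
        if (counts < 0).any():
            raise StatsError("counts must be non-negative")
        if len(self.row_labels) != counts.shape[0] or len(self.col_labels) != counts.shape[1]:
            raise StatsError("label lengths must match table shape")


def _log_table_prob(cells: Iterable[int]) -> float:
    # sorted + fsum makes the value invariant under cell permutation, so
    # symmetry-equivalent tables tie bit-exactly
    return -math.fsum(sorted(float(gammaln(n + 1)) for n in cells))


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)

    def fill(i: int, j: int, row_left: int, col_left: np.ndarray):
        if i == r - 1:
            # last row forced by column margins
            if (col_left >= 0).all():
                table[r - 1] = col_left
                yield table
            return
        if j == c - 1:
            if row_left <= col_left[j]:
                table[i, j] = row_left
                col_left[j] -= row_left
                yield from fill(i + 1, 0, int(row_sums[i + 1]), col_left)
                col_left[j] += row_left
            return
        hi = min(row_left, int(col_left[j]))
        for v in range(hi + 1):
            table[i, j] = v
            col_left[j] -= v
            yield from fill(i, j + 1, row_left - v, col_left)
            col_left[j] += v

    yield from fill(0, 0, int(row_sums[0]), np.array(col_sums, dtype=np.int64))


def fisher_exact_rxc(
    table: ContingencyTable, max_total: int = 500, tol: float = 1e-12
) -> float:
    """Exact two-tailed Fisher test for an r×c table (Freeman–Halton).

    Enumerates every table sharing the observed margins and sums the
    hypergeometric probabilities of those no more probable than the
    observed table (probability-ordering two-tail rule; ``tol`` is the
    relative slack used when comparing probabilities for ties).
    """
    counts = table.counts
    n = int(counts.sum())
    if n > max_total:
        raise StatsError(
            f"table total {n} exceeds the enumeration guard ({max_total}); "
            "use a chi-square test instead"
        )
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    log_const = float(
        gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)
    )
    log_p_obs = _log_table_prob(counts.ravel())
    cut = log_p_obs + math.log1p(tol)
    p = 0.0
    total = 0.0
    for t in _enumerate_tables(row_sums, col_sums):
        lp = _log_table_prob(t.ravel())
        prob = math.exp(log_const + lp)
        total += prob
        if lp <= cut:
            p += prob
    # normalize by the enumerated mass (analytically 1) so degenerate
    # margins that force a single table give p = 1 exactly
    return min(p / total, 1.0)


def fisher_table_probabilities(table: ContingencyTable) -> np.ndarray:
    """Probabilities of every margin-consistent table (sums to 1)."""
    counts = table.counts
    n = int(counts.sum())
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    log_const = float(
        gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)
    )
    return np.array(
        [
            math.exp(log_const + _log_table_prob(t.ravel()))
            for t in _enumerate_tables(row_sums, col_sums)
        ]
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; no correction is the default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _rest_seconds(params: GenotypeParams, duration_s: int, body_length_cm: float, rng) -> float:
    _, speeds = simulate_speed_series(params, duration_s, rng, body_length_cm)
    profile = classify_sap(SpeedSeries("sim", speeds), body_length_cm)
    return profile.seconds[0]


def type_i_error_study(
    test: str,
    n_per_group: int,
    n_reps: int,
    alpha: float,
    seed=0,
    params: GenotypeParams | None = None,
    params_b: GenotypeParams | None = None,
    duration_s: int = 600,
    body_length_cm: float = 4.0,
) -> float:
    """Monte-Carlo rejection rate of a test on simulated cohorts.

    With identical parameter blocks per group (the default) this is a
    type-I-error estimate; supplying a different ``params_b`` turns it
    into a power estimate.  ``test`` is ``"mann_whitney"`` (per-fish
    rest-SAP seconds) or ``"chi_square_sap"`` (pooled class-time table).
    Rejects when p <= alpha.
    """
    if n_reps < 1:
        raise StatsError("n_reps must be >= 1")
    if params is None:
        params = GenotypeParams(state_occupancy=(0.70, 0.25, 0.05))
    if params_b is None:
        params_b = params
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rejections = 0
    for _ in range(n_reps):
        if test == "mann_whitney":
            a = GroupSample(
                "a",
                [_rest_seconds(params, duration_s, body_length_cm, rng) for _ in range(n_per_group)],
            )
            b = GroupSample(
                "b",
                [_rest_seconds(params_b, duration_s, body_length_cm, rng) for _ in range(n_per_group)],
            )
            p = mann_whitney(a, b).p_value
        elif test == "chi_square_sap":
            cohorts = []
            for block in (params, params_b):
                cohorts.append(
                    [
                        classify_sap(
                            SpeedSeries(
                                "sim",
                                simulate_speed_series(block, duration_s, rng, body_length_cm)[1],
                            ),
                            body_length_cm,
                        )
                        for _ in range(n_per_group)
                    ]
                )
            p = chi_square_sap(cohorts[0], cohorts[1]).p_value
        else:
            raise StatsError(f"unknown test {test!r}")
        if p <= alpha:
            rejections += 1
    return rejections / n_reps
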