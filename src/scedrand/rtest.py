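"""Randomization tests with Pearson's correlation on a response function.

The test statistic is Pearson's product-moment correlation between the
observed scores and the predicted-response vector.  For every admissible
data division of the design's randomization scheme the response function is
rebuilt for that division's phase lengths and the statistic recomputed; the
collection of values (the observed one plus the pseudovalues) is the
randomization distribution.  Under the null hypothesis of no intervention
effect all divisions are equally likely, so

    p = #(pseudovalues >= observed) / m

is an exact one-sided p value in the favorable direction.  With a binary
response function the statistic is the point-biserial correlation, which is
p-value-equivalent to a mean difference.

Exploratory scans vary the latency of a delayed effect or the duration of a
temporary effect and report one test per scenario; the resulting p values
can be Bonferroni- or Holm-adjusted when used as probabilistic statements
rather than descriptive measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateDivisionError,
    DesignInconsistencyError,
    TestUndefinedError,
    UnsupportedDesignError,
)
from .io import SCEDSeries
from .response import EffectSpec, ResponseFunction, build_rf
from .schemes import (
    ABABDivision,
    ABABScheme,
    ABDivision,
    ABStartScheme,
    ATDDivision,
    ATDScheme,
    DataDivision,
    MBDivision,
    MultipleBaselineScheme,
    Scheme,
    enumerate_divisions,
)

__all__ = [
    "TestResult",
    "ScanResult",
    "pearson_statistic",
    "orient_scores",
    "randomization_distribution",
    "p_value",
    "scan_durations",
    "scan_latencies",
    "adjust_pvalues",
]


# ---------------------------------------------------------------------------
# Statistic


def pearson_statistic(scores: np.ndarray, rf: ResponseFunction) -> float:
    """Pearson correlation between scores and a response function.

    Computed over the included occasions only.  When either variable is
    constant on the included set the correlation is undefined; by convention
    the statistic is 0 there (no evidence of association), which keeps the
    number of divisions, and hence the exactness of the test, intact.
    """
    r, _ = _statistic_with_flag(np.asarray(scores, dtype=float), rf)
    return r


def _statistic_with_flag(scores: np.ndarray, rf: ResponseFunction) -> tuple[float, bool]:
    if scores.size != rf.n:
        raise ValueError(f"scores ({scores.size}) and rf ({rf.n}) lengths differ")
    x = scores[rf.mask]
    y = rf.included_values
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt((sx @ sx) * (sy @ sy))
    if denom == 0.0:
        return 0.0, True
    r = float((sx @ sy) / denom)
    return min(1.0, max(-1.0, r)), False


def orient_scores(scores: np.ndarray, aim: str) -> np.ndarray:
    """Orient scores so a favorable outcome yields a positive statistic.

    Response functions are written for an increase of the target behavior;
    when the aim is to decrease it, the scores are negated instead, leaving
    the published response-function templates untouched.
    """
    scores = np.asarray(scores, dtype=float)
    if aim == "increase":
        return scores
    if aim == "decrease":
        return -scores
    raise ValueError(f"unknown aim {aim!r}")


# ---------------------------------------------------------------------------
# Per-division response values


def _division_rfs(
    scheme: Scheme,
    division: DataDivision,
    spec: EffectSpec,
    tier_lengths: Sequence[int],
) -> list[tuple[slice, ResponseFunction | None]]:
    """Response function(s) for one division, one per A-B comparison.

    Returns (segment, rf) pairs where ``segment`` slices the relevant
    occasions out of the concatenated score vector; ``rf`` is None when the
    division is degenerate for this comparison (all-constant prediction).
    """
    out: list[tuple[slice, ResponseFunction | None]] = []

    def safe_build(n_A: int, n_B: int) -> ResponseFunction | None:
        try:
            return build_rf(spec, n_A, n_B)
        except DegenerateDivisionError:
            return None

    if isinstance(division, ABDivision):
        n = tier_lengths[0]
        out.append((slice(0, n), safe_build(division.n_A, n - division.n_A)))
    elif isinstance(division, MBDivision):
        offset = 0
        for n_i, start in zip(tier_lengths, division.starts):
            a = start - 1
            if not 1 <= a <= n_i - 1:
                raise DesignInconsistencyError(
                    f"start {start} infeasible for a tier of {n_i} occasions"
                )
            out.append((slice(offset, offset + n_i), safe_build(a, n_i - a)))
            offset += n_i
    elif isinstance(division, ABABDivision):
        n = tier_lengths[0]
        lengths = division.phase_lengths(n)
        # one A-B comparison per adjacent (A, B) phase pair
        offset = 0
        for a_len, b_len in zip(lengths[0::2], lengths[1::2]):
            out.append((slice(offset, offset + a_len + b_len), safe_build(a_len, b_len)))
            offset += a_len + b_len
    elif isinstance(division, ATDDivision):
        from .response import alternation_rf

        n = tier_lengths[0]
        if len(division.labels) != n:
            raise DesignInconsistencyError("division length differs from series length")
        out.append((slice(0, n), alternation_rf(division.labels)))
    else:
        raise TypeError(f"unknown division type: {division!r}")
    return out


def _division_statistic(
    scores: np.ndarray,
    scheme: Scheme,
    division: DataDivision,
    spec: EffectSpec,
    tier_lengths: Sequence[int],
) -> tuple[float, bool]:
    """Mean per-comparison correlation for a division, plus a degenerate flag."""
    rs = []
    degenerate = False
    for seg, rf in _division_rfs(scheme, division, spec, tier_lengths):
        if rf is None:
            rs.append(0.0)
            degenerate = True
            continue
        r, flat = _statistic_with_flag(scores[seg], rf)
        rs.append(r)
        degenerate = degenerate or flat
    return float(np.mean(rs)), degenerate


# ---------------------------------------------------------------------------
# Results


@dataclass(frozen=True)
class TestResult:
    """Outcome of one randomization test.

    ``pseudovalues`` holds the statistic at every admissible division in
    enumeration order, including the observed one at ``observed_index``.
    ``rank`` is 1 for the largest value (ties counted as extreme), and
    ``p = rank-equivalent count / m`` is the exact one-sided p value; its
    smallest attainable value is ``min_p = 1/m``.
    """

    r_obs: float
    pseudovalues: np.ndarray = field(repr=False)
    observed_index: int
    divisions: tuple[DataDivision, ...] = field(repr=False)
    degenerate_divisions: tuple[DataDivision, ...] = field(repr=False)
    two_sided: bool = False

    @property
    def m(self) -> int:
        return self.pseudovalues.size

    @property
    def rank(self) -> int:
        key = np.abs(self.pseudovalues) if self.two_sided else self.pseudovalues
        obs = key[self.observed_index]
        return int(np.sum(key > obs)) + 1

    @property
    def p(self) -> float:
        key = np.abs(self.pseudovalues) if self.two_sided else self.pseudovalues
        obs = key[self.observed_index]
        return float(np.sum(key >= obs)) / self.m

    @property
    def min_p(self) -> float:
        return 1.0 / self.m

    @property
    def favorable(self) -> bool:
        return self.r_obs > 0


def p_value(result: TestResult) -> float:
    """Exact p value: share of divisions at least as extreme as observed."""
    return result.p


@dataclass(frozen=True)
class ScanResult:
    """Results of an exploratory scan over durations or latencies.

    ``axis`` holds the scanned values (None marks the permanent scenario);
    ``results`` the corresponding TestResult per scenario.
    """

    kind: str  # "duration" | "latency"
    axis: tuple[int | None, ...]
    results: tuple[TestResult, ...]
    adjust_method: str = "none"

    @property
    def p_values(self) -> np.ndarray:
        return np.array([res.p for res in self.results])

    @property
    def adjusted_p_values(self) -> np.ndarray:
        return adjust_pvalues(self.p_values, self.adjust_method)

    def scenario_labels(self) -> list[str]:
        word = "d" if self.kind == "duration" else "L"
        return ["permanent" if v is None else f"{word}={v}" for v in self.axis]


# ---------------------------------------------------------------------------
# The test


def _as_tiers(series) -> list[SCEDSeries]:
    if isinstance(series, SCEDSeries):
        return [series]
    return list(series)


def _observed_division(
    scheme: Scheme, tiers: list[SCEDSeries], divisions: list[DataDivision]
) -> int:
    """Index of the actually realised division within the enumeration."""
    if isinstance(scheme, ABStartScheme):
        obs = ABDivision(start=tiers[0].n_A + 1)
        matches = [i for i, d in enumerate(divisions) if d == obs]
    elif isinstance(scheme, MultipleBaselineScheme):
        starts = tuple(t.n_A + 1 for t in tiers)
        matches = [i for i, d in enumerate(divisions) if d.starts == starts]
    elif isinstance(scheme, ABABScheme):
        labels = tiers[0].labels
        cps = tuple(
            i + 1 for i in range(1, len(labels)) if labels[i] != labels[i - 1]
        )
        obs = ABABDivision(change_points=cps)
        matches = [i for i, d in enumerate(divisions) if d == obs]
    elif isinstance(scheme, ATDScheme):
        obs = ATDDivision(labels=tiers[0].labels)
        matches = [i for i, d in enumerate(divisions) if d == obs]
    else:
        raise TypeError(f"not a randomization scheme: {scheme!r}")
    if not matches:
        raise DesignInconsistencyError(
            "the realised division is not in the admissible set of the scheme"
        )
    return matches[0]


def _check_series(scheme: Scheme, tiers: list[SCEDSeries]) -> list[int]:
    if isinstance(scheme, MultipleBaselineScheme):
        if len(tiers) != scheme.t:
            raise DesignInconsistencyError(
                f"scheme expects {scheme.t} tiers, got {len(tiers)}"
            )
    elif len(tiers) != 1:
        raise UnsupportedDesignError("this design takes a single series")
    if isinstance(scheme, (ABStartScheme, ABABScheme, ATDScheme)):
        if tiers[0].n != scheme.n:
            raise DesignInconsistencyError(
                f"series has {tiers[0].n} occasions but scheme expects {scheme.n}"
            )
    return [t.n for t in tiers]


def randomization_distribution(
    series: SCEDSeries | Sequence[SCEDSeries],
    scheme: Scheme,
    spec: EffectSpec,
    *,
    two_sided: bool = False,
) -> TestResult:
    """Run the randomization test for one effect specification.

    For every admissible division the response function is rebuilt for that
    division's phase lengths and correlated with the (aim-oriented) scores;
    multi-comparison designs (multiple-baseline tiers, ABAB phase pairs)
    average the per-comparison correlations.  Degenerate divisions keep a
    conventioned statistic of 0 and are flagged, never dropped.
    """
    tiers = _as_tiers(series)
    tier_lengths = _check_series(scheme, tiers)
    divisions = enumerate_divisions(scheme)
    obs_idx = _observed_division(scheme, tiers, divisions)
    scores = np.concatenate([orient_scores(t.scores, spec.aim) for t in tiers])

    stats = np.empty(len(divisions))
    degenerate: list[DataDivision] = []
    for i, division in enumerate(divisions):
        stats[i], flat = _division_statistic(
            scores, scheme, division, spec, tier_lengths
        )
        if flat:
            degenerate.append(division)
    if len(degenerate) == len(divisions):
        raise TestUndefinedError("every admissible division is degenerate")
    return TestResult(
        r_obs=float(stats[obs_idx]),
        pseudovalues=stats,
        observed_index=obs_idx,
        divisions=tuple(divisions),
        degenerate_divisions=tuple(degenerate),
        two_sided=two_sided,
    )


# ---------------------------------------------------------------------------
# Exploratory scans


def _observed_n_B(series: SCEDSeries | Sequence[SCEDSeries]) -> int:
    tiers = _as_tiers(series)
    return min(t.n_B for t in tiers)


def scan_durations(
    series: SCEDSeries | Sequence[SCEDSeries],
    scheme: Scheme,
    spec: EffectSpec,
    d_max: int,
    *,
    include_permanent: bool = True,
    two_sided: bool = False,
) -> ScanResult:
    """Exploratory scan over effect durations d = 1..d_max plus permanent.

    Each scenario reruns the full randomization test with the same scheme
    (hence identical divisions) and a temporary effect of duration d.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    n_B = _observed_n_B(series)
    if d_max > n_B:
        warnings.warn(
            f"d_max {d_max} exceeds the intervention length {n_B}; truncating",
            stacklevel=2,
        )
        d_max = n_B
    axis: list[int | None] = []
    results = []
    if include_permanent:
        axis.append(None)
        results.append(
            randomization_distribution(
                series, scheme, spec.with_(duration="permanent", effect_duration=None),
                two_sided=two_sided,
            )
        )
    for d in range(1, d_max + 1):
        axis.append(d)
        results.append(
            randomization_distribution(
                series, scheme, spec.with_(duration="temporary", effect_duration=d),
                two_sided=two_sided,
            )
        )
    return ScanResult(kind="duration", axis=tuple(axis), results=tuple(results))


def scan_latencies(
    series: SCEDSeries | Sequence[SCEDSeries],
    scheme: Scheme,
    spec: EffectSpec,
    L_max: int,
    *,
    two_sided: bool = False,
) -> ScanResult:
    """Exploratory scan over effect latencies L = 1..L_max.

    Each scenario reruns the full randomization test with a delayed onset of
    L occasions; L must stay below the intervention length or the observed
    division itself would be degenerate.
    """
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    n_B = _observed_n_B(series)
    if L_max >= n_B:
        warnings.warn(
            f"L_max {L_max} >= intervention length {n_B}; truncating to {n_B - 1}",
            stacklevel=2,
        )
        L_max = n_B - 1
    axis = []
    results = []
    for L in range(1, L_max + 1):
        axis.append(L)
        results.append(
            randomization_distribution(
                series, scheme, spec.with_(onset="delayed", latency=L),
                two_sided=two_sided,
            )
        )
    return ScanResult(kind="latency", axis=tuple(axis), results=tuple(results))


def adjust_pvalues(ps: Sequence[float], method: str = "none") -> np.ndarray:
    """Multiple-testing adjustment of scan p values.

    ``none`` returns the raw values (the descriptive, purely exploratory
    reading); ``bonferroni`` and ``holm`` give adjusted values capped at 1
    for use as probabilistic statements.
    """
    ps = np.asarray(ps, dtype=float)
    if method == "none":
        return ps.copy()
    if method not in ("bonferroni", "holm"):
        raise ValueError(f"unknown adjustment method {method!r}")
    if ps.size == 0:
        return ps.copy()
    return multipletests(ps, method=method)[1]
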