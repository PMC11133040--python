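"""Synthetic single-case series and Monte-Carlo validity/power harness.

Series are generated as

    y_t = mu + beta * t + delta * f_t + e_t,

where f_t is the unit-peak-normalized response function of a chosen effect
prototype at the true division, and e_t is Gaussian noise (i.i.d. by
default, optionally AR(1)).  Because the effect shape is normalized, delta
is the peak effect in score units for every prototype, making effect sizes
comparable across shapes.  Counts-like outcomes (e.g. a tally of behaviors)
can be emulated by rounding and flooring at zero.

The rejection-rate simulator draws the design randomization, generates the
data under that true division, runs the test, and reports the fraction of
replicates with p <= alpha — the type I error rate when delta = 0 and the
statistical power otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDivisionError, UnsupportedDesignError
from .io import SCEDSeries
from .response import EffectSpec, alternation_rf, build_rf
from .rtest import randomization_distribution
from .schemes import (
    ABABDivision,
    ABDivision,
    ATDDivision,
    MBDivision,
    Scheme,
    draw_random_assignment,
)

__all__ = [
    "GenerationModel",
    "SimulationResult",
    "generate_series",
    "simulate_rejection_rate",
]


@dataclass(frozen=True)
class GenerationModel:
    """Data-generating model for synthetic single-case series.

    Parameters
    ----------
    mu
        Baseline level, in score units.
    beta
        Linear trend per occasion, in score units.
    delta
        Peak effect size in score units (multiplies the unit-peak effect
        shape); 0 generates null data.
    sigma
        Noise standard deviation, in score units.
    shape
        The ground-truth effect prototype.
    phi
        AR(1) autocorrelation of the noise; 0 gives i.i.d. noise.
    counts
        Emulate count data: round scores and floor them at 0.
    """

    mu: float = 0.0
    beta: float = 0.0
    delta: float = 1.0
    sigma: float = 1.0
    shape: EffectSpec = EffectSpec()
    phi: float = 0.0
    counts: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not -1 < self.phi < 1:
            raise ValueError("phi must lie in (-1, 1) for a stationary AR(1)")


def _unit_peak_shape(spec: EffectSpec, n_A: int, n_B: int) -> np.ndarray:
    """Response-function values normalized to a peak of 1 (all-zero if degenerate)."""
    try:
        values = build_rf(spec.with_(baseline_trend=False), n_A, n_B).values
    except DegenerateDivisionError:
        return np.zeros(n_A + n_B)
    peak = np.max(np.abs(values))
    return values / peak if peak > 0 else values


def _noise(rng: np.random.Generator, n: int, sigma: float, phi: float) -> np.ndarray:
    if sigma == 0:
        return np.zeros(n)
    white = rng.normal(0.0, sigma, size=n)
    if phi == 0:
        return white
    # stationary AR(1): innovations scaled so the marginal sd stays sigma
    e = np.empty(n)
    e[0] = white[0]
    scale = np.sqrt(1 - phi**2)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + scale * white[t]
    return e


def generate_series(
    model: GenerationModel,
    n_A: int,
    n_B: int,
    seed: int | np.random.Generator = 0,
) -> SCEDSeries:
    """Generate one A-B series with the true division at (n_A, n_B)."""
    if n_A < 1 or n_B < 1:
        raise ValueError("both phases need at least one occasion")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_A + n_B
    t = np.arange(1, n + 1)
    y = (
        model.mu
        + model.beta * t
        + model.delta * _unit_peak_shape(model.shape, n_A, n_B)
        + _noise(rng, n, model.sigma, model.phi)
    )
    if model.counts:
        y = np.maximum(np.round(y), 0.0)
    labels = ("A",) * n_A + ("B",) * n_B
    return SCEDSeries(labels=labels, scores=y)


def _generate_for_division(
    model: GenerationModel,
    scheme: Scheme,
    division,
    rng: np.random.Generator,
    tier_lengths: Sequence[int] | None,
) -> SCEDSeries | list[SCEDSeries]:
    if isinstance(division, ABDivision):
        n = scheme.n
        return generate_series(model, division.n_A, n - division.n_A, rng)
    if isinstance(division, MBDivision):
        if tier_lengths is None:
            raise ValueError("multiple-baseline simulation needs tier_lengths")
        return [
            generate_series(model, start - 1, n_i - (start - 1), rng)
            for n_i, start in zip(tier_lengths, division.starts)
        ]
    if isinstance(division, ABABDivision):
        n = scheme.n
        lengths = division.phase_lengths(n)
        f = np.concatenate(
            [
                _unit_peak_shape(model.shape, a_len, b_len)
                for a_len, b_len in zip(lengths[0::2], lengths[1::2])
            ]
        )
        t = np.arange(1, n + 1)
        y = model.mu + model.beta * t + model.delta * f + _noise(
            rng, n, model.sigma, model.phi
        )
        if model.counts:
            y = np.maximum(np.round(y), 0.0)
        labels: list[str] = []
        for length, lab in zip(lengths, ("A", "B") * (len(lengths) // 2)):
            labels.extend([lab] * length)
        return SCEDSeries(labels=tuple(labels), scores=y)
    if isinstance(division, ATDDivision):
        f = alternation_rf(division.labels).values
        n = f.size
        t = np.arange(1, n + 1)
        y = model.mu + model.beta * t + model.delta * f + _noise(
            rng, n, model.sigma, model.phi
        )
        if model.counts:
            y = np.maximum(np.round(y), 0.0)
        return SCEDSeries(labels=division.labels, scores=y)
    raise UnsupportedDesignError(
        f"simulation not implemented for divisions of type {type(division).__name__}"
    )


@dataclass(frozen=True)
class SimulationResult:
    """Monte-Carlo rejection rate with its standard error."""

    rate: float
    se: float
    reps: int
    alpha: float


def simulate_rejection_rate(
    model: GenerationModel,
    scheme: Scheme,
    spec: EffectSpec,
    alpha: float,
    reps: int,
    seed: int | np.random.Generator = 0,
    *,
    tier_lengths: Sequence[int] | None = None,
) -> SimulationResult:
    """Estimate P(p <= alpha) by simulation.

    Each replicate (i) draws the actual division uniformly from the scheme,
    mirroring the design-stage randomization, (ii) generates data whose true
    effect sits at that division, and (iii) runs the randomization test with
    the analysis spec.  With ``model.delta = 0`` this checks test validity
    (the rate can never exceed alpha, and equals floor(alpha*m)/m up to
    Monte-Carlo error); with an effect it estimates power.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        division = draw_random_assignment(scheme, rng)
        data = _generate_for_division(model, scheme, division, rng, tier_lengths)
        result = randomization_distribution(data, scheme, spec)
        if result.p <= alpha:
            hits += 1
    rate = hits / reps
    se = float(np.sqrt(rate * (1 - rate) / reps))
    return SimulationResult(rate=rate, se=se, reps=reps, alpha=alpha)
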