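"""Response functions: vectors of predicted-response constants.

A response function encodes the expected intervention effect as one constant
per measurement occasion.  Baseline occasions are coded 0; intervention
occasions follow the pattern implied by the effect's onset (immediate or
delayed by a latency of L occasions), progression (abrupt step vs. gradual
1, 2, 3, ... ramp), duration (permanent, or temporary for d occasions) and,
for gradual temporary effects, the offset shape (abrupt drop, gradual decay,
or hold at an asymptote).  The Pearson correlation between this vector and
the observed scores is the test statistic of the randomization test, so the
response function is where the scientific expectation about the data pattern
enters the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

from .errors import DegenerateDivisionError, MaskError, UnsupportedDesignError
from .io import UserResponseValues

__all__ = [
    "EffectSpec",
    "ResponseFunction",
    "build_rf",
    "add_linear_trend",
    "apply_mask",
    "alternation_rf",
]

Aim = Literal["increase", "decrease"]
Onset = Literal["immediate", "delayed"]
Progression = Literal["abrupt", "gradual"]
Duration = Literal["permanent", "temporary"]
Offset = Literal["abrupt", "gradual", "asymptote"]


@dataclass(frozen=True)
class EffectSpec:
    """Declarative description of the expected intervention effect.

    Parameters
    ----------
    aim
        Whether the intervention aims to increase or decrease the target
        behavior.  Handled downstream by orienting the scores, so the
        response function itself is always written for an increase.
    onset
        ``immediate``, or ``delayed`` with ``latency`` occasions of no
        effect at the start of the intervention phase.
    latency
        L, number of intervention-phase occasions before the effect begins.
        0 is synonymous with an immediate onset.
    progression
        ``abrupt`` (step to a constant) or ``gradual`` (ramp 1, 2, 3, ...).
    duration
        ``permanent`` (effect lasts to the end of the phase) or
        ``temporary`` for ``effect_duration`` occasions.
    effect_duration
        d, occasions the effect lasts before wearing off (temporary only).
    offset
        How a temporary gradual effect ends: ``abrupt`` (drop to 0),
        ``gradual`` (decay by 1 per occasion, the default, mirroring the
        ramp), or ``asymptote`` (hold at the peak; an upper plateau rather
        than a loss of the effect).  Ignored for abrupt progressions, which
        simply step back to 0.
    baseline_trend
        Add an overall linear trend 1..n to the whole vector, modelling
        expected spontaneous improvement.
    custom
        User-supplied intervention-phase constants overriding the built-in
        patterns (baseline stays 0; values are truncated to the candidate
        phase length).
    """

    aim: Aim = "increase"
    onset: Onset = "immediate"
    latency: int = 0
    progression: Progression = "abrupt"
    duration: Duration = "permanent"
    effect_duration: int | None = None
    offset: Offset = "gradual"
    baseline_trend: bool = False
    custom: UserResponseValues | None = None

    def __post_init__(self) -> None:
        if self.aim not in ("increase", "decrease"):
            raise ValueError(f"unknown aim {self.aim!r}")
        if self.onset not in ("immediate", "delayed"):
            raise ValueError(f"unknown onset {self.onset!r}")
        if self.progression not in ("abrupt", "gradual"):
            raise ValueError(f"unknown progression {self.progression!r}")
        if self.duration not in ("permanent", "temporary"):
            raise ValueError(f"unknown duration {self.duration!r}")
        if self.offset not in ("abrupt", "gradual", "asymptote"):
            raise ValueError(f"unknown offset {self.offset!r}")
        if self.latency < 0:
            raise ValueError("latency must be >= 0")
        if self.onset == "immediate" and self.latency != 0:
            raise ValueError("immediate onset implies latency 0")
        if self.onset == "delayed" and self.latency < 1:
            raise ValueError("delayed onset requires latency >= 1")
        if self.duration == "temporary":
            if self.effect_duration is None or self.effect_duration < 1:
                raise ValueError("temporary effects require effect_duration >= 1")

    def with_(self, **changes) -> "EffectSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ResponseFunction:
    """Predicted-response constants aligned to measurement occasions.

    ``mask`` flags the occasions that take part in the statistic; excluded
    occasions play the role of the NA entries of a hand-written template.
    """

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = (
            np.ones(values.size, dtype=bool)
            if self.mask is None
            else np.asarray(self.mask, dtype=bool)
        )
        if values.ndim != 1 or mask.shape != values.shape:
            raise ValueError("values and mask must be 1-d arrays of equal length")
        if int(mask.sum()) < 2:
            raise MaskError("a response function needs >= 2 included occasions")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        values.setflags(write=False)
        mask.setflags(write=False)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def included_values(self) -> np.ndarray:
        """Values at the included occasions, in occasion order."""
        return self.values[self.mask]

    @property
    def is_degenerate(self) -> bool:
        """True when the included values are all identical (no contrast)."""
        inc = self.included_values
        return bool(np.all(inc == inc[0]))


def _intervention_pattern(spec: EffectSpec, n_B: int) -> np.ndarray:
    """Intervention-phase constants for one candidate phase length."""
    if spec.custom is not None:
        if len(spec.custom) < n_B:
            raise ValueError(
                f"custom response function has {len(spec.custom)} values but the "
                f"intervention phase may be as long as {n_B} occasions"
            )
        return np.asarray(spec.custom.values[:n_B], dtype=float)

    L = spec.latency
    active = n_B - L  # occasions on which an effect can show
    if active <= 0:
        raise DegenerateDivisionError(
            f"latency {L} leaves no effect occasions in a {n_B}-occasion phase"
        )
    d = active if spec.duration == "permanent" else min(spec.effect_duration, active)

    out = np.zeros(n_B, dtype=float)
    if spec.progression == "abrupt":
        out[L : L + d] = 1.0
    else:
        ramp = np.arange(1, d + 1, dtype=float)
        out[L : L + d] = ramp
        tail = active - d
        if tail > 0:
            if spec.offset == "abrupt":
                pass  # stays 0
            elif spec.offset == "gradual":
                decay = np.maximum(d - np.arange(1, tail + 1), 0.0)
                out[L + d : n_B] = decay
            else:  # asymptote: hold the peak
                out[L + d : n_B] = float(d)
    return out


def build_rf(spec: EffectSpec, n_A: int, n_B: int) -> ResponseFunction:
    """Build the response function for a candidate division (n_A, n_B).

    The vector has ``n_A`` baseline zeros followed by the intervention-phase
    pattern implied by ``spec``; if ``spec.baseline_trend`` is set, the
    overall trend 1..n is added element-wise afterwards.  The function is
    rebuilt from scratch for every candidate division because phase lengths
    change the pattern (a ramp runs to the end of whichever phase is tried).

    Raises
    ------
    DegenerateDivisionError
        When the latency swallows the whole intervention phase, leaving an
        all-zero (constant) vector.  The randomization engine converts this
        into a conventioned statistic of 0 rather than dropping the division.
    """
    if n_A < 1 or n_B < 1:
        raise ValueError("both phases need at least one occasion")
    values = np.concatenate([np.zeros(n_A), _intervention_pattern(spec, n_B)])
    rf = ResponseFunction(values=values)
    if spec.custom is None and rf.is_degenerate:
        raise DegenerateDivisionError("response function is constant for this division")
    if spec.baseline_trend:
        rf = add_linear_trend(rf)
    return rf


def add_linear_trend(rf: ResponseFunction) -> ResponseFunction:
    """Add an overall linear trend to a response function.

    The k-th *included* occasion gets +k, so with no masking this is the
    1..n trend added to the whole vector.  Masked occasions stay masked.
    """
    values = rf.values.copy()
    idx = np.flatnonzero(rf.mask)
    values[idx] += np.arange(1, idx.size + 1)
    return ResponseFunction(values=values, mask=rf.mask)


def apply_mask(rf: ResponseFunction, excluded: Iterable[int]) -> ResponseFunction:
    """Exclude the given 1-based occasions from the statistic.

    Masking narrows the comparison to a window of interest, e.g. the last
    three occasions of each phase, without touching the data file.
    """
    mask = rf.mask.copy()
    for occ in excluded:
        if not 1 <= occ <= rf.n:
            raise MaskError(f"occasion {occ} outside 1..{rf.n}")
        mask[occ - 1] = False
    if int(mask.sum()) < 2:
        raise MaskError("mask would leave fewer than 2 included occasions")
    return ResponseFunction(values=rf.values, mask=mask)


def alternation_rf(labels: Iterable[str]) -> ResponseFunction:
    """0/1 coding of a two-condition alternation (ATD) label sequence.

    The first condition in alphabetical order is coded 0, the other 1; with
    contiguous A-then-B labels this reduces to the immediate-abrupt-permanent
    phase coding.
    """
    labels = [str(l).upper() for l in labels]
    distinct = sorted(set(labels))
    if len(distinct) != 2:
        raise UnsupportedDesignError(
            f"alternation coding requires exactly 2 conditions, got {distinct}"
        )
    values = np.array([0.0 if l == distinct[0] else 1.0 for l in labels])
    return ResponseFunction(values=values)
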