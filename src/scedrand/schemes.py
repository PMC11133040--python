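"""Randomization schemes: the admissible data divisions of a design.

A randomization test is valid only when the divisions used to build the
reference distribution mirror the random assignment actually performed.
Four enumerable schemes are supported:

* AB phase design with a randomly chosen intervention start point,
* multiple-baseline designs randomized by tier order alone (Wampold–Worsham)
  or by tier order and per-tier start point (Koehler–Levin),
* ABAB (withdrawal/reversal) designs with random phase-change points,
* alternating treatments designs with block randomization.

Each scheme can enumerate its divisions, count them in closed form (the two
must agree), and draw one uniformly at random.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations, product
from typing import Union

import numpy as np

from .errors import DesignError

__all__ = [
    "ABStartScheme",
    "MultipleBaselineScheme",
    "ABABScheme",
    "ATDScheme",
    "ABDivision",
    "MBDivision",
    "ABABDivision",
    "ATDDivision",
    "enumerate_ab",
    "enumerate_mb",
    "enumerate_abab",
    "enumerate_atd",
    "enumerate_divisions",
    "count_randomizations",
    "draw_random_assignment",
]


# ---------------------------------------------------------------------------
# Divisions


@dataclass(frozen=True, order=True)
class ABDivision:
    """An AB division: the 1-based occasion at which the intervention starts."""

    start: int

    @property
    def n_A(self) -> int:
        return self.start - 1


@dataclass(frozen=True, order=True)
class MBDivision:
    """A multiple-baseline division.

    ``starts`` gives the intervention start occasion of each tier (tier
    order as in the data); ``order`` records which staggered position each
    tier received, so divisions remain distinct even when candidate start
    sets overlap across positions.
    """

    starts: tuple[int, ...]
    order: tuple[int, ...]


@dataclass(frozen=True, order=True)
class ABABDivision:
    """An ABAB division: the first occasion of each phase after the first."""

    change_points: tuple[int, ...]

    def phase_lengths(self, n: int) -> tuple[int, ...]:
        bounds = (1,) + self.change_points + (n + 1,)
        return tuple(b - a for a, b in zip(bounds[:-1], bounds[1:]))


@dataclass(frozen=True, order=True)
class ATDDivision:
    """An ATD division: the condition letter of every occasion."""

    labels: tuple[str, ...]


DataDivision = Union[ABDivision, MBDivision, ABABDivision, ATDDivision]


# ---------------------------------------------------------------------------
# Schemes


@dataclass(frozen=True)
class ABStartScheme:
    """Random intervention start point for a two-phase (A-B) design.

    Admissible baseline lengths a satisfy
    ``min_A <= a <= min(max_A, n - min_B)``; the intervention then starts at
    occasion a + 1.  ``max_A`` defaults to no upper bound beyond ``n - min_B``.
    """

    n: int
    min_A: int = 1
    max_A: int | None = None
    min_B: int = 1

    def __post_init__(self) -> None:
        if self.min_A < 1 or self.min_B < 1:
            raise DesignError("minimum phase lengths must be >= 1")
        if not self.baseline_lengths():
            raise DesignError(
                f"no admissible divisions: n={self.n}, baseline "
                f"{self.min_A}..{self.max_A}, intervention >= {self.min_B}"
            )

    def baseline_lengths(self) -> list[int]:
        hi = self.n - self.min_B
        if self.max_A is not None:
            hi = min(hi, self.max_A)
        return list(range(self.min_A, hi + 1))


@dataclass(frozen=True)
class MultipleBaselineScheme:
    """Randomization of a multiple-baseline design across ``t`` tiers.

    variant ``"WW"`` (Wampold–Worsham): the staggered start points are fixed
    and only the assignment of tiers to start points is random, giving t!
    divisions.  ``start_points`` is then one start occasion per staggered
    position.

    variant ``"KL"`` (Koehler–Levin): the tier order is random and each
    staggered position additionally draws its start from a candidate set,
    giving t! x prod(set sizes) divisions.  ``start_points`` is then one
    candidate tuple per position.
    """

    variant: str
    t: int
    start_points: tuple

    def __post_init__(self) -> None:
        if self.variant not in ("WW", "KL"):
            raise DesignError(f"unknown multiple-baseline variant {self.variant!r}")
        if self.t < 1:
            raise DesignError("number of tiers must be >= 1")
        if len(self.start_points) != self.t:
            raise DesignError("need one start point (set) per tier")
        if self.variant == "KL":
            sets = [tuple(s) for s in self.start_points]
            if any(len(s) == 0 for s in sets):
                raise DesignError("KL candidate start sets must be non-empty")
            flat = [x for s in sets for x in s]
            if len(set(flat)) < len(flat):
                warnings.warn(
                    "candidate start sets overlap across positions; divisions "
                    "with identical start tuples are kept distinct by tier order",
                    stacklevel=2,
                )
            object.__setattr__(self, "start_points", tuple(sets))
        else:
            object.__setattr__(
                self, "start_points", tuple(int(s) for s in self.start_points)
            )


@dataclass(frozen=True)
class ABABScheme:
    """Random phase-change points for a withdrawal design with I phases."""

    n: int
    I: int = 4
    k: int = 1

    def __post_init__(self) -> None:
        if self.I < 2 or self.I % 2 != 0:
            raise DesignError("number of phases must be an even number >= 2")
        if self.k < 1:
            raise DesignError("minimal phase length must be >= 1")
        if self.n < self.I * self.k:
            raise DesignError(
                f"series of {self.n} cannot hold {self.I} phases of >= {self.k}"
            )


@dataclass(frozen=True)
class ATDScheme:
    """Block randomization for an alternating treatments design.

    Each of the ``b`` blocks holds the two conditions once, in either order,
    so the series has n = 2b occasions and 2^b admissible sequences.
    """

    b: int
    conditions: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.b < 1:
            raise DesignError("need at least one block")
        if len(set(self.conditions)) != 2:
            raise DesignError("need exactly two distinct conditions")

    @property
    def n(self) -> int:
        return 2 * self.b


Scheme = Union[ABStartScheme, MultipleBaselineScheme, ABABScheme, ATDScheme]


# ---------------------------------------------------------------------------
# Enumeration


def enumerate_ab(scheme: ABStartScheme) -> list[ABDivision]:
    """All admissible AB divisions, ascending by baseline length."""
    return [ABDivision(start=a + 1) for a in scheme.baseline_lengths()]


def enumerate_mb(scheme: MultipleBaselineScheme) -> list[MBDivision]:
    """All admissible multiple-baseline divisions.

    A division assigns staggered position ``order[i]`` (and its start point)
    to tier i; KL schemes additionally choose one start per position.
    """
    out: list[MBDivision] = []
    if scheme.variant == "WW":
        for perm in permutations(range(scheme.t)):
            starts = tuple(scheme.start_points[p] for p in perm)
            out.append(MBDivision(starts=starts, order=perm))
    else:
        for perm in permutations(range(scheme.t)):
            candidate_sets = [scheme.start_points[p] for p in perm]
            for choice in product(*candidate_sets):
                out.append(MBDivision(starts=tuple(choice), order=perm))
    return out


def enumerate_abab(scheme: ABABScheme) -> list[ABABDivision]:
    """All ordered change-point tuples leaving every phase >= k occasions."""
    n, I, k = scheme.n, scheme.I, scheme.k
    slack = n - I * k  # free occasions to distribute over the I phases
    out = []
    # stars and bars: each choice of I-1 bars among slack + I - 1 slots
    # splits the slack into I nonnegative extras, one per phase
    for bars in combinations(range(slack + I - 1), I - 1):
        prev = -1
        extras = []
        for bpos in bars:
            extras.append(bpos - prev - 1)
            prev = bpos
        lengths = [k + e for e in extras]  # phases 1..I-1; last phase implied
        cps = []
        pos = 1
        for length in lengths:
            pos += length
            cps.append(pos)
        out.append(ABABDivision(change_points=tuple(cps)))
    out.sort()
    return out


def enumerate_atd(scheme: ATDScheme) -> list[ATDDivision]:
    """All 2^b condition sequences (each block AB or BA)."""
    a, b = scheme.conditions
    out = []
    for flips in product((False, True), repeat=scheme.b):
        labels: list[str] = []
        for flip in flips:
            labels.extend((b, a) if flip else (a, b))
        out.append(ATDDivision(labels=tuple(labels)))
    return out


def enumerate_divisions(scheme: Scheme) -> list[DataDivision]:
    """Enumerate the admissible divisions of any supported scheme."""
    if isinstance(scheme, ABStartScheme):
        return enumerate_ab(scheme)
    if isinstance(scheme, MultipleBaselineScheme):
        return enumerate_mb(scheme)
    if isinstance(scheme, ABABScheme):
        return enumerate_abab(scheme)
    if isinstance(scheme, ATDScheme):
        return enumerate_atd(scheme)
    raise TypeError(f"not a randomization scheme: {scheme!r}")


def count_randomizations(scheme: Scheme) -> int:
    """Closed-form size of the randomization distribution.

    Always equals ``len(enumerate_divisions(scheme))``; the test needs at
    least 20 divisions for a p value as small as 0.05 to be attainable.
    """
    if isinstance(scheme, ABStartScheme):
        return len(scheme.baseline_lengths())
    if isinstance(scheme, MultipleBaselineScheme):
        count = math.factorial(scheme.t)
        if scheme.variant == "KL":
            for s in scheme.start_points:
                count *= len(s)
        return count
    if isinstance(scheme, ABABScheme):
        return math.comb(scheme.n - scheme.I * scheme.k + scheme.I - 1, scheme.I - 1)
    if isinstance(scheme, ATDScheme):
        return 2**scheme.b
    raise TypeError(f"not a randomization scheme: {scheme!r}")


def draw_random_assignment(
    scheme: Scheme, seed: int | np.random.Generator
) -> DataDivision:
    """Draw one division uniformly at random (the design-stage randomization)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    divisions = enumerate_divisions(scheme)
    if not divisions:
        raise DesignError("scheme admits no divisions")
    return divisions[int(rng.integers(len(divisions)))]
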