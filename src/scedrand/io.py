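"""Reading and writing the plain-text dialects used for single-case data.

A single-case dataset is a two-column whitespace- (or tab-) delimited text
file with a header row naming the columns ``phase`` and ``score`` in either
order.  ``phase`` holds condition letters (``A``/``B`` for phase designs,
free letters for alternation designs) and ``score`` the numeric measurement
of the target behavior, one row per measurement occasion in temporal order.

A user-defined response function is a one-line file of comma-separated
numbers giving the predicted response for the intervention phase, one number
per possible intervention occasion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ParseError

__all__ = [
    "SCEDSeries",
    "UserResponseValues",
    "read_sced_file",
    "write_sced_file",
    "read_user_rf",
]


@dataclass(frozen=True)
class SCEDSeries:
    """An ordered series of measurement occasions with condition labels.

    Parameters
    ----------
    labels
        Per-occasion condition letter, upper-case.  For phase-design
        operations the labels must form one contiguous block of ``A``
        followed by one contiguous block of ``B``; alternation designs
        accept any two-letter pattern.
    scores
        Per-occasion numeric measurements, same length as ``labels``.

    Notes
    -----
    Measurement occasions are implicitly numbered 1..n in row order, so
    "the intervention starts at occasion 10" means ``n_A == 9``.
    """

    labels: tuple[str, ...]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(str(l).upper() for l in self.labels)
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if len(labels) != scores.size:
            raise ValueError(
                f"labels ({len(labels)}) and scores ({scores.size}) differ in length"
            )
        if scores.size < 2:
            raise ValueError("a series needs at least 2 measurement occasions")
        if not np.all(np.isfinite(scores)):
            bad = int(np.flatnonzero(~np.isfinite(scores))[0]) + 1
            raise ValueError(f"non-finite score at occasion {bad}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "scores", scores)
        scores.setflags(write=False)

    @property
    def n(self) -> int:
        """Total number of measurement occasions."""
        return len(self.labels)

    @property
    def occasions(self) -> np.ndarray:
        """1-based session indices."""
        return np.arange(1, self.n + 1)

    @property
    def is_contiguous_ab(self) -> bool:
        """True when labels are a block of A followed by a block of B."""
        lab = self.labels
        if set(lab) != {"A", "B"}:
            return False
        first_b = lab.index("B")
        return first_b >= 1 and all(l == "B" for l in lab[first_b:])

    def _require_phase_design(self) -> int:
        if not self.is_contiguous_ab:
            raise ValueError(
                "phase-design operation requires contiguous A-then-B labels; "
                f"got {''.join(self.labels)}"
            )
        return self.labels.index("B")

    @property
    def n_A(self) -> int:
        """Baseline phase length (contiguous A-B series only)."""
        return self._require_phase_design()

    @property
    def n_B(self) -> int:
        """Intervention phase length (contiguous A-B series only)."""
        return self.n - self._require_phase_design()


@dataclass(frozen=True)
class UserResponseValues:
    """User-defined response-function constants for the intervention phase.

    The vector must be at least as long as the longest admissible
    intervention phase; shorter candidate phases use a truncated prefix.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 1:
            raise ValueError("a response function needs at least one value")
        if not all(np.isfinite(vals)):
            raise ValueError("response-function values must be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


def read_sced_file(path: str | Path) -> SCEDSeries:
    """Read a two-column ``phase``/``score`` text file into a series.

    The delimiter is any run of whitespace or a single tab; the header row is
    mandatory and the two columns may appear in either order.  Trailing blank
    lines are ignored.  Scores must all be numeric; a non-numeric score is
    reported with its (1-based) data row number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file contains no data") from None
    cols = {c.strip().lower(): c for c in df.columns}
    if "phase" not in cols or "score" not in cols:
        raise FormatError(
            f"{path}: expected columns 'phase' and 'score', found {list(df.columns)}"
        )
    df = df.dropna(how="all")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    labels = [str(v).strip().upper() for v in df[cols["phase"]]]
    scores = np.empty(len(df), dtype=float)
    for i, raw in enumerate(df[cols["score"]]):
        try:
            scores[i] = float(raw)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric score {raw!r} at data row {i + 1}"
            ) from None
    return SCEDSeries(labels=tuple(labels), scores=scores)


def write_sced_file(series: SCEDSeries, path: str | Path) -> None:
    """Write a series in the two-column dialect read by :func:`read_sced_file`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("phase\tscore\n")
        for lab, score in zip(series.labels, series.scores):
            fh.write(f"{lab}\t{score:g}\n")


def read_user_rf(path: str | Path) -> UserResponseValues:
    """Read a one-line comma-separated response-function file."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if len(lines) == 0:
        raise EmptyInputError(f"{path}: file is empty")
    if len(lines) > 1:
        raise FormatError(
            f"{path}: expected a single line of comma-separated numbers, "
            f"found {len(lines)} non-empty lines"
        )
    values = []
    for pos, tok in enumerate(lines[0].split(","), start=1):
        tok = tok.strip()
        try:
            values.append(float(tok))
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric value {tok!r} at position {pos}"
            ) from None
    return UserResponseValues(values=tuple(values))
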