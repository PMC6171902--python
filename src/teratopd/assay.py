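"""In vivo tumorigenicity assay data model and descriptive summaries.

The assay transplants graded doses of cells into immunodeficient mice and
palpates weekly for tumor nodules over a fixed observation horizon
(16 weeks by default).  This module holds the per-animal records and the
descriptive quantities derived from them: caliper tumor volume, per-line
tumor incidence, group latency, and the tied rank ordering of cell lines
used downstream for rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import EmptyInputError, ValidationError

#: Default observation horizon in weeks; animals tumor-free at the horizon
#: count as non-responders.
OBSERVATION_WEEKS = 16


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding, which maps 0.5 to 0;
    incidence percentages and dose estimates are conventionally reported
    with halves rounded up (away from zero for negatives).
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement of a subcutaneous tumor.

    Length and width are recorded as measured; width may exceed length.
    """

    animal_id: str
    week: int
    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValidationError(f"week must be >= 0, got {self.week}")
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValidationError(
                f"tumor dimensions must be positive, got "
                f"length={self.length_mm}, width={self.width_mm}"
            )

    @property
    def volume_mm3(self) -> float:
        return tumor_volume(self.length_mm, self.width_mm)


@dataclass(frozen=True)
class AnimalOutcome:
    """Terminal outcome for one inoculated animal."""

    animal_id: str
    line_id: str
    dose: int
    tumor_formed: bool
    first_palpable_week: Optional[int] = None
    observation_weeks: int = OBSERVATION_WEEKS

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValidationError(f"dose must be non-negative, got {self.dose}")
        if self.tumor_formed:
            if self.first_palpable_week is None:
                raise ValidationError(
                    f"animal {self.animal_id}: tumor_formed requires first_palpable_week"
                )
            if not (0 <= self.first_palpable_week <= self.observation_weeks):
                raise ValidationError(
                    f"animal {self.animal_id}: first_palpable_week "
                    f"{self.first_palpable_week} outside [0, {self.observation_weeks}]"
                )
        elif self.first_palpable_week is not None:
            raise ValidationError(
                f"animal {self.animal_id}: first_palpable_week set without tumor_formed"
            )


@dataclass(frozen=True)
class LineSummary:
    """Per-line tumorigenicity variables: incidence percent and latency."""

    line_id: str
    n_animals: int
    n_tumor: int
    incidence_pct: int
    latency_weeks: Optional[int]


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume, ``0.5 * length * width**2`` in mm^3.

    The standard two-dimension external estimate for subcutaneous xenografts.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValidationError(
            f"tumor dimensions must be positive, got length={length_mm}, width={width_mm}"
        )
    return 0.5 * length_mm * width_mm**2


def incidence_percent(n_tumor: int, n_animals: int) -> int:
    """Tumor incidence as an integer percent, halves rounded away from zero."""
    if n_animals < 1:
        raise ValidationError("incidence undefined for zero animals")
    if not 0 <= n_tumor <= n_animals:
        raise ValidationError(
            f"n_tumor must lie in [0, n_animals], got {n_tumor}/{n_animals}"
        )
    return round_half_away(100.0 * n_tumor / n_animals)


def group_latency(outcomes: Sequence[AnimalOutcome]) -> Optional[int]:
    """Latency of a dose group: earliest week any animal's tumor was palpable.

    Returns ``None`` when no animal in the group formed a tumor.  All
    outcomes must belong to one cell line.
    """
    if len(outcomes) == 0:
        raise EmptyInputError("group_latency requires at least one outcome")
    lines = {o.line_id for o in outcomes}
    if len(lines) > 1:
        raise ValidationError(f"outcomes span multiple lines: {sorted(lines)}")
    weeks = [o.first_palpable_week for o in outcomes if o.tumor_formed]
    if not weeks:
        return None
    return min(weeks)  # type: ignore[type-var]


def summarize_lines(outcomes: Iterable[AnimalOutcome]) -> list[LineSummary]:
    """Collapse per-animal outcomes into per-line incidence and latency."""
    by_line: dict[str, list[AnimalOutcome]] = {}
    for o in outcomes:
        by_line.setdefault(o.line_id, []).append(o)
    if not by_line:
        raise EmptyInputError("no outcomes supplied")
    summaries = []
    for line_id in sorted(by_line):
        group = by_line[line_id]
        n_tumor = sum(o.tumor_formed for o in group)
        summaries.append(
            LineSummary(
                line_id=line_id,
                n_animals=len(group),
                n_tumor=n_tumor,
                incidence_pct=incidence_percent(n_tumor, len(group)),
                latency_weeks=group_latency(group),
            )
        )
    return summaries


@dataclass(frozen=True)
class RankOrder:
    """Tied ranking of cell lines by one tumorigenicity variable.

    ``classes`` lists tie classes from first to last in the sort direction;
    ``midranks`` carries the average rank of each line (ties share their
    midrank), which is the quantity rank correlation consumes.
    """

    classes: tuple[tuple[str, ...], ...]
    midranks: Mapping[str, float]
    direction: str


def rank_lines(
    values: Mapping[str, float], direction: str = "ascending"
) -> RankOrder:
    """Order lines by value into tie classes and assign midranks.

    Lines with equal values share a tie class and the midrank of the
    positions the class occupies.  Midranks over n lines always sum to
    n(n+1)/2 regardless of ties.
    """
    if direction not in ("ascending", "descending"):
        raise ValidationError(f"unknown direction {direction!r}")
    if not values:
        raise EmptyInputError("rank_lines requires at least one line")
    for line, v in values.items():
        if not math.isfinite(v):
            raise ValidationError(f"non-finite value for line {line!r}: {v}")

    reverse = direction == "descending"
    ordered = sorted(values, key=lambda k: values[k], reverse=reverse)
    classes: list[tuple[str, ...]] = []
    midranks: dict[str, float] = {}
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and values[ordered[j]] == values[ordered[i]]:
            j += 1
        tied = tuple(sorted(ordered[i:j]))
        classes.append(tied)
        mid = (i + 1 + j) / 2.0  # positions i+1 .. j
        for line in tied:
            midranks[line] = mid
        i = j
    return RankOrder(classes=tuple(classes), midranks=midranks, direction=direction)
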