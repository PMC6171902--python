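"""Spearman-Karber estimation of the 50% tumor-producing dose (TPD50).

The TPD50 is the quantal-bioassay median: the cell dose at which half of
the inoculated animals develop a tumor.  On an equally spaced log10 dose
grid with response proportions p_1 .. p_k, the Spearman-Karber estimator of
the log10 median dose is

    m = x_k + d/2 - d * sum_i p_i

with x_k the log10 of the highest dose and d the grid spacing.  Its
variance is

    Var(m) = d^2 * sum_i p_i (1 - p_i) / n_i

and the 95% CI is m +/- 1.96 sqrt(Var(m)), exponentiated back to cells.

The estimator requires the response to span 0% to 100%.  When a tested
series does not, a single dummy dose group one 10-fold step below (0%
incidence) or above (100% incidence) the tested range is appended before
estimation; dummy groups carry p in {0, 1} and therefore contribute
nothing to the variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .assay import round_half_away
from .errors import (
    DegenerateDesignError,
    EmptyInputError,
    GridError,
    UnextendedSeriesError,
    ValidationError,
)

#: Tolerance on the equality of consecutive log10 dose spacings.
GRID_TOL = 1e-9


@dataclass(frozen=True)
class DoseGroup:
    """One quantal dose group: ``n_tumor`` responders of ``n_animals`` at ``dose``."""

    dose: float
    n_animals: int
    n_tumor: int

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValidationError(f"dose must be positive, got {self.dose}")
        if self.n_animals < 1:
            raise ValidationError(f"n_animals must be >= 1, got {self.n_animals}")
        if not 0 <= self.n_tumor <= self.n_animals:
            raise ValidationError(
                f"n_tumor must lie in [0, n_animals], got {self.n_tumor}/{self.n_animals}"
            )

    @property
    def p(self) -> float:
        """Observed response proportion."""
        return self.n_tumor / self.n_animals

    @property
    def log_dose(self) -> float:
        return math.log10(self.dose)


@dataclass(frozen=True)
class DoseSeries:
    """Quantal dose groups sorted on an equally spaced log10 grid.

    Dose-0 control groups must be excluded before construction (log of zero
    is undefined; controls carry no information for the median-dose
    estimator).  ``extended_low``/``extended_high`` flag dummy groups added
    by :func:`extend_series`.
    """

    groups: tuple[DoseGroup, ...]
    extended_low: bool = False
    extended_high: bool = False

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise EmptyInputError("a dose series needs at least one group")
        object.__setattr__(self, "groups", tuple(self.groups))
        doses = [g.dose for g in self.groups]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValidationError("dose groups must be sorted by strictly increasing dose")
        logs = self.log_doses
        if len(logs) >= 3:
            spacings = [b - a for a, b in zip(logs, logs[1:])]
            if max(spacings) - min(spacings) > GRID_TOL:
                raise GridError(
                    f"doses are not on an equally spaced log10 grid: spacings {spacings}"
                )

    @property
    def log_doses(self) -> tuple[float, ...]:
        return tuple(g.log_dose for g in self.groups)

    @property
    def d(self) -> float:
        """Common log10 spacing between consecutive doses."""
        if len(self.groups) < 2:
            raise DegenerateDesignError("spacing undefined for a single dose group")
        return self.log_doses[1] - self.log_doses[0]

    @property
    def proportions(self) -> tuple[float, ...]:
        return tuple(g.p for g in self.groups)

    @property
    def spans_full_response(self) -> bool:
        return self.groups[0].n_tumor == 0 and self.groups[-1].p == 1.0

    @classmethod
    def from_counts(
        cls, rows: Iterable[tuple[float, int, int]], drop_controls: bool = True
    ) -> "DoseSeries":
        """Build a series from ``(dose, n_animals, n_tumor)`` rows.

        Rows with dose 0 are control groups and are dropped by default.
        """
        groups = []
        for dose, n, k in rows:
            if dose == 0:
                if drop_controls:
                    continue
                raise ValidationError("dose-0 control groups cannot enter a series")
            groups.append(DoseGroup(dose=dose, n_animals=n, n_tumor=k))
        if not groups:
            raise EmptyInputError("no non-control dose groups supplied")
        return cls(groups=tuple(sorted(groups, key=lambda g: g.dose)))


@dataclass(frozen=True)
class PotencyEstimate:
    """Spearman-Karber TPD50 estimate with variance and normal-theory CI.

    All internal quantities live on the log10-dose scale; ``tpd50`` and
    ``ci_dose`` are back-transformed to cells per animal.
    """

    m: float
    var_m: float
    z: float
    extended_low: bool
    extended_high: bool
    n_groups: int
    n_animals: int

    @property
    def tpd50(self) -> float:
        return 10.0**self.m

    @property
    def se_m(self) -> float:
        return math.sqrt(self.var_m)

    @property
    def ci_log(self) -> tuple[float, float]:
        half = self.z * self.se_m
        return (self.m - half, self.m + half)

    @property
    def ci_dose(self) -> tuple[float, float]:
        lo, hi = self.ci_log
        return (10.0**lo, 10.0**hi)

    @property
    def tpd50_rounded(self) -> int:
        return round_half_away(self.tpd50)

    @property
    def ci_rounded(self) -> tuple[int, int]:
        lo, hi = self.ci_dose
        return (round_half_away(lo), round_half_away(hi))


def extend_series(series: DoseSeries) -> DoseSeries:
    """Apply the dummy-dose extension so the series spans 0% to 100%.

    If the lowest tested dose shows any responders, one dummy group is
    prepended a single 10-fold step below with 0% incidence; if the highest
    tested dose shows any non-responders, one dummy group is appended a
    10-fold step above with 100% incidence.  Dummy groups inherit the group
    size of the adjacent tested group.  A series already spanning the full
    response is returned unchanged.  At most one step is added per side.
    """
    groups = list(series.groups)
    if len(groups) >= 2:
        step = 10.0 ** series.d
    else:
        step = 10.0
    extended_low = series.extended_low
    extended_high = series.extended_high
    if groups[0].n_tumor > 0:
        low = groups[0]
        groups.insert(0, DoseGroup(dose=low.dose / step, n_animals=low.n_animals, n_tumor=0))
        extended_low = True
    if groups[-1].p < 1.0:
        high = groups[-1]
        groups.append(
            DoseGroup(dose=high.dose * step, n_animals=high.n_animals, n_tumor=high.n_animals)
        )
        extended_high = True
    out = DoseSeries(
        groups=tuple(groups), extended_low=extended_low, extended_high=extended_high
    )
    if not out.spans_full_response:
        raise UnextendedSeriesError(
            "series still does not span 0% to 100% after a one-step extension "
            "on each side; the estimator is not applicable to this design"
        )
    return out


def spearman_karber(series: DoseSeries, z: float = 1.96) -> PotencyEstimate:
    """Spearman-Karber log10-median-dose estimate for an extended series.

    The series must already span 0% (lowest dose) to 100% (highest dose)
    response; apply :func:`extend_series` first if it does not.
    """
    if len(series.groups) < 2:
        raise DegenerateDesignError(
            "the Spearman-Karber estimator needs at least two dose groups"
        )
    if not series.spans_full_response:
        raise UnextendedSeriesError(
            "series must span 0% to 100% response; apply extend_series first"
        )
    d = series.d
    x_k = series.log_doses[-1]
    ps = series.proportions
    m = x_k + d / 2.0 - d * sum(ps)
    var_m = d**2 * sum(g.p * (1.0 - g.p) / g.n_animals for g in series.groups)
    return PotencyEstimate(
        m=m,
        var_m=var_m,
        z=z,
        extended_low=series.extended_low,
        extended_high=series.extended_high,
        n_groups=len(series.groups),
        n_animals=sum(g.n_animals for g in series.groups),
    )


def estimate_tpd50(
    rows: Iterable[tuple[float, int, int]], z: float = 1.96, extend: bool = True
) -> PotencyEstimate:
    """Convenience wrapper: counts -> series -> extension -> estimate."""
    series = DoseSeries.from_counts(rows)
    if extend:
        series = extend_series(series)
    return spearman_karber(series, z=z)


def tpd50_ratio(a: PotencyEstimate, b: PotencyEstimate) -> float:
    """Fold difference between two potency estimates, ``a.tpd50 / b.tpd50``,
    reported to one decimal."""
    return round(a.tpd50 / b.tpd50, 1)
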