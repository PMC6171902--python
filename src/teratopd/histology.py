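"""Teratoma specimen records and group comparison of immaturity grades.

Teratomas are graded 0-3 by the amount of immature neuroepithelium in the
specimen (O'Connor-Norris system); grade 0 is a fully mature teratoma.
Grades across cell-line groups are compared with the tie-corrected
Kruskal-Wallis rank test, with an exact permutation p-value available for
the small group sizes typical of teratoma assays.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, ValidationError

log = logging.getLogger(__name__)

GERM_LAYER_CLASSES = ("two_layers", "three_layers")


@dataclass(frozen=True)
class TeratomaRecord:
    """One excised tumor specimen with size, germ-layer class, and grade."""

    line_id: str
    specimen_no: int
    volume_mm3: float
    week: int
    germ_layers: str
    grade: int
    two_layer_pair: Optional[str] = None

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2, 3):
            raise ValidationError(
                f"grade must be 0-3, got {self.grade} "
                f"(specimen {self.line_id} #{self.specimen_no})"
            )
        if self.germ_layers not in GERM_LAYER_CLASSES:
            raise ValidationError(
                f"germ_layers must be one of {GERM_LAYER_CLASSES}, got {self.germ_layers!r}"
            )
        if self.volume_mm3 <= 0:
            raise ValidationError(f"volume must be positive, got {self.volume_mm3}")


@dataclass(frozen=True)
class GradeComparison:
    """Tie-corrected Kruskal-Wallis statistic across cell-line groups."""

    H: float
    df: int
    p_value: float
    method: str


def classify_maturity(record: TeratomaRecord) -> str:
    """A teratoma is mature only at grade 0; any immature neuroepithelium
    (grade >= 1) makes it an immature teratoma."""
    return "mature" if record.grade == 0 else "immature"


def _kw_statistic(ranks: np.ndarray, sizes: Sequence[int], tie_factor: float) -> float:
    """Tie-corrected H from pooled midranks split into consecutive groups."""
    n = ranks.size
    h = 0.0
    start = 0
    for size in sizes:
        mean_rank = ranks[start : start + size].mean()
        h += size * mean_rank**2
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_factor


def _tie_factor(pooled: np.ndarray) -> float:
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return float(correction)


def kruskal_wallis(
    grades: Mapping[str, Sequence[int]],
    method: str = "chi2",
    max_exact_n: int = 14,
    n_resamples: int = 20000,
    seed: Optional[int] = None,
) -> GradeComparison:
    """Kruskal-Wallis comparison of grades across cell-line groups.

    Parameters
    ----------
    grades
        Mapping of line id to that line's specimen grades.  Empty groups
        are dropped with a warning; at least two non-empty groups are
        required.  Groups of a single specimen are retained (the statistic
        is defined for n_j = 1).
    method
        ``"chi2"`` (default) uses the chi-square approximation with
        df = groups - 1.  ``"permutation"`` computes the p-value from the
        permutation distribution of H over reassignments of the pooled
        grades to groups: exhaustive when the pooled sample is at most
        ``max_exact_n``, otherwise ``n_resamples`` Monte-Carlo draws
        (``seed`` required in that case).

    Notes
    -----
    When every pooled grade is identical the statistic is defined as
    H = 0 with p = 1 (the tie correction is degenerate there).
    """
    groups = []
    for line_id, values in grades.items():
        if len(values) == 0:
            log.warning("dropping line %s: no specimens", line_id)
            continue
        groups.append((line_id, [int(v) for v in values]))
    if len(groups) < 2:
        raise DegenerateDesignError(
            "Kruskal-Wallis needs at least two non-empty groups"
        )
    df = len(groups) - 1
    pooled = np.concatenate([np.asarray(v, dtype=float) for _, v in groups])
    sizes = [len(v) for _, v in groups]

    if np.all(pooled == pooled[0]):
        return GradeComparison(H=0.0, df=df, p_value=1.0, method=method)

    tie_factor = _tie_factor(pooled)
    ranks = stats.rankdata(pooled)
    h_obs = _kw_statistic(ranks, sizes, tie_factor)

    if method == "chi2":
        # matches scipy.stats.kruskal (cross-checked in the test suite)
        p = float(stats.chi2.sf(h_obs, df))
    elif method == "permutation":
        p = _permutation_p(ranks, sizes, tie_factor, h_obs, max_exact_n, n_resamples, seed)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return GradeComparison(H=float(h_obs), df=df, p_value=p, method=method)


def _permutation_p(
    ranks: np.ndarray,
    sizes: Sequence[int],
    tie_factor: float,
    h_obs: float,
    max_exact_n: int,
    n_resamples: int,
    seed: Optional[int],
) -> float:
    n = ranks.size
    tol = 1e-9
    if n <= max_exact_n:
        count = 0
        total = 0
        indices = frozenset(range(n))
        # enumerate distinct assignments of observations to groups
        def recurse(remaining: frozenset, group_idx: int) -> None:
            nonlocal count, total
            if group_idx == len(sizes) - 1:
                perm_ranks = _gather(ranks, remaining, sizes, assignment)
                h = _kw_statistic(perm_ranks, sizes, tie_factor)
                total += 1
                if h >= h_obs - tol:
                    count += 1
                return
            for combo in itertools.combinations(sorted(remaining), sizes[group_idx]):
                assignment.append(combo)
                recurse(remaining - set(combo), group_idx + 1)
                assignment.pop()

        assignment: list[tuple[int, ...]] = []
        recurse(indices, 0)
        return count / total
    if seed is None:
        raise ValidationError("Monte-Carlo permutation p-value requires a seed")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        h = _kw_statistic(rng.permutation(ranks), sizes, tie_factor)
        if h >= h_obs - tol:
            count += 1
    return (count + 1) / (n_resamples + 1)


def _gather(
    ranks: np.ndarray,
    last_group: frozenset,
    sizes: Sequence[int],
    assignment: Sequence[Sequence[int]],
) -> np.ndarray:
    order: list[int] = []
    for combo in assignment:
        order.extend(combo)
    order.extend(sorted(last_group))
    return ranks[np.asarray(order, dtype=int)]


def grades_by_line(records: Sequence[TeratomaRecord]) -> dict[str, list[int]]:
    """Group specimen grades by cell line, preserving first-seen line order."""
    out: dict[str, list[int]] = {}
    for r in records:
        out.setdefault(r.line_id, []).append(r.grade)
    return out


def count_mature(records: Sequence[TeratomaRecord]) -> int:
    """Number of fully mature (grade 0) specimens."""
    return sum(classify_maturity(r) == "mature" for r in records)
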