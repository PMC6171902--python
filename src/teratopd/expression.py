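"""Probe selection correlating expression with tumorigenicity variables.

A three-stage cascade over a probes x samples intensity matrix
(MAS5-normalized scale, 10 cell lines x 3 replicates by default):

1. detection-call filter - keep only probes called "present" in every
   sample ("marginal" counts as absent);
2. one-way ANOVA filter - keep probes whose intensity differs among cell
   lines at p < 0.05;
3. rank-correlation selection - collapse replicates to per-line means and
   keep probes whose Spearman correlation with BOTH per-line tumorigenicity
   variables (latency of tumor formation, tumor incidence) is significant
   at p < 0.01, in either direction.

The cascade is strictly nested: selected probes are a subset of the
ANOVA-retained probes, which are a subset of the present-retained probes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, ValidationError

log = logging.getLogger(__name__)

PRESENT = "P"
ABSENT = "A"
MARGINAL = "M"

DEFAULT_ALPHA_ANOVA = 0.05
DEFAULT_ALPHA_CORR = 0.01


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe x sample intensities with detection calls and a sample->line map.

    ``intensities`` and ``calls`` are probes-by-samples DataFrames with
    identical index/columns; ``sample_to_line`` maps each sample column to
    its cell line.  Every line must carry the same number of replicates.
    """

    intensities: pd.DataFrame
    calls: pd.DataFrame
    sample_to_line: pd.Series

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.calls.index) or not (
            self.intensities.columns.equals(self.calls.columns)
        ):
            raise ValidationError("intensities and calls must share index and columns")
        missing = set(self.intensities.columns) - set(self.sample_to_line.index)
        if missing:
            raise ValidationError(f"samples without a line assignment: {sorted(missing)}")
        bad = set(np.unique(self.calls.to_numpy())) - {PRESENT, ABSENT, MARGINAL}
        if bad:
            raise ValidationError(f"unknown detection calls: {sorted(bad)}")
        counts = self.sample_to_line.loc[self.intensities.columns].value_counts()
        if counts.nunique() > 1:
            raise ValidationError(
                f"unequal replicate counts per line: {counts.to_dict()}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.intensities.columns:
            seen.setdefault(self.sample_to_line[s], None)
        return list(seen)

    def samples_of(self, line: str) -> list[str]:
        return [s for s in self.intensities.columns if self.sample_to_line[s] == line]


@dataclass(frozen=True)
class TumorigenicityVariables:
    """Per-line latency (weeks) and incidence (percent)."""

    latency_weeks: Mapping[str, int]
    incidence_pct: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.latency_weeks) != set(self.incidence_pct):
            raise ValidationError("latency and incidence must cover the same lines")

    @property
    def lines(self) -> list[str]:
        return list(self.latency_weeks)


@dataclass(frozen=True)
class ProbeAssociation:
    """Spearman association of one probe with both tumorigenicity variables."""

    probe_id: str
    rho_latency: float
    p_latency: float
    rho_incidence: float
    p_incidence: float
    selected: bool = False
    reason: Optional[str] = None


def present_filter(matrix: ExpressionMatrix) -> list[str]:
    """Probes called present in every sample; marginal counts as absent."""
    mask = (matrix.calls == PRESENT).all(axis=1)
    return list(matrix.calls.index[mask])


def anova_filter(
    matrix: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA_ANOVA,
    probes: Optional[Sequence[str]] = None,
) -> list[str]:
    """Probes whose intensity differs among cell lines (one-way ANOVA p < alpha).

    Probes with zero variance everywhere (constant intensity) carry no
    between-line signal and are eliminated with a logged note.
    """
    lines = matrix.lines
    if len(lines) < 2:
        raise DegenerateDesignError("ANOVA filter needs at least two lines")
    sub = matrix.intensities if probes is None else matrix.intensities.loc[list(probes)]
    groups = [sub[matrix.samples_of(line)].to_numpy().T for line in lines]
    if min(g.shape[0] for g in groups) < 2:
        raise DegenerateDesignError("ANOVA filter needs at least two replicates per line")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        warnings.simplefilter("ignore", stats.DegenerateDataWarning)
        _, pvals = stats.f_oneway(*groups, axis=0)
    pvals = np.asarray(pvals)
    constant = np.isnan(pvals)
    if constant.any():
        log.info("eliminating %d constant probes from the ANOVA filter", constant.sum())
    keep = (~constant) & (pvals < alpha)
    return list(sub.index[keep])


def per_line_summary(
    matrix: ExpressionMatrix, probes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Arithmetic mean of replicate intensities per line (lines x probes)."""
    sub = matrix.intensities if probes is None else matrix.intensities.loc[list(probes)]
    grouped = sub.T.groupby(matrix.sample_to_line.loc[sub.columns])
    means = grouped.mean()
    return means.loc[matrix.lines]


def _spearman(
    x: np.ndarray, y: np.ndarray, method: str, n_perm: int, rng: Optional[np.random.Generator]
) -> tuple[float, float]:
    rho, p = stats.spearmanr(x, y)
    if method == "permutation":
        if rng is None:
            raise ValidationError("permutation p-values require a seed")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        for _ in range(n_perm):
            r = abs(np.corrcoef(rx, rng.permutation(ry))[0, 1])
            if r >= obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return float(rho), float(p)


def spearman_assoc(
    summary: pd.DataFrame,
    variables: TumorigenicityVariables,
    method: str = "t",
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> list[ProbeAssociation]:
    """Spearman rho and p of each probe's per-line means against both variables.

    Ties in either variable or the probe summary are handled by midranks.
    ``method="t"`` (default) uses the two-sided t approximation with
    n - 2 degrees of freedom; ``method="permutation"`` draws ``n_perm``
    seeded permutations of the line labels.  A probe whose per-line means
    are constant has no defined rank correlation and is flagged with a
    reason instead of a p-value.
    """
    lines = list(summary.index)
    missing = set(lines) - set(variables.lines)
    if missing:
        raise ValidationError(f"variables missing for lines: {sorted(missing)}")
    if len(lines) < 4:
        raise DegenerateDesignError("rank correlation needs at least 4 lines")
    lat = np.array([variables.latency_weeks[l] for l in lines], dtype=float)
    inc = np.array([variables.incidence_pct[l] for l in lines], dtype=float)
    for name, var in (("latency", lat), ("incidence", inc)):
        if np.all(var == var[0]):
            raise ValidationError(f"{name} is constant across lines")
    rng = np.random.default_rng(seed) if seed is not None else None

    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        for probe in summary.columns:
            y = summary[probe].to_numpy(dtype=float)
            if np.all(y == y[0]):
                out.append(
                    ProbeAssociation(
                        probe_id=probe,
                        rho_latency=float("nan"),
                        p_latency=float("nan"),
                        rho_incidence=float("nan"),
                        p_incidence=float("nan"),
                        selected=False,
                        reason="constant per-line summary",
                    )
                )
                continue
            rho_l, p_l = _spearman(y, lat, method, n_perm, rng)
            rho_i, p_i = _spearman(y, inc, method, n_perm, rng)
            out.append(
                ProbeAssociation(
                    probe_id=probe,
                    rho_latency=rho_l,
                    p_latency=p_l,
                    rho_incidence=rho_i,
                    p_incidence=p_i,
                )
            )
    return out


def select_correlated(
    assocs: Sequence[ProbeAssociation], alpha: float = DEFAULT_ALPHA_CORR
) -> list[ProbeAssociation]:
    """Mark probes significant against BOTH variables at p < alpha.

    Either sign of correlation qualifies.  Returns new association records
    with the ``selected`` flag set.
    """
    out = []
    for a in assocs:
        if a.reason is not None:
            out.append(a)
            continue
        sel = bool(a.p_latency < alpha and a.p_incidence < alpha)
        out.append(replace(a, selected=sel))
    return out


def selected_probe_ids(assocs: Sequence[ProbeAssociation]) -> list[str]:
    return [a.probe_id for a in assocs if a.selected]


def collapse_to_genes(
    probe_ids: Sequence[str], probe_to_gene: Mapping[str, str]
) -> list[str]:
    """Collapse selected probes to unique gene symbols (sorted).

    Probes absent from the map are dropped with a logged warning.
    """
    genes: set[str] = set()
    for p in probe_ids:
        g = probe_to_gene.get(p)
        if g is None:
            log.warning("probe %s has no gene mapping; dropped from gene list", p)
            continue
        genes.add(g)
    return sorted(genes)


def run_selection(
    matrix: ExpressionMatrix,
    variables: TumorigenicityVariables,
    alpha_anova: float = DEFAULT_ALPHA_ANOVA,
    alpha_corr: float = DEFAULT_ALPHA_CORR,
    method: str = "t",
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> tuple[list[str], list[str], list[ProbeAssociation]]:
    """Full cascade: present filter -> ANOVA filter -> dual rank correlation.

    Returns (present-retained, ANOVA-retained, associations with selection
    flags); the selected probes are those flagged in the third element.
    """
    present = present_filter(matrix)
    retained = anova_filter(matrix, alpha=alpha_anova, probes=present)
    summary = per_line_summary(matrix, probes=retained)
    assocs = spearman_assoc(summary, variables, method=method, n_perm=n_perm, seed=seed)
    assocs = select_correlated(assocs, alpha=alpha_corr)
    return present, retained, assocs
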