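"""Synthetic-data generators with known ground truth for every stage.

Three generators emulate the assay's data layers:

* quantal dose-response cohorts under a one-hit tumor-initiation model,
  P(tumor | dose D) = 1 - exp(-ln2 * D / TPD50), so that half of the
  animals respond exactly at the true TPD50;
* replicate expression matrices (10 lines x 3 replicates by default) with
  a configurable number of probes planted to track a latent tumorigenicity
  score, defined as the rank-standardized average of (-latency rank,
  incidence rank) so planted probes correlate with both selection
  variables;
* annotated variant tables constructed arm by arm (records built to fail
  exactly one triage criterion, plus records built to pass all of them),
  so the triage output can be checked against construction counts.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assay import AnimalOutcome
from .errors import ValidationError
from .expression import ABSENT, PRESENT, ExpressionMatrix, TumorigenicityVariables
from .potency import DoseGroup, DoseSeries
from .variants import CancerGeneList, VariantRecord

#: Ten-fold dose design used throughout: 1e1..1e4 cells/animal.
DEFAULT_DOSES = (1e1, 1e2, 1e3, 1e4)
#: Latency span (weeks) observed across lines; simulated first-palpable
#: weeks are drawn uniformly from this range.
LATENCY_SPAN = (4, 9)


def one_hit_probability(dose: float, tpd50: float) -> float:
    """One-hit response probability; equals 0.5 at dose == tpd50."""
    return 1.0 - math.exp(-math.log(2.0) * dose / tpd50)


@dataclass(frozen=True)
class DoseResponseTruth:
    """Ground truth for a simulated quantal cohort."""

    true_tpd50: float
    doses: tuple[float, ...] = DEFAULT_DOSES
    n_per_dose: int = 10
    model: str = "one_hit"

    def __post_init__(self) -> None:
        if self.true_tpd50 <= 0:
            raise ValidationError("true_tpd50 must be positive")
        if any(d <= 0 for d in self.doses):
            raise ValidationError("doses must be positive")
        if self.n_per_dose < 1:
            raise ValidationError("n_per_dose must be >= 1")
        if self.model not in ("one_hit", "logistic"):
            raise ValidationError(f"unknown model {self.model!r}")

    def probability(self, dose: float) -> float:
        if self.model == "one_hit":
            return one_hit_probability(dose, self.true_tpd50)
        # logistic in log10 dose, unit slope, centered at the true TPD50
        return 1.0 / (1.0 + math.exp(-(math.log10(dose) - math.log10(self.true_tpd50)) / 0.25))


def simulate_dose_response(
    truth: DoseResponseTruth, seed: int, line_id: str = "synthetic"
) -> tuple[DoseSeries, list[AnimalOutcome]]:
    """Draw per-animal Bernoulli outcomes under the dose-response truth.

    Tumor-bearing animals get a first-palpable week uniform over the
    observed latency span (4-9 weeks).
    """
    rng = np.random.default_rng(seed)
    groups = []
    outcomes = []
    for dose in truth.doses:
        p = truth.probability(dose)
        formed = rng.random(truth.n_per_dose) < p
        weeks = rng.integers(LATENCY_SPAN[0], LATENCY_SPAN[1] + 1, truth.n_per_dose)
        for i in range(truth.n_per_dose):
            outcomes.append(
                AnimalOutcome(
                    animal_id=f"{line_id}-d{dose:g}-{i + 1}",
                    line_id=line_id,
                    dose=int(dose),
                    tumor_formed=bool(formed[i]),
                    first_palpable_week=int(weeks[i]) if formed[i] else None,
                )
            )
        groups.append(
            DoseGroup(dose=dose, n_animals=truth.n_per_dose, n_tumor=int(formed.sum()))
        )
    return DoseSeries(groups=tuple(groups)), outcomes


def tumorigenicity_score(variables: TumorigenicityVariables) -> pd.Series:
    """Latent per-line tumorigenicity: standardized mean of the rank of
    (-latency) and the rank of incidence.

    High score = early, frequent tumors.  Ties in the variables propagate
    as midranks.
    """
    lines = variables.lines
    lat = np.array([variables.latency_weeks[l] for l in lines], dtype=float)
    inc = np.array([variables.incidence_pct[l] for l in lines], dtype=float)
    composite = (stats.rankdata(-lat) + stats.rankdata(inc)) / 2.0
    z = (composite - composite.mean()) / composite.std(ddof=0)
    return pd.Series(z, index=lines)


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted-probe ground truth for a simulated expression matrix."""

    n_probes: int = 2000
    n_planted: int = 100
    effect_size: float = 3.0
    sigma: float = 50.0
    baseline: float = 500.0
    present_rate: float = 0.96
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.n_planted <= self.n_probes:
            raise ValidationError("n_planted must lie in [0, n_probes]")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not 0.0 <= self.present_rate <= 1.0:
            raise ValidationError("present_rate must lie in [0, 1]")

    @property
    def planted_probe_ids(self) -> tuple[str, ...]:
        return tuple(f"planted_{i:05d}" for i in range(self.n_planted))

    @property
    def null_probe_ids(self) -> tuple[str, ...]:
        return tuple(f"null_{i:05d}" for i in range(self.n_probes - self.n_planted))


def simulate_expression(
    truth: ExpressionTruth, variables: TumorigenicityVariables, seed: int
) -> ExpressionMatrix:
    """Simulate a replicate intensity matrix with planted correlated probes.

    Planted probes have per-line means ``baseline + effect_size * sigma *
    score`` with the standardized latent tumorigenicity score; null probes
    share the baseline mean.  Replicate noise is i.i.d. normal(0, sigma).
    Planted probes are always called present (they model genes expressed
    in every line); null probes are present independently with
    ``present_rate`` per sample.
    """
    rng = np.random.default_rng(seed)
    score = tumorigenicity_score(variables)
    lines = list(score.index)
    reps = truth.n_replicates
    samples = [f"{line}_r{r + 1}" for line in lines for r in range(reps)]
    sample_to_line = pd.Series(
        [line for line in lines for _ in range(reps)], index=samples
    )
    probe_ids = list(truth.planted_probe_ids) + list(truth.null_probe_ids)

    means = np.full((len(probe_ids), len(samples)), truth.baseline)
    score_per_sample = np.repeat(score.to_numpy(), reps)
    means[: truth.n_planted, :] += truth.effect_size * truth.sigma * score_per_sample

    intensities = means + rng.normal(0.0, truth.sigma, size=means.shape)
    calls = np.where(
        rng.random(size=means.shape) < truth.present_rate, PRESENT, ABSENT
    )
    calls[: truth.n_planted, :] = PRESENT

    return ExpressionMatrix(
        intensities=pd.DataFrame(intensities, index=probe_ids, columns=samples),
        calls=pd.DataFrame(calls, index=probe_ids, columns=samples),
        sample_to_line=sample_to_line,
    )


#: Arms of the variant-triage cascade a synthetic record can be built to fail.
VARIANT_ARMS = ("pass_all", "fail_vaf", "fail_depth", "fail_impact", "fail_gene", "fail_cosmic")


@dataclass(frozen=True)
class VariantTruth:
    """Requested per-arm record counts for one or more lines.

    ``counts`` maps line id -> arm -> count; every arm name must come from
    :data:`VARIANT_ARMS`.
    """

    counts: Mapping[str, Mapping[str, int]]
    vaf_threshold: float = 0.09
    depth_threshold: int = 40

    def __post_init__(self) -> None:
        for line, arms in self.counts.items():
            for arm, k in arms.items():
                if arm not in VARIANT_ARMS:
                    raise ValidationError(f"unknown arm {arm!r} for line {line}")
                if k < 0:
                    raise ValidationError(f"negative count for {line}/{arm}")


def make_gene_list(n: int = 613, seed: int = 0) -> CancerGeneList:
    """A synthetic cancer-gene list of ``n`` placeholder symbols.

    Stands in for a curated Cancer Gene Census-style list when only the
    list's size and set semantics matter.
    """
    del seed  # symbols are deterministic; kept for interface symmetry
    return CancerGeneList.from_symbols(f"CGC{i:04d}" for i in range(n))


def _draw_vaf(rng: np.random.Generator, threshold: float, above: bool) -> float:
    """Beta(2,5) draw rescaled to the required side of the VAF threshold."""
    b = rng.beta(2.0, 5.0)
    if above:
        v = threshold + (1.0 - threshold) * b
        return min(1.0, max(v, np.nextafter(threshold, 1.0)))
    return threshold * b


def _draw_depth(rng: np.random.Generator, threshold: int, at_least: bool) -> int:
    if at_least:
        # Poisson(150) mass below 40 is negligible; clip for safety
        return int(max(threshold, rng.poisson(150)))
    # conditioning Poisson(150) below 40 is numerically degenerate;
    # a uniform draw below the threshold models shallow off-target sites
    return int(rng.integers(5, threshold))


def simulate_variants(
    truth: VariantTruth, genes: CancerGeneList, seed: int
) -> list[VariantRecord]:
    """Construct annotated variant records arm by arm.

    Records in the ``pass_all`` arm satisfy every triage criterion by
    construction; each ``fail_*`` arm breaks exactly its own criterion and
    satisfies the rest, so the surviving count per line must equal the
    requested ``pass_all`` count.
    """
    rng = np.random.default_rng(seed)
    listed = sorted(genes.symbols)
    if not listed:
        raise ValidationError("the gene list is empty")
    records = []
    counter = 0
    for line in sorted(truth.counts):
        for arm in VARIANT_ARMS:
            for _ in range(truth.counts[line].get(arm, 0)):
                counter += 1
                vaf = _draw_vaf(rng, truth.vaf_threshold, above=arm != "fail_vaf")
                depth = _draw_depth(rng, truth.depth_threshold, at_least=arm != "fail_depth")
                if arm == "fail_impact":
                    impact = str(rng.choice(["LOW", "MODIFIER"]))
                else:
                    impact = str(rng.choice(["HIGH", "MODERATE"]))
                if arm == "fail_gene":
                    gene = f"NOTLISTED{counter:05d}"
                else:
                    gene = str(listed[int(rng.integers(len(listed)))])
                cosmic = () if arm == "fail_cosmic" else (f"COSM{counter:07d}",)
                ref, alt = (str(b) for b in rng.choice(list("ACGT"), 2, replace=False))
                records.append(
                    VariantRecord(
                        line_id=line,
                        chrom=f"chr{int(rng.integers(1, 23))}",
                        pos=int(rng.integers(1, 200_000_000)),
                        ref=ref,
                        alt=alt,
                        gene_symbol=gene,
                        vaf=float(vaf),
                        depth=depth,
                        impact=impact,
                        cosmic_ids=cosmic,
                    )
                )
    return records


def default_variant_truth(
    lines: Sequence[str],
    seed: int,
    pass_range: tuple[int, int] = (61, 77),
    fail_per_arm: int = 25,
) -> VariantTruth:
    """Per-line arm counts with pass-all counts drawn from ``pass_range``."""
    rng = np.random.default_rng(seed)
    counts = {}
    for line in lines:
        arms: dict[str, int] = {arm: fail_per_arm for arm in VARIANT_ARMS if arm != "pass_all"}
        arms["pass_all"] = int(rng.integers(pass_range[0], pass_range[1] + 1))
        counts[line] = arms
    return VariantTruth(counts=counts)
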