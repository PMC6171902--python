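"""End-to-end pipeline over the plain-text inputs, with a run report.

Stages run in a fixed order (potency -> summaries -> grades -> probe
selection -> variant triage); a stage executes only when its inputs are
configured.  Each stage writes its outputs under the run directory and
contributes in/out record counts to the run report, which also echoes the
configuration, the package version, and wall-clock timestamps.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, io
from .assay import summarize_lines
from .errors import TeratopdError
from .expression import run_selection, selected_probe_ids
from .histology import count_mature, grades_by_line, kruskal_wallis
from .potency import extend_series, spearman_karber
from .variants import filter_variants, line_overlap, per_line_gene_summary

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input paths and thresholds for one pipeline run.

    Threshold defaults match the analysis conventions documented in each
    stage's module.
    """

    outcomes: Optional[str] = None
    measurements: Optional[str] = None
    incidence: Optional[str] = None
    specimens: Optional[str] = None
    expr: Optional[str] = None
    calls: Optional[str] = None
    samples: Optional[str] = None
    variables: Optional[str] = None
    variants: Optional[str] = None
    genes: Optional[str] = None
    alpha_anova: float = 0.05
    alpha_corr: float = 0.01
    vaf_min: float = 0.09
    depth_min: int = 40
    z: float = 1.96
    seed: Optional[int] = None
    outdir: str = "teratopd_run"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TeratopdError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(TeratopdError):
    """A pipeline stage failed; the stage name prefixes the message."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; return the run report dict.

    Outputs land in ``config.outdir``; the report is also written there as
    ``run_report.json``.  Any stage failure aborts the run with a
    stage-named error after writing a failure marker next to the partial
    outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.as_dict()
    report: dict = {
        "version": __version__,
        "config": cfg,
        "config_hash": io.config_hash(cfg),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            counts = fn()
        except Exception as exc:
            (outdir / "FAILED").write_text(f"{name}: {exc}\n")
            raise StageError(f"stage {name}: {exc}") from exc
        counts["seconds"] = round(time.perf_counter() - t0, 3)
        report["stages"][name] = counts
        log.info("stage %s done: %s", name, counts)

    if config.incidence:
        run_stage("tpd50", lambda: _stage_tpd50(config, outdir, cfg))
    if config.outcomes:
        run_stage("summarize", lambda: _stage_summarize(config, outdir, cfg))
    if config.specimens:
        run_stage("grades", lambda: _stage_grades(config, outdir, cfg))
    if config.expr and config.calls and config.samples and config.variables:
        run_stage("correlate", lambda: _stage_correlate(config, outdir, cfg))
    if config.variants and config.genes:
        run_stage("filter_variants", lambda: _stage_variants(config, outdir, cfg))

    report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    io.write_json_with_header(outdir / "run_report.json", report, cfg)
    return report


def _stage_tpd50(config: RunConfig, outdir: Path, cfg: dict) -> dict:
    series = io.read_dose_table(config.incidence)
    rows = []
    for label, s in series.items():
        est = spearman_karber(extend_series(s), z=config.z)
        rows.append(io.potency_to_dict(label, est))
    io.write_tsv_with_header(outdir / "tpd50.tsv", pd.DataFrame(rows), cfg)
    return {"series_in": len(series), "estimates_out": len(rows)}


def _stage_summarize(config: RunConfig, outdir: Path, cfg: dict) -> dict:
    outcomes = io.read_outcomes_csv(config.outcomes)
    summaries = summarize_lines(outcomes)
    df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    if config.measurements:
        meas = io.read_measurements_csv(config.measurements)
        vol = meas.groupby("line_id")["volume_mm3"].max().rename("max_volume_mm3")
        df = df.merge(vol, on="line_id", how="left")
    io.write_tsv_with_header(outdir / "line_summaries.tsv", df, cfg)
    return {"animals_in": len(outcomes), "lines_out": len(summaries)}


def _stage_grades(config: RunConfig, outdir: Path, cfg: dict) -> dict:
    records = io.read_specimens_csv(config.specimens)
    grades = grades_by_line(records)
    comparison = kruskal_wallis(grades)
    payload = {
        "n_specimens": len(records),
        "n_mature": count_mature(records),
        "n_immature": len(records) - count_mature(records),
        "H": comparison.H,
        "df": comparison.df,
        "p_value": comparison.p_value,
        "method": comparison.method,
    }
    io.write_json_with_header(outdir / "grades.json", payload, cfg)
    return {"specimens_in": len(records), "groups": len(grades)}


def _stage_correlate(config: RunConfig, outdir: Path, cfg: dict) -> dict:
    matrix = io.read_expression(config.expr, config.calls, config.samples)
    variables = io.read_variables_csv(config.variables)
    present, retained, assocs = run_selection(
        matrix,
        variables,
        alpha_anova=config.alpha_anova,
        alpha_corr=config.alpha_corr,
        seed=config.seed,
    )
    df = pd.DataFrame([dataclasses.asdict(a) for a in assocs])
    io.write_tsv_with_header(outdir / "probe_associations.tsv", df, cfg)
    n_selected = len(selected_probe_ids(assocs))
    if not (n_selected <= len(retained) <= len(present) <= len(matrix.probe_ids)):
        raise TeratopdError("cascade subset relation violated")  # pragma: no cover
    return {
        "probes_in": len(matrix.probe_ids),
        "present_retained": len(present),
        "anova_retained": len(retained),
        "selected": n_selected,
    }


def _stage_variants(config: RunConfig, outdir: Path, cfg: dict) -> dict:
    records = io.read_variants_tsv(config.variants)
    genes = io.read_gene_list(config.genes)
    result = filter_variants(
        records, genes, vaf_min=config.vaf_min, depth_min=config.depth_min
    )
    io.write_variants_tsv(outdir / "variants_surviving.tsv", result.surviving)
    summary = per_line_gene_summary(result)
    payload = {
        "counts": result.counts,
        "genes_per_line": summary,
    }
    if len(summary) >= 2:
        payload["jaccard"] = line_overlap(summary).round(4).to_dict()
    io.write_json_with_header(outdir / "variant_summary.json", payload, cfg)
    return {"variants_in": len(records), "variants_surviving": len(result.surviving)}
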