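"""Readers and writers for the plain-text interchange formats.

All tabular inputs are small CSV/TSV files; VCF is supported only at the
variant-ingest boundary.  Outputs written by the pipeline carry a comment
header with the package version and a hash of the run configuration so
re-runs are attributable.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .assay import AnimalOutcome, TumorMeasurement
from .errors import ValidationError
from .expression import ExpressionMatrix, TumorigenicityVariables
from .histology import TeratomaRecord
from .potency import DoseSeries, PotencyEstimate
from .variants import IMPACT_RANK, CancerGeneList, VariantRecord

PathLike = Union[str, Path]


def _read_table(path: PathLike, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # surface file context
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------- assay I/O

def read_outcomes_csv(path: PathLike) -> list[AnimalOutcome]:
    df = _read_table(path, ",")
    _require_columns(df, ["animal_id", "line_id", "dose", "tumor_formed"], path)
    outcomes = []
    for idx, row in df.iterrows():
        week = row.get("first_palpable_week")
        has_week = week is not None and not (isinstance(week, float) and math.isnan(week))
        try:
            outcomes.append(
                AnimalOutcome(
                    animal_id=str(row["animal_id"]),
                    line_id=str(row["line_id"]),
                    dose=int(row["dose"]),
                    tumor_formed=bool(int(row["tumor_formed"])),
                    first_palpable_week=int(week) if has_week else None,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}, row {idx + 2}: {exc}") from exc
    return outcomes


def write_outcomes_csv(path: PathLike, outcomes: Iterable[AnimalOutcome]) -> None:
    rows = [
        {
            "animal_id": o.animal_id,
            "line_id": o.line_id,
            "dose": o.dose,
            "tumor_formed": int(o.tumor_formed),
            "first_palpable_week": o.first_palpable_week,
        }
        for o in outcomes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_measurements_csv(path: PathLike) -> pd.DataFrame:
    """Weekly caliper measurements with derived volume (mm^3) per row."""
    from .assay import tumor_volume

    df = _read_table(path, ",")
    _require_columns(df, ["animal_id", "line_id", "week", "length_mm", "width_mm"], path)
    for idx, row in df.iterrows():
        try:
            TumorMeasurement(
                animal_id=str(row["animal_id"]),
                week=int(row["week"]),
                length_mm=float(row["length_mm"]),
                width_mm=float(row["width_mm"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {idx + 2}: {exc}") from exc
    df = df.copy()
    df["volume_mm3"] = [
        tumor_volume(l, w) for l, w in zip(df["length_mm"], df["width_mm"])
    ]
    return df


# -------------------------------------------------------------- potency I/O

def read_dose_table(path: PathLike) -> dict[str, DoseSeries]:
    """Dose-incidence CSV (group_label, dose, n_animals, n_tumor) -> series.

    Dose-0 control rows are dropped before building each log-grid series.
    """
    df = _read_table(path, ",")
    _require_columns(df, ["group_label", "dose", "n_animals", "n_tumor"], path)
    series = {}
    for label, sub in df.groupby("group_label", sort=False):
        rows = [
            (float(r["dose"]), int(r["n_animals"]), int(r["n_tumor"]))
            for _, r in sub.iterrows()
        ]
        series[str(label)] = DoseSeries.from_counts(rows)
    return series


def write_dose_table(
    path: PathLike, series: dict[str, Sequence[tuple[float, int, int]]]
) -> None:
    rows = []
    for label, counts in series.items():
        for dose, n, k in counts:
            rows.append(
                {"group_label": label, "dose": dose, "n_animals": n, "n_tumor": k}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def potency_to_dict(label: str, est: PotencyEstimate) -> dict:
    lo, hi = est.ci_dose
    lo_r, hi_r = est.ci_rounded
    return {
        "group_label": label,
        "m_log10": est.m,
        "tpd50": est.tpd50,
        "tpd50_rounded": est.tpd50_rounded,
        "var_m": est.var_m,
        "z": est.z,
        "ci_lower": lo,
        "ci_upper": hi,
        "ci_lower_rounded": lo_r,
        "ci_upper_rounded": hi_r,
        "extended_low": est.extended_low,
        "extended_high": est.extended_high,
        "n_groups": est.n_groups,
        "n_animals": est.n_animals,
    }


# ------------------------------------------------------------ histology I/O

_LAYER_ALIASES = {
    "three_layers": "three_layers",
    "three": "three_layers",
    "two_layers": "two_layers",
    "ectoderm/mesoderm": "two_layers",
    "em": "two_layers",
}


def read_specimens_csv(path: PathLike) -> list[TeratomaRecord]:
    df = _read_table(path, ",")
    _require_columns(
        df, ["line_id", "specimen_no", "volume_mm3", "week", "germ_layers", "grade"], path
    )
    records = []
    for idx, row in df.iterrows():
        layers_raw = str(row["germ_layers"]).strip().lower()
        layers = _LAYER_ALIASES.get(layers_raw)
        if layers is None:
            raise ValidationError(
                f"{path}, row {idx + 2}: unknown germ_layers {row['germ_layers']!r}"
            )
        try:
            records.append(
                TeratomaRecord(
                    line_id=str(row["line_id"]),
                    specimen_no=int(row["specimen_no"]),
                    volume_mm3=float(row["volume_mm3"]),
                    week=int(row["week"]),
                    germ_layers=layers,
                    grade=int(row["grade"]),
                    two_layer_pair="ectoderm/mesoderm" if layers == "two_layers" else None,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}, row {idx + 2}: {exc}") from exc
    return records


def write_specimens_csv(path: PathLike, records: Iterable[TeratomaRecord]) -> None:
    rows = [
        {
            "line_id": r.line_id,
            "specimen_no": r.specimen_no,
            "volume_mm3": r.volume_mm3,
            "week": r.week,
            "germ_layers": r.germ_layers,
            "grade": r.grade,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------------- expression I/O

def read_expression(
    expr_path: PathLike, calls_path: PathLike, samples_path: PathLike
) -> ExpressionMatrix:
    """Expression TSV + detection-call TSV + sample sheet CSV -> matrix.

    Both TSVs have probe_id as the first column and one column per sample;
    the sample sheet maps sample_id to line_id.
    """
    expr = _read_table(expr_path, "\t").set_index("probe_id")
    calls = _read_table(calls_path, "\t").set_index("probe_id")
    sheet = _read_table(samples_path, ",")
    _require_columns(sheet, ["sample_id", "line_id"], samples_path)
    mapping = pd.Series(
        sheet["line_id"].astype(str).to_numpy(), index=sheet["sample_id"].astype(str)
    )
    return ExpressionMatrix(
        intensities=expr.astype(float), calls=calls.astype(str), sample_to_line=mapping
    )


def write_expression(
    outdir: PathLike, matrix: ExpressionMatrix, prefix: str = "expression"
) -> tuple[Path, Path, Path]:
    outdir = Path(outdir)
    expr_path = outdir / f"{prefix}_intensities.tsv"
    calls_path = outdir / f"{prefix}_calls.tsv"
    samples_path = outdir / f"{prefix}_samples.csv"
    matrix.intensities.rename_axis("probe_id").to_csv(expr_path, sep="\t")
    matrix.calls.rename_axis("probe_id").to_csv(calls_path, sep="\t")
    pd.DataFrame(
        {"sample_id": matrix.sample_to_line.index, "line_id": matrix.sample_to_line.values}
    ).to_csv(samples_path, index=False)
    return expr_path, calls_path, samples_path


def read_variables_csv(path: PathLike) -> TumorigenicityVariables:
    df = _read_table(path, ",")
    _require_columns(df, ["line_id", "latency_weeks", "incidence_pct"], path)
    return TumorigenicityVariables(
        latency_weeks={str(r["line_id"]): int(r["latency_weeks"]) for _, r in df.iterrows()},
        incidence_pct={str(r["line_id"]): int(r["incidence_pct"]) for _, r in df.iterrows()},
    )


def write_variables_csv(path: PathLike, variables: TumorigenicityVariables) -> None:
    rows = [
        {
            "line_id": line,
            "latency_weeks": variables.latency_weeks[line],
            "incidence_pct": variables.incidence_pct[line],
        }
        for line in variables.lines
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_probe_gene_map(path: PathLike) -> dict[str, str]:
    df = _read_table(path, "\t")
    _require_columns(df, ["probe_id", "gene_symbol"], path)
    return {str(r["probe_id"]): str(r["gene_symbol"]) for _, r in df.iterrows()}


# -------------------------------------------------------------- variant I/O

def read_gene_list(path: PathLike) -> CancerGeneList:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    symbols = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            symbols.append(line.split("\t")[0])
    return CancerGeneList.from_symbols(symbols)


def read_variants_tsv(path: PathLike) -> list[VariantRecord]:
    df = _read_table(path, "\t")
    _require_columns(
        df, ["line_id", "chrom", "pos", "ref", "alt", "gene", "vaf", "depth", "impact"], path
    )
    records = []
    for idx, row in df.iterrows():
        cosmic_raw = row.get("cosmic_ids")
        if cosmic_raw is None or (isinstance(cosmic_raw, float) and math.isnan(cosmic_raw)):
            cosmic: tuple[str, ...] = ()
        else:
            cosmic = tuple(c for c in str(cosmic_raw).split(";") if c)
        gene = row["gene"]
        gene = "" if isinstance(gene, float) and math.isnan(gene) else str(gene)
        try:
            records.append(
                VariantRecord(
                    line_id=str(row["line_id"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    gene_symbol=gene,
                    vaf=float(row["vaf"]),
                    depth=int(row["depth"]),
                    impact=str(row["impact"]),
                    cosmic_ids=cosmic,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}, row {idx + 2}: {exc}") from exc
    return records


def write_variants_tsv(path: PathLike, records: Iterable[VariantRecord]) -> None:
    rows = [
        {
            "line_id": r.line_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene_symbol,
            "vaf": r.vaf,
            "depth": r.depth,
            "impact": r.impact,
            "cosmic_ids": ";".join(r.cosmic_ids),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf(
    path: PathLike, line_id: str, cosmic_info_key: Optional[str] = None
) -> list[VariantRecord]:
    """Minimal single-sample VCF reader for annotated variants.

    VAF comes from FORMAT ``AF`` when present, otherwise from the
    ``AD``-derived alt/total ratio; depth from FORMAT ``DP``.  Gene symbol
    and impact come from a SnpEff-style ``ANN`` INFO field, taking the
    highest-impact annotation matching each alt allele.  COSMIC ids come
    from the ID column (entries starting with ``COS``) or, when
    ``cosmic_info_key`` is given, from that INFO key.  Multi-allelic sites
    are split into one record per alt allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValidationError(
            f"{path}: expected a single-sample VCF, found {len(vcf.samples)} samples"
        )
    def fmt(variant, key):
        try:
            return variant.format(key)
        except KeyError:
            return None

    records = []
    for v in vcf:
        ann_by_allele = _parse_ann(v.INFO.get("ANN"))
        ids = [] if v.ID in (None, ".") else str(v.ID).split(";")
        cosmic = tuple(i for i in ids if i.upper().startswith("COS"))
        if cosmic_info_key is not None:
            extra = v.INFO.get(cosmic_info_key)
            if extra:
                cosmic = cosmic + tuple(str(extra).split(";"))
        depth = fmt(v, "DP")
        depth = int(depth[0][0]) if depth is not None else int(v.INFO.get("DP", 0))
        afs = fmt(v, "AF")
        for alt_idx, alt in enumerate(v.ALT):
            if afs is not None:
                vaf = float(afs[0][alt_idx if afs.shape[1] > alt_idx else 0])
            else:
                ad = fmt(v, "AD")
                if ad is None:
                    raise ValidationError(
                        f"{path}: {v.CHROM}:{v.POS} has neither AF nor AD"
                    )
                counts = ad[0]
                total = counts.sum()
                vaf = float(counts[alt_idx + 1] / total) if total > 0 else 0.0
            gene, impact = ann_by_allele.get(alt, ("", "MODIFIER"))
            records.append(
                VariantRecord(
                    line_id=line_id,
                    chrom=str(v.CHROM),
                    pos=int(v.POS),
                    ref=str(v.REF),
                    alt=str(alt),
                    gene_symbol=gene,
                    vaf=vaf,
                    depth=depth,
                    impact=impact,
                    cosmic_ids=cosmic,
                )
            )
    return records


def _parse_ann(ann: Optional[str]) -> dict[str, tuple[str, str]]:
    """ANN field -> alt allele -> (gene, highest impact)."""
    out: dict[str, tuple[str, str]] = {}
    if not ann:
        return out
    for entry in str(ann).split(","):
        fields = entry.split("|")
        if len(fields) < 4:
            continue
        allele, _, impact, gene = fields[0], fields[1], fields[2], fields[3]
        impact = impact.upper()
        if impact not in IMPACT_RANK:
            continue
        prev = out.get(allele)
        if prev is None or IMPACT_RANK[impact] < IMPACT_RANK[prev[1]]:
            out[allele] = (gene, impact)
    return out


# ------------------------------------------------------------------ headers

def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_tsv_with_header(path: PathLike, df: pd.DataFrame, config: dict) -> None:
    """TSV with a provenance comment line (version + config hash)."""
    with open(path, "w") as fh:
        fh.write(f"# teratopd {__version__} config={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_json_with_header(path: PathLike, payload: dict, config: dict) -> None:
    payload = {
        "_meta": {"version": __version__, "config_hash": config_hash(config)},
        **payload,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
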