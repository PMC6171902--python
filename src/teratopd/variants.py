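"""Cancer-gene variant triage for exome-sequenced cell lines.

Annotated variants are filtered through a fixed cascade: variant allele
fraction above 9% (strict, the reliability floor of the sequencing depth
used), read depth of at least 40 (inclusive), a HIGH or MODERATE predicted
impact on the encoded protein, membership of the gene in a curated
cancer-gene list (Cancer Gene Census style, 613 symbols), and a
variant-level match in the COSMIC catalogue.  Surviving variants are
summarized per line as unique gene sets and compared across lines with the
Jaccard index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, ValidationError

log = logging.getLogger(__name__)

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
#: Severity order used to pick the representative annotation of a variant.
IMPACT_RANK = {impact: i for i, impact in enumerate(IMPACT_CLASSES)}

DEFAULT_VAF_MIN = 0.09
DEFAULT_DEPTH_MIN = 40
DEFAULT_IMPACTS = frozenset({"HIGH", "MODERATE"})


@dataclass(frozen=True)
class VariantRecord:
    """One annotated small variant (SNV or short indel) in one cell line."""

    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str
    vaf: float
    depth: int
    impact: str
    cosmic_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(
                f"vaf must lie in [0, 1], got {self.vaf} at {self.chrom}:{self.pos}"
            )
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth}")
        if self.pos < 1:
            raise ValidationError(f"pos is 1-based, got {self.pos}")
        if self.impact not in IMPACT_CLASSES:
            raise ValidationError(
                f"unknown impact {self.impact!r} for {self.line_id} "
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"
            )


@dataclass(frozen=True)
class CancerGeneList:
    """Case-normalized set of cancer-gene symbols."""

    symbols: frozenset[str]

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "CancerGeneList":
        return cls(symbols=frozenset(s.strip().upper() for s in symbols if s.strip()))

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class TriageResult:
    """Surviving variants per line with the thresholds that produced them."""

    surviving: tuple[VariantRecord, ...]
    vaf_min: float
    depth_min: int
    impacts: frozenset[str]
    require_cosmic: bool
    n_input: int

    @property
    def by_line(self) -> dict[str, list[VariantRecord]]:
        out: dict[str, list[VariantRecord]] = {}
        for r in self.surviving:
            out.setdefault(r.line_id, []).append(r)
        return out

    @property
    def counts(self) -> dict[str, int]:
        return {line: len(rs) for line, rs in self.by_line.items()}


def passes_filter(
    record: VariantRecord,
    genes: CancerGeneList,
    vaf_min: float = DEFAULT_VAF_MIN,
    depth_min: int = DEFAULT_DEPTH_MIN,
    impacts: frozenset[str] = DEFAULT_IMPACTS,
    require_cosmic: bool = True,
) -> bool:
    """Single-record form of the triage predicate.

    VAF is compared strictly (a variant at exactly the 9% floor is
    excluded); depth inclusively.
    """
    if record.vaf <= vaf_min:
        return False
    if record.depth < depth_min:
        return False
    if record.impact not in impacts:
        return False
    if record.gene_symbol not in genes:
        return False
    if require_cosmic and len(record.cosmic_ids) == 0:
        return False
    return True


def filter_variants(
    records: Sequence[VariantRecord],
    genes: CancerGeneList,
    vaf_min: float = DEFAULT_VAF_MIN,
    depth_min: int = DEFAULT_DEPTH_MIN,
    impacts: Iterable[str] = DEFAULT_IMPACTS,
    require_cosmic: bool = True,
) -> TriageResult:
    """Apply the five-arm triage cascade to annotated variant records.

    Records without a gene symbol cannot be matched against the gene list
    and are dropped with a logged warning before filtering.
    """
    impacts = frozenset(impacts)
    unknown = impacts - set(IMPACT_CLASSES)
    if unknown:
        raise ValidationError(f"unknown impact classes requested: {sorted(unknown)}")
    usable = []
    for r in records:
        if not r.gene_symbol:
            log.warning(
                "dropping variant %s %s:%d %s>%s: missing gene symbol",
                r.line_id, r.chrom, r.pos, r.ref, r.alt,
            )
            continue
        usable.append(r)
    surviving = tuple(
        r
        for r in usable
        if passes_filter(r, genes, vaf_min, depth_min, impacts, require_cosmic)
    )
    return TriageResult(
        surviving=surviving,
        vaf_min=vaf_min,
        depth_min=depth_min,
        impacts=impacts,
        require_cosmic=require_cosmic,
        n_input=len(records),
    )


def per_line_gene_summary(result: TriageResult) -> dict[str, list[str]]:
    """Sorted unique gene symbols with surviving variants, per line."""
    out: dict[str, list[str]] = {}
    for line, recs in result.by_line.items():
        out[line] = sorted({r.gene_symbol.upper() for r in recs})
    return out


def line_overlap(summaries: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Pairwise Jaccard index of per-line gene sets.

    J(A, B) = |A n B| / |A u B|; the diagonal is 1, and two empty sets are
    defined as fully overlapping (J = 1) with a logged note.
    """
    lines = list(summaries)
    if len(lines) < 2:
        raise DegenerateDesignError("overlap needs at least two lines")
    sets = {line: set(summaries[line]) for line in lines}
    mat = np.ones((len(lines), len(lines)))
    for i, a in enumerate(lines):
        for j, b in enumerate(lines):
            if j <= i:
                continue
            union = sets[a] | sets[b]
            if not union:
                log.info("lines %s and %s both have empty gene sets; J := 1", a, b)
                j_ab = 1.0
            else:
                j_ab = len(sets[a] & sets[b]) / len(union)
            mat[i, j] = mat[j, i] = j_ab
    return pd.DataFrame(mat, index=lines, columns=lines)
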