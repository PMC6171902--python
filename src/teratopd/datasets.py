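"""Bundled reference tables for the hiPSC tumorigenicity assay.

Small worked datasets used in examples, tests, and the reproduction
script:

* three dose-incidence series for the 201B7 hiPSC line transplanted as
  clumps, as single cells on NHDF feeders, and as single cells on NHDF
  feeders with the Rho-kinase inhibitor Y-27632 (dose in cells/animal);
* per-line tumor latency and incidence for ten commonly available hiPSC
  lines inoculated at 3e4 cells/animal (6 animals per line);
* the teratoma specimen table for those lines (volume, week of excision,
  germ-layer class, immaturity grade 0-3).
"""

from __future__ import annotations

from .histology import TeratomaRecord

#: Dose-incidence rows (dose, n_animals, n_tumor) per transplantation format.
#: Dose-0 control groups are omitted (all were tumor-free); the clumps
#: format was tested from 1e2 cells, the single-cell formats from 1e1.
DOSE_SERIES: dict[str, tuple[tuple[float, int, int], ...]] = {
    "hiPSC clumps": ((1e2, 6, 2), (1e3, 6, 2), (1e4, 6, 6)),
    "Single hiPSCs/NHDF": ((1e1, 6, 0), (1e2, 6, 0), (1e3, 6, 0), (1e4, 6, 5)),
    "Single hiPSCs/NHDF + Y27632": ((1e1, 10, 0), (1e2, 10, 2), (1e3, 10, 7), (1e4, 10, 8)),
}

#: Per-line tumorigenicity variables: (latency weeks, n_animals, n_tumor).
#: Incidence percent follows as round(100 * n_tumor / n_animals).
LINE_OUTCOMES: dict[str, tuple[int, int, int]] = {
    "201B7": (6, 6, 6),
    "253G1": (4, 6, 6),
    "409B2": (5, 6, 4),
    "454E2": (4, 6, 6),
    "HiPS-RIKEN-1A": (7, 6, 6),
    "HiPS-RIKEN-2A": (6, 6, 1),
    "HiPS-RIKEN-12A": (9, 6, 4),
    "ATCC-DYR0100": (4, 6, 5),
    "ATCC-HYR0103": (9, 6, 4),
    "mc-iPS": (8, 6, 4),
}


def line_latencies() -> dict[str, int]:
    return {line: lat for line, (lat, _, _) in LINE_OUTCOMES.items()}


def line_incidences() -> dict[str, int]:
    from .assay import incidence_percent

    return {
        line: incidence_percent(k, n) for line, (_, n, k) in LINE_OUTCOMES.items()
    }


#: Teratoma specimens: (line, specimen_no, volume mm3, week, germ layers, grade).
#: "three" = all three germ layers; "em" = ectoderm/mesoderm only.
_SPECIMEN_ROWS: tuple[tuple[str, int, float, int, str, int], ...] = (
    ("201B7", 1, 1468, 16, "three", 3),
    ("201B7", 2, 1406, 16, "three", 1),
    ("201B7", 3, 2026, 14, "three", 3),
    ("201B7", 4, 648, 16, "three", 1),
    ("201B7", 5, 991, 16, "em", 3),
    ("201B7", 6, 332, 16, "three", 1),
    ("253G1", 1, 760, 16, "three", 1),
    ("253G1", 2, 139, 16, "em", 1),
    ("253G1", 3, 814, 16, "em", 1),
    ("253G1", 4, 58, 16, "three", 1),
    ("253G1", 5, 168, 16, "em", 1),
    ("253G1", 6, 1599, 13, "em", 3),
    ("409B2", 3, 244, 16, "em", 2),
    ("409B2", 4, 400, 16, "em", 3),
    ("409B2", 5, 43, 16, "three", 1),
    ("409B2", 6, 128, 16, "em", 1),
    ("454E2", 1, 2369, 15, "three", 3),
    ("454E2", 2, 2030, 11, "three", 1),
    ("454E2", 3, 804, 16, "em", 1),
    ("454E2", 4, 1592, 16, "em", 1),
    ("454E2", 5, 2319, 15, "three", 1),
    ("454E2", 6, 2021, 13, "three", 1),
    ("HiPS-RIKEN-1A", 1, 697, 16, "three", 3),
    ("HiPS-RIKEN-1A", 2, 99, 16, "three", 1),
    ("HiPS-RIKEN-1A", 3, 226, 16, "em", 3),
    ("HiPS-RIKEN-1A", 4, 273, 16, "three", 2),
    ("HiPS-RIKEN-1A", 5, 961, 16, "three", 1),
    ("HiPS-RIKEN-1A", 6, 141, 16, "three", 1),
    ("HiPS-RIKEN-2A", 6, 1603, 9, "three", 2),
    ("HiPS-RIKEN-12A", 1, 595, 16, "em", 1),
    ("HiPS-RIKEN-12A", 2, 85, 16, "three", 1),
    ("HiPS-RIKEN-12A", 5, 506, 16, "three", 3),
    ("HiPS-RIKEN-12A", 6, 49, 16, "three", 1),
    ("ATCC-DYR0100", 1, 2481, 11, "three", 3),
    ("ATCC-DYR0100", 2, 1172, 16, "three", 1),
    ("ATCC-DYR0100", 3, 2030, 8, "three", 1),
    ("ATCC-DYR0100", 4, 690, 16, "three", 1),
    ("ATCC-DYR0100", 6, 2179, 14, "three", 1),
    ("ATCC-HYR0103", 2, 2380, 11, "three", 1),
    ("ATCC-HYR0103", 3, 4218, 13, "three", 2),
    ("ATCC-HYR0103", 4, 2950, 16, "three", 2),
    ("ATCC-HYR0103", 6, 524, 16, "three", 1),
    ("mc-iPS", 2, 181, 16, "three", 0),
    ("mc-iPS", 3, 1921, 15, "three", 0),
    ("mc-iPS", 5, 1115, 16, "three", 3),
    ("mc-iPS", 6, 213, 16, "three", 1),
)


def example_line_outcomes() -> list:
    """Per-animal outcomes consistent with the per-line summary table.

    For each line, the recorded number of animals formed tumors, the
    earliest at the line's latency week and the rest at later weeks within
    the observation horizon; the remaining animals stayed tumor-free.
    Collapsing these records with :func:`teratopd.assay.summarize_lines`
    reproduces ``LINE_OUTCOMES`` exactly.
    """
    from .assay import OBSERVATION_WEEKS, AnimalOutcome

    outcomes = []
    for line, (latency, n_animals, n_tumor) in LINE_OUTCOMES.items():
        for i in range(n_animals):
            formed = i < n_tumor
            week = min(latency + 2 * i, OBSERVATION_WEEKS) if formed else None
            outcomes.append(
                AnimalOutcome(
                    animal_id=f"{line}-{i + 1}",
                    line_id=line,
                    dose=30000,
                    tumor_formed=formed,
                    first_palpable_week=week,
                )
            )
    return outcomes


def teratoma_specimens() -> list[TeratomaRecord]:
    """The bundled teratoma specimen table as validated records."""
    records = []
    for line, no, vol, week, layers, grade in _SPECIMEN_ROWS:
        records.append(
            TeratomaRecord(
                line_id=line,
                specimen_no=no,
                volume_mm3=float(vol),
                week=week,
                germ_layers="three_layers" if layers == "three" else "two_layers",
                grade=grade,
                two_layer_pair="ectoderm/mesoderm" if layers == "em" else None,
            )
        )
    return records
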