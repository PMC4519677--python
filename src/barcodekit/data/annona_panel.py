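"""Reference panel: species-specific matK primers for seven Annona species.

Published primer sequences with their reported melting temperatures (from
the Thermo Multiple Primer Analyzer convention), annealing temperatures and
expected amplicon sizes, plus the two universal barcode primer pairs.  The
panel serves two roles: it is the calibration set for the default
nearest-neighbor Tm parameters (``scripts/calibrate_tm.py``), and it drives
validation of in-silico PCR against the published amplicon sizes when the
corresponding GenBank sequences are available locally.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PanelPrimer:
    name: str
    sense: str  # F | R
    sequence: str  # 5'->3'
    tm_celsius: float | None  # as published, 1 decimal
    annealing_temp: float | None
    expected_size: int | None
    specificity: str


#: The 14 species-specific primers (7 markers) with published Tm values.
SPECIFIC_PRIMERS: tuple[PanelPrimer, ...] = (
    PanelPrimer("AChF1", "F", "GTATATGAATGTGAATCGGTATTC", 58.3, 65, 396, "Annona cherimola matK"),
    PanelPrimer("AChR1", "R", "TTGACTCCTTACTGCGGAAT", 61.7, 65, 396, "Annona cherimola matK"),
    PanelPrimer("AChReF1", "F", "GCTTCGGAATGATTTTCC", 60.1, 65, 364, "Annona reticulata matK"),
    PanelPrimer("AReR1", "R", "CGCCTTAGCCAACGATT", 61.9, 65, 364, "Annona reticulata matK"),
    PanelPrimer("ASqF1", "F", "CCATTTCCGTTTGTTCAAAC", 62.2, 69, 315, "Annona squamosa matK"),
    PanelPrimer("ASqR1", "R", "GGTAAGATTTCCATTTCTTCATC", 59.8, 69, 315, "Annona squamosa matK"),
    PanelPrimer("AMuF1", "F", "CATTTACGATCAACATCCTTTA", 58.6, 65, 332, "Annona muricata matK"),
    PanelPrimer("AMuR1", "R", "GAAGAATTTTGGCGTACACTTA", 60.2, 65, 332, "Annona muricata matK"),
    PanelPrimer("AMaF1", "F", "ATACAAGATGCTCCCTCTTTG", 60.2, 69, 644, "Annona macroprophyllata matK"),
    PanelPrimer("AMaR1", "R", "TTAGCCAATGATCCAATCATT", 61.2, 69, 644, "Annona macroprophyllata matK"),
    PanelPrimer("AGlF1", "F", "CGATCAACATCCTTTGGG", 62.1, 69, 476, "Annona glabra matK"),
    PanelPrimer("AGlR1", "R", "GCCGGCTTACTAATAGGGTT", 61.3, 69, 476, "Annona glabra matK"),
    PanelPrimer("APuF1", "F", "TTCTTGTTCCTATATAATATTCATA", 53.2, 61, 619, "Annona purpurea matK"),
    PanelPrimer("APuR1", "R", "GAGAAAGATTTCTGTATATGCGT", 58.5, 61, 619, "Annona purpurea matK"),
)

#: Universal barcode amplification primers (no published Tm).
UNIVERSAL_PRIMERS: tuple[PanelPrimer, ...] = (
    PanelPrimer("3F_kim", "F", "CGTACAGTACTTTTGTGTTTACGAG", None, 52, None, "Universal matK"),
    PanelPrimer("1R_kim", "R", "ACCCAGTCCATCTGGAAATCTTGGTTC", None, 52, None, "Universal matK"),
    PanelPrimer("rbcLa_F", "F", "ATGTCACCACAAACAGAGACTAAAGC", None, 55, None, "Universal rbcL"),
    PanelPrimer("rbcLa_R", "R", "GTAAAATCAAGTCCACCRCG", None, 55, None, "Universal rbcL"),
)

#: Published multiplex groups: annealing temperature -> expected band sizes.
MULTIPLEX_GROUPS: dict[int, tuple[int, ...]] = {
    65: (396, 364, 332),  # cherimola, reticulata, muricata
    69: (315, 644, 476),  # squamosa, macroprophyllata, glabra
}

#: Extra band: AChReF1 cross-binds A. cherimola templates, so pooled with
#: AChR1 it yields an additional product of this size.
CROSS_BAND_ACH_REF1_ACHR1 = 271

#: GenBank accession ranges of the deposited barcode sequences
#: (matK KM068846-KM068866, rbcL KM068867-KM068887); used only by the
#: optional online validation scripts.
MATK_ACCESSIONS = tuple(f"KM0688{n}" for n in range(46, 67))
RBCL_ACCESSIONS = tuple(f"KM0688{n}" for n in range(67, 88))


def primer_dict(include_universal: bool = False) -> dict[str, str]:
    """Name -> sequence for the panel."""
    primers = SPECIFIC_PRIMERS + (UNIVERSAL_PRIMERS if include_universal else ())
    return {p.name: p.sequence for p in primers}


def published_tms() -> dict[str, float]:
    """Name -> published melting temperature for the 14 specific primers."""
    return {p.name: p.tm_celsius for p in SPECIFIC_PRIMERS}
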