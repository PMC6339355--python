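"""A synthetic example library for a three-gene carotenoid operon.

These parts are synthetic stand-ins: ids, strengths and short placeholder
sequences are invented for demonstration and testing, not taken from any
registry.  The library mirrors the canonical screening layout — five
constitutive promoters of low-to-medium relative strength (RPU against a
reference promoter), three RBS parts spanning low/medium/high strength
(each embedded in an assembly linker), the three pathway CDSs (GGPP
synthase crtE, phytoene synthase crtB, phytoene desaturase crtI), one
terminator and a low-copy p15A backbone — giving the familiar
5 x 3 x 3 x 3 x 6 = 810-configuration design space.
"""

from __future__ import annotations

from pathlib import Path

from .parts import Part, PartClass, PartLibrary, export_doe_table, rank_parts

_PROMOTERS = [
    # (id, name, RPU) — low-to-medium strengths
    ("Pc01", "prom_low", 0.12),
    ("Pc02", "prom_lowmed", 0.21),
    ("Pc03", "prom_med", 0.33),
    ("Pc04", "prom_medhi", 0.47),
    ("Pc05", "prom_high", 0.68),
]

_RBS = [
    ("R01", "rbs_low", 0.30),
    ("R02", "rbs_med", 1.00),
    ("R03", "rbs_high", 2.60),
]

_CDS = [
    ("crtE", "crtE", "GGPP synthase"),
    ("crtB", "crtB", "phytoene synthase"),
    ("crtI", "crtI", "phytoene desaturase"),
]

_SEQ = {
    "promoter": "TTGACAGCTAGCTCAGTCCTAGGTATAATGCTAGC",
    "rbs": "TCTAGAGAAAGAGGAGAAATACTAG",
    "cds": "ATGGCTGAAACCGTTGCTTACCTGGAAGGTCGTTAA",
    "terminator": "CCAGGCATCAAATAAAACGAAAGGCTCAGTCGAAAG",
    "linker": "GGCTCGGGAGACCTATCG",
    "backbone": "TTTCCATAGGCTCCGCCCCCCTGACGAGCATCACAA",
}


def demo_library(ranked: bool = True) -> PartLibrary:
    """The synthetic 810-configuration example library."""
    parts = []
    for pid, name, rpu in _PROMOTERS:
        parts.append(Part(pid, name, PartClass.PROMOTER, "E. coli",
                          _SEQ["promoter"], rpu, "RPU", "J23101"))
    for pid, name, strength in _RBS:
        parts.append(Part(pid, name, PartClass.RBS, "E. coli",
                          _SEQ["rbs"], strength, "relative", "B0034"))
    for pid, name, desc in _CDS:
        parts.append(Part(pid, name, PartClass.CDS, "P. ananatis", _SEQ["cds"]))
    parts.append(Part("T01", "terminator", PartClass.TERMINATOR, "E. coli",
                      _SEQ["terminator"]))
    for i, (rid, _, _) in enumerate(_RBS, start=1):
        parts.append(Part(f"L{i:02d}", f"linker_{rid}", PartClass.LINKER,
                          "", _SEQ["linker"]))
    parts.append(Part("BB01", "p15A_backbone", PartClass.BACKBONE, "E. coli",
                      _SEQ["backbone"]))
    library = PartLibrary.from_parts(parts, source="demo")
    if ranked:
        library = rank_parts(library, PartClass.PROMOTER)
        library = rank_parts(library, PartClass.RBS)
    return library


def demo_design_config() -> dict:
    """Design-config mapping for :func:`~operon_doe.design.build_design_space`."""
    return {
        "genes": ["crtE", "crtB", "crtI"],
        "gene_codes": {"crtE": "E", "crtB": "B", "crtI": "I"},
        "rbs_linkers": {"R01": "L01", "R02": "L02", "R03": "L03"},
        "terminator": "T01",
        "backbone": "BB01",
    }


def demo_standard_curve_points() -> tuple[list[float], list[float]]:
    """Synthetic external-standard series (conc mg/mL, peak area).

    The smallest nonzero standard, 3.6e-5 mg/mL, corresponds to a titre of
    0.05 mg/g DCW for a 1 mL culture at OD600 = 2.0 extracted into 1 mL —
    so the curve's default detection floor matches the simulator's.
    """
    conc = [0.0, 3.6e-5, 2e-4, 1e-3, 2e-3, 4e-3]
    areas = [round(12.0 + 95_000.0 * c, 6) for c in conc]
    return conc, areas


def write_demo_parts_csv(destination: str | Path) -> Path:
    """Write the ranked example library as a part CSV."""
    return export_doe_table(demo_library(ranked=True), destination)
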