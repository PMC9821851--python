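"""Curated seed library for American ginseng (Panax quinquefolius) analysis.

The seed set covers the discriminative marker compounds characterized in
wild-vs-cultivated root comparisons -- eleven ginsenosides spanning the four
sapogenin scaffolds (PPD, PPT, OT, OA), eight non-ginsenoside markers
(phenolic glycosides, disaccharide derivatives, organic-acid derivatives)
-- plus the ginsenoside reference standards routinely run as a QC mix.
Users supply their own, larger libraries as TSV/JSON for production work;
this set is enough to exercise and validate every pipeline stage.

Each marker entry carries the negative-mode reference attributes used for
validation: observed retention time (min), measured m/z, which adduct ions
were seen, the group in which the compound is more abundant, and the
nominal-mass MS2 ion ladder (base peak scaled to 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import CompoundRecord
from .ms2 import SpectrumPeaks

__all__ = [
    "MarkerEntry",
    "GINSENOSIDE_MARKERS",
    "NON_GINSENOSIDE_MARKERS",
    "REFERENCE_STANDARDS",
    "seed_records",
    "seed_library",
    "marker_spectrum",
]


@dataclass(frozen=True)
class MarkerEntry:
    name: str
    formula: str
    compound_class: str
    rt_min: float
    measured_mz: float
    adducts: tuple[str, ...]  # species observed in negative mode
    richer_in: str  # "wild" | "cultivated"
    ms2_precursor: float
    ms2_peaks: tuple[tuple[float, float], ...]  # (m/z, relative intensity %)


GINSENOSIDE_MARKERS: tuple[MarkerEntry, ...] = (
    MarkerEntry(
        "notoginsenoside H", "C47H80O19", "OT", 28.6, 993.5275,
        ("[M-H]-", "[M+HCOO]-"), "wild", 993.0,
        ((947, 100), (815, 58), (797, 8), (653, 94), (491, 6), (191, 6), (179, 14), (161, 69)),
    ),
    MarkerEntry(
        "glucoginsenoside Rf", "C48H82O19", "PPT", 34.6, 1007.545,
        ("[M-H]-", "[M+HCOO]-"), "wild", 1007.0,
        ((961, 100), (799, 28), (781, 6), (637, 34), (475, 11), (179, 15), (161, 30)),
    ),
    MarkerEntry(
        "notoginsenoside R1", "C47H80O18", "PPT", 38.5, 977.5331,
        ("[M-H]-", "[M+HCOO]-"), "wild", 977.0,
        ((931, 94), (799, 38), (637, 100), (161, 32)),
    ),
    MarkerEntry(
        "pseudoginsenoside RT2", "C41H70O14", "OT", 49.4, 831.4748,
        ("[M-H]-", "[M+HCOO]-"), "wild", 831.0,
        ((785, 88), (653, 73), (191, 7), (161, 100)),
    ),
    MarkerEntry(
        "ginsenoside Rc", "C53H90O22", "PPD", 62.8, 1123.591,
        ("[M-H]-", "[M+HCOO]-"), "wild", 1123.0,
        ((1078, 100), (945, 16), (916, 9), (783, 14), (191, 9)),
    ),
    MarkerEntry(
        "chicusetsusaponin IVa", "C42H66O14", "OA", 64.3, 793.4376,
        ("[M-H]-",), "cultivated", 793.0,
        ((793, 100), (631, 20), (569, 7), (455, 3)),
    ),
    MarkerEntry(
        "malonylginsenoside Rd", "C51H84O21", "PPD", 64.9, 1031.542,
        ("[M-H]-",), "cultivated", 1031.0,
        ((945, 100), (927, 17), (783, 22), (765, 14), (663, 5), (621, 15), (459, 4)),
    ),
    MarkerEntry(
        "pseudoginsenoside Rc1", "C50H84O19", "PPD", 64.9, 987.5515,
        ("[M-H]-",), "cultivated", 987.0,
        ((945, 100), (927, 13), (783, 25), (765, 15), (663, 6), (621, 21), (459, 5), (179, 10), (161, 32)),
    ),
    MarkerEntry(
        "malonylfloralginsenoside Rd6", "C54H86O24", "PPD", 65.4, 1117.545,
        ("[M-H]-",), "cultivated", 1117.0,
        ((987, 35), (945, 100), (927, 78), (783, 23), (765, 30), (621, 25)),
    ),
    MarkerEntry(
        "ginsenoside Rd", "C48H82O18", "PPD", 65.8, 991.5477,
        ("[M-H]-", "[M+HCOO]-"), "cultivated", 945.0,
        ((945, 100), (783, 20), (621, 11), (459, 3)),
    ),
    MarkerEntry(
        "malonylginsenoside Rb1", "C57H94O26", "PPD", 62.6, 1193.595,
        ("[M-H]-",), "cultivated", 1193.0,
        ((1107, 100), (1089, 38), (945, 25), (927, 6), (783, 15), (179, 39)),
    ),
)

NON_GINSENOSIDE_MARKERS: tuple[MarkerEntry, ...] = (
    MarkerEntry(
        "quinic acid derivative", "C19H34O17", "non-ginsenoside", 1.8, 533.1718,
        ("[M-H]-",), "cultivated", 533.0, ((191, 100),),
    ),
    MarkerEntry(
        "methyl gallate-glucoside", "C14H18O10", "non-ginsenoside", 7.5, 345.0816,
        ("[M-H]-",), "wild", 345.0, ((345, 90), (330, 100), (183, 55)),
    ),
    MarkerEntry(
        "hexyl 6-O-glucopyranosyl-glucopyranoside", "C18H34O11", "non-ginsenoside",
        13.4, 471.2087, ("[M-H]-", "[M+HCOO]-"), "wild", 471.0,
        ((425, 100), (293, 91), (161, 26)),
    ),
    MarkerEntry(
        "glucopyranosyl-methylbutanoyl-glucopyranoside", "C17H30O12", "non-ginsenoside",
        14.0, 425.1672, ("[M-H]-",), "wild", 425.0,
        ((379, 20), (191, 8), (179, 48), (161, 12), (101, 31), (89, 100)),
    ),
    MarkerEntry(
        "sinapic acid hexoside", "C17H22O10", "non-ginsenoside", 14.3, 385.1144,
        ("[M-H]-",), "wild", 385.0, ((223, 100), (208, 18), (179, 47), (164, 36)),
    ),
    MarkerEntry(
        "benzyl alcohol xylopyranosyl-(1-6)-glucopyranoside", "C18H26O10",
        "non-ginsenoside", 14.8, 447.1513, ("[M-H]-", "[M+HCOO]-"), "wild", 447.0,
        ((401, 13), (269, 100), (161, 42)),
    ),
    MarkerEntry(
        "everlastoside C", "C16H30O10", "non-ginsenoside", 15.9, 381.1767,
        ("[M-H]-",), "wild", 381.0, ((249, 100), (161, 34), (101, 39), (89, 13)),
    ),
    MarkerEntry(
        "isoconiferoside", "C22H32O13", "non-ginsenoside", 18.2, 503.1774,
        ("[M-H]-",), "wild", 503.0,
        ((503, 100), (341, 18), (179, 10), (161, 43), (101, 46), (89, 41)),
    ),
)

# QC reference-standard mix (name, formula, class). Pseudoginsenoside F11
# stands in for the ocotillol-type standard of the mix.
REFERENCE_STANDARDS: tuple[tuple[str, str, str], ...] = (
    ("ginsenoside Rb1", "C54H92O23", "PPD"),
    ("ginsenoside Rb2", "C53H90O22", "PPD"),
    ("ginsenoside Rb3", "C53H90O22", "PPD"),
    ("ginsenoside Rg1", "C42H72O14", "PPT"),
    ("ginsenoside Rg2", "C42H72O13", "PPT"),
    ("ginsenoside Rg3", "C42H72O13", "PPD"),
    ("ginsenoside Re", "C48H82O18", "PPT"),
    ("ginsenoside Rh2", "C36H62O8", "PPD"),
    ("pseudoginsenoside F11", "C42H72O14", "OT"),
)


def seed_records(include_non_ginsenosides: bool = True) -> list[CompoundRecord]:
    """All seed compounds as :class:`CompoundRecord` objects.

    Marker names take priority; standards duplicating a marker (Rc, Rd)
    or another standard's name are included once.
    """
    records: dict[str, CompoundRecord] = {}
    entries = list(GINSENOSIDE_MARKERS)
    if include_non_ginsenosides:
        entries += list(NON_GINSENOSIDE_MARKERS)
    for e in entries:
        records[e.name] = CompoundRecord.from_formula(
            e.name, e.formula, compound_class=e.compound_class, source_ref="marker table"
        )
    for name, formula, cls in REFERENCE_STANDARDS:
        if name not in records:
            records[name] = CompoundRecord.from_formula(
                name, formula, compound_class=cls, source_ref="reference standard"
            )
    return list(records.values())


def seed_library(polarities=("negative",), include_non_ginsenosides: bool = True):
    """Seed compounds expanded into an ion library (negative mode default)."""
    from .chem import build_library

    return build_library(seed_records(include_non_ginsenosides), polarities)


def marker_spectrum(name: str) -> SpectrumPeaks:
    """Reference nominal-mass MS2 spectrum for a seed marker compound."""
    for e in GINSENOSIDE_MARKERS + NON_GINSENOSIDE_MARKERS:
        if e.name == name:
            return SpectrumPeaks(
                precursor_mz=e.ms2_precursor,
                peaks=[(float(mz), float(ri)) for mz, ri in e.ms2_peaks],
            )
    raise KeyError(f"no reference spectrum for {name!r}")
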