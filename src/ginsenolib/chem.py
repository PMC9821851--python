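"""Molecular formulas, monoisotopic masses and ESI adduct enumeration.

This module turns a table of compound records (name + neutral formula) into a
searchable *ion library*: every compound expanded into the m/z values of the
adduct and multiply-charged species it can form under electrospray ionization.
Saponins such as ginsenosides ionize in negative mode mainly as [M-H]-,
[M+HCOO]- and [M+CF3COO]- (the mobile-phase acids), plus doubly-charged
variants for the larger, heavily glycosylated molecules.

Ionization arithmetic uses the proton mass (1.007276 Da) rather than the
neutral hydrogen mass, i.e. the electron is accounted for explicitly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "FormulaError",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "AdductSpecies",
    "CompoundRecord",
    "IonLibrary",
    "enumerate_adducts",
    "build_library",
    "NEGATIVE_SPECIES",
    "POSITIVE_SPECIES",
    "DEFAULT_SPECIES",
]

# Monoisotopic masses of the most abundant isotope, Da (IUPAC/CODATA).
ELEMENT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "Na": 22.9897693,
    "Mg": 23.9850417,
    "Si": 27.9769265,
    "P": 30.9737615,
    "S": 31.9720707,
    "Cl": 34.9688527,
    "K": 38.9637065,
    "Ca": 39.9625910,
    "Br": 78.9183376,
    "I": 126.9044719,
}

PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054858

# Neutral masses of the small molecules involved in adduct formation, Da.
MASS_HCOOH = 46.00548
MASS_TFA = 113.99286
MASS_H2O = 18.01056
MASS_NH3 = 17.02655
MASS_NA = 22.98977
MASS_K = 38.96371


class FormulaError(ValueError):
    """Raised for formula strings that cannot be interpreted."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula_text: str) -> dict[str, int]:
    """Parse a plain Hill-notation formula string into element counts.

    Only element-count pairs are supported -- no parentheses, isotope
    markers, charges or hydrate dots, which matches how saponin formulas
    are written in compound tables (e.g. ``"C53H90O22"``).

    Raises
    ------
    FormulaError
        On an empty string, an unrecognized element symbol, or an explicit
        zero count. The message names the offending token.
    """
    if not isinstance(formula_text, str) or not formula_text.strip():
        raise FormulaError("empty formula string")
    text = formula_text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"unparseable token at {text[pos:]!r} in {text!r}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaError(f"non-positive count for {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = m.end()
    return counts


def formula_to_string(counts: Mapping[str, int]) -> str:
    """Serialize element counts in canonical Hill order (C, H, then A-Z)."""
    symbols = list(counts)
    if "C" in counts:
        ordered = ["C"] + (["H"] if "H" in counts else [])
        ordered += sorted(s for s in symbols if s not in ("C", "H"))
    else:
        ordered = sorted(symbols)
    return "".join(f"{s}{counts[s]}" if counts[s] != 1 else s for s in ordered)


def monoisotopic_mass(counts: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: sum of most-abundant-isotope masses."""
    try:
        return float(sum(ELEMENT_MASSES[el] * n for el, n in counts.items()))
    except KeyError as exc:
        raise FormulaError(f"no isotope mass stored for element {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class AdductSpecies:
    """One ESI ion species: m/z = (M + mass_shift) / charge.

    ``mass_shift`` is the signed total mass change (adduct attachment,
    proton transfers, electron bookkeeping) applied to the neutral
    monoisotopic mass M before division by the charge count.
    """

    label: str
    polarity: str  # "negative" | "positive"
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"polarity must be negative/positive, got {self.polarity!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    def mz(self, neutral_mass: float) -> float:
        value = (neutral_mass + self.mass_shift) / self.charge
        if value <= 0:
            raise ValueError(
                f"non-positive m/z for {self.label} at neutral mass {neutral_mass}"
            )
        return value


NEGATIVE_SPECIES: tuple[AdductSpecies, ...] = (
    AdductSpecies("[M-H]-", "negative", -PROTON_MASS, 1),
    AdductSpecies("[M+HCOO]-", "negative", MASS_HCOOH - PROTON_MASS, 1),
    AdductSpecies("[M+CF3COO]-", "negative", MASS_TFA - PROTON_MASS, 1),
    AdductSpecies("[M-2H]2-", "negative", -2 * PROTON_MASS, 2),
    AdductSpecies("[M+HCOO-2H]2-", "negative", MASS_HCOOH - 2 * PROTON_MASS, 2),
    AdductSpecies("[M+2HCOO-2H]2-", "negative", 2 * MASS_HCOOH - 2 * PROTON_MASS, 2),
)

POSITIVE_SPECIES: tuple[AdductSpecies, ...] = (
    AdductSpecies("[M+H]+", "positive", PROTON_MASS, 1),
    AdductSpecies("[M+Na]+", "positive", MASS_NA - ELECTRON_MASS, 1),
    AdductSpecies("[M+K]+", "positive", MASS_K - ELECTRON_MASS, 1),
    AdductSpecies("[M+NH4]+", "positive", MASS_NH3 + PROTON_MASS, 1),
    AdductSpecies("[M+H-H2O]+", "positive", PROTON_MASS - MASS_H2O, 1),
    AdductSpecies("[M+2H]2+", "positive", 2 * PROTON_MASS, 2),
)

DEFAULT_SPECIES: dict[str, tuple[AdductSpecies, ...]] = {
    "negative": NEGATIVE_SPECIES,
    "positive": POSITIVE_SPECIES,
}

COMPOUND_CLASSES = ("PPD", "PPT", "OT", "OA", "non-ginsenoside", "unknown")


@dataclass
class CompoundRecord:
    """One library entry: a named compound with a neutral formula.

    ``compound_class`` is the sapogenin (aglycone) scaffold for
    ginsenosides -- PPD, PPT, OT or OA -- or ``non-ginsenoside``/``unknown``.
    """

    name: str
    formula: dict[str, int]
    compound_class: str = "unknown"
    cas: str | None = None
    hmdb_id: str | None = None
    foodb_id: str | None = None
    source_ref: str | None = None
    monoisotopic_mass: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        self.monoisotopic_mass = monoisotopic_mass(self.formula)

    @classmethod
    def from_formula(cls, name: str, formula_text: str, **kwargs) -> "CompoundRecord":
        return cls(name=name, formula=parse_formula(formula_text), **kwargs)

    @property
    def formula_string(self) -> str:
        return formula_to_string(self.formula)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "formula": self.formula_string,
            "monoisotopic_mass": self.monoisotopic_mass,
            "compound_class": self.compound_class,
            "cas": self.cas,
            "hmdb_id": self.hmdb_id,
            "foodb_id": self.foodb_id,
            "source_ref": self.source_ref,
        }


def enumerate_adducts(
    compound: CompoundRecord,
    polarity: str,
    species_set: Sequence[AdductSpecies] | None = None,
) -> list[tuple[AdductSpecies, float]]:
    """Theoretical m/z for each enabled ion species of one compound."""
    if species_set is None:
        species_set = DEFAULT_SPECIES[polarity]
    if not species_set:
        raise ValueError("species_set must be non-empty")
    out = []
    for sp in species_set:
        if sp.polarity != polarity:
            raise ValueError(
                f"species {sp.label} has polarity {sp.polarity}, expected {polarity}"
            )
        out.append((sp, sp.mz(compound.monoisotopic_mass)))
    return out


class IonLibrary:
    """Compound x adduct-species expansion with range queries by m/z.

    Rows live in a DataFrame sorted by theoretical m/z; ``query`` uses a
    binary search over the m/z column, so lookups are O(log n).
    """

    COLUMNS = (
        "compound",
        "compound_class",
        "formula",
        "neutral_mass",
        "species",
        "polarity",
        "charge",
        "theoretical_mz",
    )

    def __init__(self, df: pd.DataFrame, records: Sequence[CompoundRecord] = ()):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"ion library missing columns: {sorted(missing)}")
        if len(df) and (df["theoretical_mz"] <= 0).any():
            raise ValueError("ion library contains non-positive m/z")
        dup = df.duplicated(subset=["compound", "species", "polarity"])
        if dup.any():
            raise ValueError("duplicate (compound, species) rows in ion library")
        self._df = df.sort_values("theoretical_mz", kind="mergesort").reset_index(drop=True)
        self._mz = self._df["theoretical_mz"].to_numpy()
        self.records = {r.name: r for r in records}

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def query(self, mz: float, tol_mda: float = 5.0) -> pd.DataFrame:
        """All library rows with |theoretical m/z - mz| <= tol (milli-Da)."""
        if tol_mda <= 0:
            raise ValueError("tolerance must be positive")
        tol = tol_mda * 1e-3
        lo = int(np.searchsorted(self._mz, mz - tol, side="left"))
        hi = int(np.searchsorted(self._mz, mz + tol, side="right"))
        return self._df.iloc[lo:hi]

    def class_of(self, compound: str) -> str:
        rec = self.records.get(compound)
        if rec is not None:
            return rec.compound_class
        rows = self._df[self._df["compound"] == compound]
        return rows["compound_class"].iloc[0] if len(rows) else "unknown"

    # ---- serialization -------------------------------------------------

    def to_tsv(self, path) -> None:
        self._df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_json(self, path) -> None:
        payload = [r.to_dict() for r in self.records.values()]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def build_library(
    records: Iterable[CompoundRecord],
    polarities: Sequence[str] = ("negative",),
    species_config: Mapping[str, Sequence[AdductSpecies]] | None = None,
) -> IonLibrary:
    """Expand compound records into an :class:`IonLibrary`.

    Row count equals ``len(records) * sum(len(species) per polarity)``.
    Duplicate compound names are rejected -- isomers must be given
    distinguishable names, as they are in curated saponin tables.
    """
    records = list(records)
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate compound names: {dupes}")
    species_config = dict(species_config or DEFAULT_SPECIES)
    rows = []
    for i, rec in enumerate(records):
        for pol in polarities:
            try:
                pairs = enumerate_adducts(rec, pol, species_config.get(pol))
            except (ValueError, FormulaError) as exc:
                raise type(exc)(f"record {i} ({rec.name!r}): {exc}") from exc
            for sp, mz in pairs:
                rows.append(
                    {
                        "compound": rec.name,
                        "compound_class": rec.compound_class,
                        "formula": rec.formula_string,
                        "neutral_mass": rec.monoisotopic_mass,
                        "species": sp.label,
                        "polarity": sp.polarity,
                        "charge": sp.charge,
                        "theoretical_mz": mz,
                    }
                )
    df = pd.DataFrame(rows, columns=list(IonLibrary.COLUMNS))
    return IonLibrary(df, records)
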