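"""Synthetic two-group LC-MS feature tables and MS2 spectra with ground truth.

The generator emulates the statistical structure of a wild-vs-cultivated
root comparison: each planted library compound appears as a cluster of
co-eluting adduct features (shared retention time with small jitter,
milli-Dalton-scale Gaussian mass error, fixed adduct intensity ratios with
the formate adduct strongest in negative mode), per-sample log-normal
intensities with a multiplicative group fold-change effect, plus decoy
features placed well away from every library ion so that any decoy match
is an unambiguous error. Default group sizes are 12 wild and 19 cultivated
samples, the design of the study the package targets.

Everything is reproducible from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import PROTON_MASS, CompoundRecord, IonLibrary, MASS_HCOOH, formula_to_string
from .features import FeatureTable
from .ms2 import (
    DIAGNOSTIC_IONS_ACCURATE,
    LossRuleSet,
    SpectrumPeaks,
    default_rules,
)

__all__ = [
    "PlantedCompound",
    "SimulationConfig",
    "GroundTruth",
    "generate_feature_table",
    "generate_spectrum",
    "random_glycoside",
]

# Qualitative negative-mode adduct intensity pattern: the formate adduct
# dominates, the deprotonated molecule follows, minor species trail.
DEFAULT_ADDUCT_RATIOS: dict[str, float] = {
    "[M+HCOO]-": 1.0,
    "[M-H]-": 0.6,
    "[M+CF3COO]-": 0.25,
    "[M+HCOO-2H]2-": 0.2,
    "[M-2H]2-": 0.15,
    "[M+2HCOO-2H]2-": 0.1,
}


@dataclass(frozen=True)
class PlantedCompound:
    """One ground-truth compound planted into the simulated table."""

    name: str
    fold_change: float = 1.0  # wild/cultivated mean ratio (>1 = richer in wild)
    species: tuple[str, ...] = ("[M+HCOO]-", "[M-H]-", "[M-2H]2-")
    base_intensity: float = 1e6  # cultivated-group mean of the strongest adduct
    cv: float = 0.2  # biological coefficient of variation (log-normal)

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.cv <= 0 or self.base_intensity <= 0:
            raise ValueError("base_intensity and cv must be positive")


@dataclass
class SimulationConfig:
    planted: list[PlantedCompound]
    n_wild: int = 12
    n_cultivated: int = 19
    mass_error_sd_mda: float = 1.0  # Gaussian m/z error, milli-Da
    rt_jitter_sd_min: float = 0.02  # within-cluster RT jitter, minutes
    rt_jitter_clip_min: float = 0.05  # hard cap = rt_window / 4
    decoy_count: int = 100
    decoy_exclusion_mda: float = 10.0  # min decoy distance from any library ion
    decoy_cv: float = 0.4
    mz_range: tuple[float, float] = (150.0, 1300.0)
    rt_range: tuple[float, float] = (1.0, 80.0)
    adduct_ratios: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ADDUCT_RATIOS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wild < 2 or self.n_cultivated < 2:
            raise ValueError("group sizes must be >= 2")
        if self.decoy_exclusion_mda <= 0:
            raise ValueError("decoy exclusion radius must be positive")


@dataclass
class GroundTruth:
    """Planted-compound bookkeeping for recovery checks."""

    planted: dict[str, dict]  # compound -> {feature_ids, species, fold_change, class, rt}
    decoy_ids: list[str]

    def to_dict(self) -> dict:
        return {"planted": self.planted, "decoy_ids": self.decoy_ids}


def _lognormal_mean_calibrated(rng, mean: float, cv: float, size: int) -> np.ndarray:
    """Log-normal draws whose expectation equals ``mean`` at the given CV."""
    sigma = np.sqrt(np.log1p(cv**2))
    return mean * np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def generate_feature_table(
    config: SimulationConfig, library: IonLibrary
) -> tuple[FeatureTable, GroundTruth]:
    """Simulate a two-group feature table from planted library compounds.

    Every planted compound yields one feature per configured adduct
    species (m/z = theoretical + Gaussian error, one shared retention time
    with clipped jitter, log-normal intensities with the fold change
    applied to the wild group); decoys are uniform in m/z outside the
    exclusion radius of every library ion and carry no group effect.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"W{i + 1:02d}" for i in range(config.n_wild)] + [
        f"C{i + 1:02d}" for i in range(config.n_cultivated)
    ]
    groups = {s: ("wild" if s.startswith("W") else "cultivated") for s in sample_ids}

    rows = []
    planted_truth: dict[str, dict] = {}
    fid = 0
    for pc in config.planted:
        lib_rows = library.df[library.df["compound"] == pc.name]
        if lib_rows.empty:
            raise KeyError(f"planted compound {pc.name!r} absent from library")
        rt_center = rng.uniform(*config.rt_range)
        ids = []
        for sp in pc.species:
            row = lib_rows[lib_rows["species"] == sp]
            if row.empty:
                raise KeyError(f"species {sp!r} not enumerated for {pc.name!r}")
            theo = float(row["theoretical_mz"].iloc[0])
            ratio = config.adduct_ratios.get(sp, 0.3)
            jitter = np.clip(
                rng.normal(0.0, config.rt_jitter_sd_min),
                -config.rt_jitter_clip_min,
                config.rt_jitter_clip_min,
            )
            base = pc.base_intensity * ratio
            wild = _lognormal_mean_calibrated(rng, base * pc.fold_change, pc.cv, config.n_wild)
            cult = _lognormal_mean_calibrated(rng, base, pc.cv, config.n_cultivated)
            fid += 1
            ids.append(f"F{fid:05d}")
            rows.append(
                [ids[-1], theo + rng.normal(0.0, config.mass_error_sd_mda * 1e-3),
                 rt_center + jitter, *wild, *cult]
            )
        planted_truth[pc.name] = {
            "feature_ids": ids,
            "species": list(pc.species),
            "fold_change": pc.fold_change,
            "class": library.class_of(pc.name),
            "rt": rt_center,
        }

    lib_mz = np.sort(library.df["theoretical_mz"].to_numpy())
    excl = config.decoy_exclusion_mda * 1e-3
    decoy_ids = []
    n_placed = 0
    while n_placed < config.decoy_count:
        mz = rng.uniform(*config.mz_range)
        idx = np.searchsorted(lib_mz, mz)
        near = [lib_mz[k] for k in (idx - 1, idx) if 0 <= k < lib_mz.size]
        if near and min(abs(mz - v) for v in near) < excl:
            continue
        fid += 1
        n_placed += 1
        decoy_ids.append(f"F{fid:05d}")
        base = 10 ** rng.uniform(4, 6)
        intens = _lognormal_mean_calibrated(
            rng, base, config.decoy_cv, config.n_wild + config.n_cultivated
        )
        rows.append([decoy_ids[-1], mz, rng.uniform(*config.rt_range), *intens])

    df = pd.DataFrame(rows, columns=["feature_id", "mz", "rt", *sample_ids])
    df = df.set_index("feature_id")
    table = FeatureTable(df, groups)
    return table, GroundTruth(planted=planted_truth, decoy_ids=decoy_ids)


def default_planted() -> list[PlantedCompound]:
    """The default simulation scenario: the eleven marker ginsenosides.

    Fold changes emulate the magnitudes reported for the markers --
    wild-favored compounds between 2.3x and 54.5x, cultivated-favored
    between 2.6x and 14.4x (expressed as wild/cultivated ratios < 1).
    """
    wild_fc = {
        "notoginsenoside H": 15.9,
        "glucoginsenoside Rf": 4.0,
        "notoginsenoside R1": 6.0,
        "pseudoginsenoside RT2": 54.5,
        "ginsenoside Rc": 2.3,
    }
    cultivated_fc = {
        "chicusetsusaponin IVa": 2.6,
        "malonylginsenoside Rd": 14.4,
        "pseudoginsenoside Rc1": 5.0,
        "malonylfloralginsenoside Rd6": 4.0,
        "ginsenoside Rd": 3.0,
        "malonylginsenoside Rb1": 8.0,
    }
    planted = [PlantedCompound(name, fc) for name, fc in wild_fc.items()]
    planted += [PlantedCompound(name, 1.0 / fc) for name, fc in cultivated_fc.items()]
    return planted


SUGAR_FORMULAS = {"Glc": "C6H10O5", "Xyl/Ara": "C5H8O4", "Rha": "C6H10O4", "GlurA": "C6H8O6"}
ACYL_FORMULAS = {"Ace": "C2H2O", "But": "C4H4O", "Mal": "C3H2O3"}
AGLYCONE_FORMULAS = {"PPD": "C30H52O3", "PPT": "C30H52O4", "OT": "C30H52O5", "OA": "C30H48O3"}


def generate_spectrum(
    compound: CompoundRecord,
    glycan_plan: list[str],
    rules: LossRuleSet | None = None,
    formate_precursor: bool = False,
    validate: bool = True,
) -> SpectrumPeaks:
    """Idealized negative-mode MS2 ladder for a glycoside.

    The peak list is the cumulative-loss ladder from the deprotonated
    molecule through the ordered ``glycan_plan`` (loss labels from the
    rule set), optionally preceded by a formate-adduct precursor whose
    first step is the 46 Da adduct dissociation. Intensities decay
    geometrically from the base peak. With ``validate=True`` the ladder
    terminal must equal the diagnostic sapogenin ion of the compound's
    class within 0.5 Da.
    """
    if rules is None:
        rules = default_rules()
    by_label = {r.label: r for r in rules}
    unknown = [lbl for lbl in glycan_plan if lbl not in by_label]
    if unknown:
        raise KeyError(f"plan uses unknown loss labels: {unknown}")

    mh = compound.monoisotopic_mass - PROTON_MASS  # [M-H]-
    ladder = [mh]
    for lbl in glycan_plan:
        ladder.append(ladder[-1] - by_label[lbl].accurate)
    if ladder[-1] <= 0:
        raise ValueError("glycan plan exceeds the precursor mass")
    if validate and compound.compound_class in AGLYCONE_FORMULAS:
        expected = {
            diag for diag, cls in DIAGNOSTIC_IONS_ACCURATE.items()
            if cls == compound.compound_class
        }.pop()
        if abs(ladder[-1] - expected) > 0.5:
            raise ValueError(
                f"plan terminal {ladder[-1]:.4f} inconsistent with "
                f"{compound.compound_class} aglycone ion {expected:.4f}"
            )
    peaks = [(mz, round(100.0 * 0.7**i, 4)) for i, mz in enumerate(ladder)]
    precursor = mh
    if formate_precursor:
        precursor = compound.monoisotopic_mass + MASS_HCOOH - PROTON_MASS
    return SpectrumPeaks(precursor_mz=precursor, peaks=peaks)


def random_glycoside(
    rng: np.random.Generator,
    aglycone_class: str | None = None,
    n_sugars: tuple[int, int] = (1, 4),
    acyl_prob: float = 0.3,
) -> tuple[CompoundRecord, list[str]]:
    """A random synthetic glycoside plus its fragmentation plan.

    Sugar units are added to a sapogenin formula (condensation already
    accounted for: each unit contributes its neutral-loss formula), with
    an optional acyl substituent. The returned plan lists the acyl loss
    first, then the glycosyl losses -- the order in which such compounds
    fragment.
    """
    if aglycone_class is None:
        aglycone_class = str(rng.choice(list(AGLYCONE_FORMULAS)))
    from .chem import parse_formula

    counts = dict(parse_formula(AGLYCONE_FORMULAS[aglycone_class]))
    k = int(rng.integers(n_sugars[0], n_sugars[1] + 1))
    sugars = [str(rng.choice(list(SUGAR_FORMULAS))) for _ in range(k)]
    plan = list(sugars)
    acyls = []
    if rng.random() < acyl_prob:
        acyls = [str(rng.choice(list(ACYL_FORMULAS)))]
    for lbl in sugars + acyls:
        unit = SUGAR_FORMULAS.get(lbl) or ACYL_FORMULAS[lbl]
        for el, n in parse_formula(unit).items():
            counts[el] = counts.get(el, 0) + n
    name = f"synthetic {aglycone_class} glycoside {formula_to_string(counts)}"
    record = CompoundRecord(name=name, formula=counts, compound_class=aglycone_class)
    return record, acyls + plan
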