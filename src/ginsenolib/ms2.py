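"""Neutral-loss decomposition of ginsenoside MS2 spectra.

Ginsenosides fragment in negative-mode CID by shedding their sugar chain:
glycosyl units leave as neutral losses of 162 Da (hexose, -Glc), 132 Da
(pentose, -Xyl/Ara), 146 Da (deoxyhexose, -Rha) or 176 Da (-GlurA), and
acyl substituents on the sugars detach as 42 Da (-Ace), 68 Da (-But) or
86 Da (-Mal); acyl groups leave before the glycosyl they sit on. A formate
adduct precursor first dissociates by 46 Da to the deprotonated molecule.
The ladder terminates at the deprotonated sapogenin, whose m/z diagnoses
the aglycone scaffold: 459 -> PPD, 475 -> PPT, 491 -> OT, 455 -> OA.

``decompose_chain`` formalizes this as a longest-path search over the
directed acyclic graph whose nodes are the fragment peaks (plus the
precursor) and whose edges are admissible neutral losses between
descending m/z values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .chem import monoisotopic_mass, parse_formula

__all__ = [
    "SpectrumPeaks",
    "LossRule",
    "LossRuleSet",
    "default_rules",
    "LossChain",
    "DIAGNOSTIC_IONS",
    "DIAGNOSTIC_IONS_ACCURATE",
    "decompose_chain",
    "classify_aglycone",
    "annotate_substituents",
    "diagnostic_ion_scan",
    "classify_library_hits",
]


@dataclass
class SpectrumPeaks:
    """An MS2 peak list: precursor m/z plus (m/z, relative intensity %) pairs."""

    precursor_mz: float
    peaks: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for mz, ri in self.peaks:
            if not (0 < ri <= 100):
                raise ValueError(f"relative intensity {ri} out of (0, 100] at m/z {mz}")
        # descending m/z; chain search walks high -> low
        self.peaks = sorted(set(self.peaks), key=lambda p: (-p[0], -p[1]))


@dataclass(frozen=True)
class LossRule:
    label: str
    nominal: float  # Da, for integer peak lists
    accurate: float  # Da, monoisotopic
    kind: str  # "sugar" | "acyl" | "adduct" | "water"

    def mass(self, accurate: bool) -> float:
        return self.accurate if accurate else self.nominal


def _m(formula: str) -> float:
    return monoisotopic_mass(parse_formula(formula))


_DEFAULT_RULES: tuple[LossRule, ...] = (
    LossRule("Glc", 162.0, _m("C6H10O5"), "sugar"),
    LossRule("Xyl/Ara", 132.0, _m("C5H8O4"), "sugar"),
    LossRule("Rha", 146.0, _m("C6H10O4"), "sugar"),
    LossRule("GlurA", 176.0, _m("C6H8O6"), "sugar"),
    LossRule("Ace", 42.0, _m("C2H2O"), "acyl"),
    LossRule("But", 68.0, _m("C4H4O"), "acyl"),
    LossRule("Mal", 86.0, _m("C3H2O3"), "acyl"),
    LossRule("HCOOH", 46.0, _m("CH2O2"), "adduct"),
    LossRule("H2O", 18.0, _m("H2O"), "water"),
)


class LossRuleSet:
    """The admissible neutral losses, with nominal and accurate masses."""

    def __init__(self, rules: Iterable[LossRule] = _DEFAULT_RULES):
        self.rules = tuple(rules)
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise ValueError("loss labels must be unique")

    def match(self, delta: float, tol: float, accurate: bool) -> LossRule | None:
        """Best rule explaining a mass difference, or None."""
        best, best_err = None, tol
        for r in self.rules:
            err = abs(delta - r.mass(accurate))
            if err <= best_err:
                best, best_err = r, err
        return best

    def __iter__(self):
        return iter(self.rules)


def default_rules() -> LossRuleSet:
    return LossRuleSet()


# Deprotonated sapogenin ions (nominal) -> aglycone scaffold.
DIAGNOSTIC_IONS: dict[float, str] = {459.0: "PPD", 475.0: "PPT", 491.0: "OT", 455.0: "OA"}

# Accurate counterparts, computed from the sapogenin formulas [M_aglycone - H]-.
_AGLYCONE_FORMULAS = {"PPD": "C30H52O3", "PPT": "C30H52O4", "OT": "C30H52O5", "OA": "C30H48O3"}
DIAGNOSTIC_IONS_ACCURATE: dict[float, str] = {
    _m(f) - 1.00727646: cls for cls, f in _AGLYCONE_FORMULAS.items()
}


@dataclass
class LossChain:
    """An ordered fragmentation path with labeled neutral losses."""

    ions: list[float]  # descending m/z, chain members
    steps: list[tuple[str, float]]  # (loss label, loss mass) per edge
    precursor_mz: float
    unexplained: list[float] = field(default_factory=list)
    aglycone_class: str = "unknown"

    @property
    def terminal_ion(self) -> float:
        return self.ions[-1]

    def __len__(self) -> int:
        return len(self.steps)

    def to_dict(self) -> dict:
        return {
            "precursor_mz": self.precursor_mz,
            "ions": self.ions,
            "steps": [{"loss": lbl, "mass": m} for lbl, m in self.steps],
            "terminal_ion": self.terminal_ion,
            "aglycone_class": self.aglycone_class,
            "unexplained": self.unexplained,
        }


def _build_edges(
    nodes: Sequence[float], rules: LossRuleSet, tol: float, accurate: bool, precursor_idx: int
) -> dict[int, list[tuple[int, LossRule]]]:
    edges: dict[int, list[tuple[int, LossRule]]] = {i: [] for i in range(len(nodes))}
    for i, j in itertools.combinations(range(len(nodes)), 2):
        # nodes sorted descending: i < j means nodes[i] > nodes[j]
        rule = rules.match(nodes[i] - nodes[j], tol, accurate)
        if rule is None:
            continue
        if rule.kind == "adduct" and i != precursor_idx:
            continue  # adduct dissociation only as the chain's first step
        edges[i].append((j, rule))
    return edges


def decompose_chain(
    spectrum: SpectrumPeaks,
    rules: LossRuleSet | None = None,
    tol: float | None = None,
    accurate: bool = False,
) -> LossChain:
    """Longest neutral-loss path through a peak list.

    Nodes are the fragment peaks plus the precursor (added unless it
    coincides with a listed peak within ``tol``); edges connect descending
    m/z pairs whose difference matches a rule-set loss within ``tol``.
    Among equally long chains the tie-break prefers fewer distinct loss
    types, then higher summed fragment intensity, then lexicographically
    larger ion sequence (deterministic).

    Default tolerance is 0.5 Da for nominal integer peak lists and 0.02 Da
    in accurate-mass mode.
    """
    if rules is None:
        rules = default_rules()
    if tol is None:
        tol = 0.02 if accurate else 0.5
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if not spectrum.peaks:
        raise ValueError("spectrum has no peaks")

    intensity = {mz: ri for mz, ri in spectrum.peaks}
    nodes = [mz for mz, _ in spectrum.peaks]
    if all(abs(spectrum.precursor_mz - mz) > tol for mz in nodes):
        nodes.append(spectrum.precursor_mz)
    nodes.sort(reverse=True)
    precursor_idx = min(
        range(len(nodes)), key=lambda i: abs(nodes[i] - spectrum.precursor_mz)
    )
    edges = _build_edges(nodes, rules, tol, accurate, precursor_idx)

    # DP pass: longest path length from each node.
    order = range(len(nodes) - 1, -1, -1)  # ascending m/z = reverse topological
    best_len = [0] * len(nodes)
    for i in order:
        for j, _ in edges[i]:
            best_len[i] = max(best_len[i], 1 + best_len[j])
    target = max(best_len)

    # Enumerate maximal-length paths only, then tie-break.
    def extend(i: int, path: list[int], steps: list[LossRule]):
        if best_len[i] == 0:
            yield list(path), list(steps)
            return
        for j, rule in edges[i]:
            if 1 + best_len[j] == best_len[i]:
                path.append(j)
                steps.append(rule)
                yield from extend(j, path, steps)
                path.pop()
                steps.pop()

    candidates = []
    for start in range(len(nodes)):
        if best_len[start] != target:
            continue
        for path, steps in extend(start, [start], []):
            n_types = len({r.label for r in steps})
            total_int = sum(intensity.get(nodes[i], 0.0) for i in path)
            ion_seq = tuple(nodes[i] for i in path)
            candidates.append((n_types, -total_int, tuple(-m for m in ion_seq), path, steps))
    n_types, _, _, path, steps = min(candidates)

    chain_ions = [nodes[i] for i in path]
    on_chain = set(chain_ions)
    accurate_flag = accurate
    chain = LossChain(
        ions=chain_ions,
        steps=[(r.label, r.mass(accurate_flag)) for r in steps],
        precursor_mz=spectrum.precursor_mz,
        unexplained=[mz for mz, _ in spectrum.peaks if mz not in on_chain],
    )
    chain.aglycone_class = classify_aglycone(chain, tol=tol, accurate=accurate)
    return chain


def classify_aglycone(
    chain: LossChain,
    table: Mapping[float, str] | None = None,
    tol: float = 0.5,
    accurate: bool = False,
    mode: str = "terminal",
) -> str:
    """Aglycone scaffold called from a chain's diagnostic ion.

    ``mode="terminal"`` checks the chain's terminal ion only (the strict
    ladder-end reading); ``mode="any"`` accepts a diagnostic ion anywhere
    along the chain. Returns ``"unknown"`` when nothing matches.
    """
    if table is None:
        table = DIAGNOSTIC_IONS_ACCURATE if accurate else DIAGNOSTIC_IONS
    if mode not in ("terminal", "any"):
        raise ValueError("mode must be 'terminal' or 'any'")
    probes = chain.ions if mode == "any" else [chain.terminal_ion]
    for ion in probes:
        for diag, cls in table.items():
            if abs(ion - diag) <= tol:
                return cls
    return "unknown"


def annotate_substituents(chain: LossChain, rules: LossRuleSet | None = None) -> list[str]:
    """Acyl substituent labels (Ace/But/Mal) along a chain, in loss order."""
    if rules is None:
        rules = default_rules()
    acyl = {r.label for r in rules if r.kind == "acyl"}
    return [lbl for lbl, _ in chain.steps if lbl in acyl]


def diagnostic_ion_scan(
    spectra: Mapping[str, SpectrumPeaks] | Sequence[SpectrumPeaks],
    table: Mapping[float, str] | None = None,
    tol: float = 0.5,
) -> dict:
    """Which diagnostic sapogenin ions each spectrum contains.

    Emulates a parent-ion mapping: every spectrum is scanned for product
    ions at the four diagnostic m/z values; spectra with none are dropped.
    Spectra hitting more than one diagnostic ion are reported with all
    classes (ambiguous).
    """
    if table is None:
        table = DIAGNOSTIC_IONS
    if isinstance(spectra, Mapping):
        items = list(spectra.items())
    else:
        items = [(s.precursor_mz, s) for s in spectra]
    if not items:
        raise ValueError("no spectra supplied")
    hits: dict = {}
    for key, spec in items:
        classes = sorted(
            {cls for mz, _ in spec.peaks for diag, cls in table.items() if abs(mz - diag) <= tol}
        )
        if classes:
            hits[key] = classes
    return hits


def classify_library_hits(
    groups: Sequence, spectra: Mapping[str, SpectrumPeaks] | None = None, tol: float = 0.5
) -> dict[str, int]:
    """Tally metabolite groups per aglycone class.

    The class comes from the group's MS2 spectrum (diagnostic-ion scan of
    the chain) when one is supplied, otherwise from the library record the
    group was matched to. ``groups`` may be MetaboliteGroup objects (with
    ``compound`` and ``compound_class``) or plain (name, class) pairs.
    """
    tally = {cls: 0 for cls in ("PPD", "PPT", "OT", "OA", "non-ginsenoside", "unknown")}
    for g in groups:
        if isinstance(g, tuple):
            name, cls = g
        else:
            name, cls = g.compound, getattr(g, "compound_class", "unknown")
        if spectra is not None and name in spectra:
            chain = decompose_chain(spectra[name], tol=tol)
            called = classify_aglycone(chain, tol=tol, mode="any")
            if called != "unknown":
                cls = called
        tally[cls if cls in tally else "unknown"] += 1
    return tally
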