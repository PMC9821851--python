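"""Feature-table matching against the ion library and adduct coalescing.

A *feature* is an ion with a unique (m/z, retention time) pair carrying one
intensity per sample. Matching flags every feature whose m/z falls within
an absolute tolerance (default +/-5 mDa) of any library ion; the matched
and unmatched partitions become the ginsenoside and non-ginsenoside
matrices. Because one metabolite shows up as several co-eluting adduct and
charge-state features, matched features are then coalesced into metabolite
groups by shared best-candidate compound and retention time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import IonLibrary

__all__ = [
    "FeatureTable",
    "Candidate",
    "MatchResult",
    "MetaboliteGroup",
    "match_features",
    "split_dataset",
    "coalesce_adducts",
    "count_unique_rts",
]

GROUPS = ("wild", "cultivated")


@dataclass
class FeatureTable:
    """Features (rows) x samples (intensity columns) with group labels.

    ``features`` is indexed by feature_id with columns ``mz``, ``rt`` and
    one column per sample; ``groups`` maps sample_id -> group label
    (``wild`` or ``cultivated``).
    """

    features: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        df = self.features
        if not df.index.is_unique:
            raise ValueError("feature ids must be unique")
        for col in ("mz", "rt"):
            if col not in df.columns:
                raise ValueError(f"feature table missing column {col!r}")
        if len(df):
            if (df["mz"] <= 0).any():
                raise ValueError("m/z values must be positive")
            if (df["rt"] < 0).any():
                raise ValueError("retention times must be non-negative")
        missing = set(self.groups) - set(df.columns)
        if missing:
            raise ValueError(f"sample columns absent from table: {sorted(missing)}")
        bad = set(self.groups.values()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)} (expected {GROUPS})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def intensities(self) -> pd.DataFrame:
        return self.features[self.sample_ids]

    def subset(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.features.loc[list(feature_ids)].copy(), dict(self.groups))

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class Candidate:
    compound: str
    species: str
    theoretical_mz: float
    delta_mda: float  # observed - theoretical, milli-Da
    delta_ppm: float
    compound_class: str = "unknown"


@dataclass
class MatchResult:
    feature_id: str
    mz: float
    rt: float
    candidates: list[Candidate]

    @property
    def best(self) -> Candidate:
        return self.candidates[0]


@dataclass
class MetaboliteGroup:
    """Co-eluting matched features coalesced into one putative metabolite."""

    compound: str
    compound_class: str
    consensus_rt: float
    member_ids: list[str]
    species: set[str]
    representative_id: str
    representative_intensities: pd.Series = field(repr=False, default=None)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def match_features(
    table: FeatureTable, library: IonLibrary, tol_mda: float = 5.0
) -> tuple[list[MatchResult], list[str]]:
    """Partition features into library matches and non-matches.

    Every feature with at least one library ion within ``tol_mda`` milli-Da
    becomes a :class:`MatchResult` whose candidates are sorted by |delta|;
    the rest are returned as a list of unmatched feature ids. The two
    partitions always cover the input exactly.
    """
    if tol_mda <= 0:
        raise ValueError("tolerance must be positive")
    if len(library) == 0:
        raise ValueError("ion library is empty")
    if len(table) == 0:
        warnings.warn("empty feature table: nothing to match", stacklevel=2)
        return [], []
    matched: list[MatchResult] = []
    unmatched: list[str] = []
    for fid, row in table.features.iterrows():
        hits = library.query(float(row["mz"]), tol_mda)
        if len(hits) == 0:
            unmatched.append(fid)
            continue
        cands = [
            Candidate(
                compound=h.compound,
                species=h.species,
                theoretical_mz=h.theoretical_mz,
                delta_mda=(row["mz"] - h.theoretical_mz) * 1e3,
                delta_ppm=(row["mz"] - h.theoretical_mz) / h.theoretical_mz * 1e6,
                compound_class=h.compound_class,
            )
            for h in hits.itertuples()
        ]
        cands.sort(key=lambda c: (abs(c.delta_mda), c.compound, c.species))
        matched.append(MatchResult(str(fid), float(row["mz"]), float(row["rt"]), cands))
    return matched, unmatched


def split_dataset(
    table: FeatureTable, matched: list[MatchResult]
) -> tuple[FeatureTable, FeatureTable]:
    """Split into (ginsenoside, non-ginsenoside) matrices by match status."""
    matched_ids = [m.feature_id for m in matched]
    matched_set = set(matched_ids)
    other_ids = [fid for fid in table.features.index if fid not in matched_set]
    return table.subset(matched_ids), table.subset(other_ids)


def coalesce_adducts(
    matched: list[MatchResult],
    table: FeatureTable | None = None,
    rt_window: float = 0.2,
) -> list[MetaboliteGroup]:
    """Merge co-eluting features of the same best-candidate compound.

    Within each compound, grouping is seeded from the most intense
    remaining feature (summed intensity when a table is given, else the
    smallest |delta m/z|); every unassigned feature within ``rt_window/2``
    of the seed joins that group, so the maximum RT spread inside a group
    never exceeds ``rt_window``. Features of the same compound at clearly
    different retention times (isomers) stay separate.
    """
    if rt_window <= 0:
        raise ValueError("rt_window must be positive")
    by_compound: dict[str, list[MatchResult]] = {}
    for m in matched:
        by_compound.setdefault(m.best.compound, []).append(m)

    def weight(m: MatchResult) -> float:
        if table is not None and m.feature_id in table.features.index:
            return float(table.features.loc[m.feature_id, table.sample_ids].sum())
        return -abs(m.best.delta_mda)

    groups: list[MetaboliteGroup] = []
    for compound, members in sorted(by_compound.items()):
        remaining = sorted(members, key=lambda m: (-weight(m), m.feature_id))
        while remaining:
            seed = remaining[0]
            in_group = [m for m in remaining if abs(m.rt - seed.rt) <= rt_window / 2]
            remaining = [m for m in remaining if abs(m.rt - seed.rt) > rt_window / 2]
            rts = [m.rt for m in in_group]
            cls = next(
                (c.compound_class for c in seed.candidates if c.compound == compound),
                "unknown",
            )
            groups.append(
                MetaboliteGroup(
                    compound=compound,
                    compound_class=cls,
                    consensus_rt=float(np.median(rts)),
                    member_ids=[m.feature_id for m in in_group],
                    species={
                        c.species
                        for m in in_group
                        for c in m.candidates
                        if c.compound == compound
                    },
                    representative_id=seed.feature_id,
                    representative_intensities=(
                        table.features.loc[seed.feature_id, table.sample_ids]
                        if table is not None
                        else None
                    ),
                )
            )
    return groups


def count_unique_rts(rts, rt_window: float = 0.2) -> int:
    """Number of single-linkage retention-time clusters at the window.

    In one dimension single-linkage clustering is exact: sort the RTs and
    cut wherever the gap between neighbours exceeds the window.
    """
    if rt_window <= 0:
        raise ValueError("rt_window must be positive")
    values = np.sort(np.asarray(list(rts), dtype=float))
    if values.size == 0:
        return 0
    return int(1 + np.sum(np.diff(values) > rt_window))
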