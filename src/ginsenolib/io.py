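"""Readers and writers for the pipeline's plain-text formats.

Formats: compound libraries as TSV or JSON; feature tables as CSV (one row
per feature: id, m/z, RT in minutes, then one intensity column per sample)
with a sidecar JSON mapping sample columns to groups -- the shape of an
XCMS pairwise export; MS2 peak lists as MGF or long-format CSV; results
and matrices as CSV with fixed numeric precision so reruns diff cleanly
(m/z to 4 decimals, p-values in 3-significant-figure scientific notation).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import CompoundRecord, parse_formula
from .features import FeatureTable, MatchResult, MetaboliteGroup
from .ms2 import LossChain, SpectrumPeaks

__all__ = [
    "read_library_table",
    "write_library_tsv",
    "read_library_json",
    "read_feature_table",
    "write_feature_table",
    "write_match_results",
    "write_groups_json",
    "read_spectra_mgf",
    "write_spectra_mgf",
    "read_spectra_csv",
    "write_chains_json",
    "write_results_csv",
    "write_matrix_csv",
]

_LIBRARY_COLUMNS = ("name", "formula", "compound_class", "cas", "hmdb_id", "foodb_id", "source_ref")


def _records_from_frame(df: pd.DataFrame, origin: str) -> list[CompoundRecord]:
    if "name" not in df.columns or "formula" not in df.columns:
        raise ValueError(f"{origin}: library needs 'name' and 'formula' columns")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                CompoundRecord(
                    name=str(row.name),
                    formula=parse_formula(str(row.formula)),
                    compound_class=str(getattr(row, "compound_class", "unknown") or "unknown"),
                    cas=getattr(row, "cas", None) or None,
                    hmdb_id=getattr(row, "hmdb_id", None) or None,
                    foodb_id=getattr(row, "foodb_id", None) or None,
                    source_ref=getattr(row, "source_ref", None) or None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{origin}, row {i} ({getattr(row, 'name', '?')}): {exc}") from exc
    return records


def read_library_table(path) -> list[CompoundRecord]:
    """Compound records from a TSV file (columns: name, formula, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return _records_from_frame(df, str(path))


def write_library_tsv(records: Sequence[CompoundRecord], path) -> None:
    rows = [
        {
            "name": r.name,
            "formula": r.formula_string,
            "compound_class": r.compound_class,
            "cas": r.cas or "",
            "hmdb_id": r.hmdb_id or "",
            "foodb_id": r.foodb_id or "",
            "source_ref": r.source_ref or "",
            "monoisotopic_mass": f"{r.monoisotopic_mass:.6f}",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library_json(path) -> list[CompoundRecord]:
    with open(path) as fh:
        payload = json.load(fh)
    df = pd.DataFrame(payload).fillna("")
    return _records_from_frame(df, str(path))


def read_feature_table(csv_path, groups_path) -> FeatureTable:
    """Feature CSV plus sidecar group map (JSON: {sample_id: group})."""
    df = pd.read_csv(csv_path)
    required = {"feature_id", "mz", "rt"}
    if not required <= set(df.columns):
        raise ValueError(f"{csv_path}: feature CSV needs columns {sorted(required)}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        row = int(df.index[df["feature_id"] == dup][1]) + 2  # 1-based + header
        raise ValueError(f"{csv_path}, line {row}: duplicate feature id {dup!r}")
    with open(groups_path) as fh:
        groups = json.load(fh)
    return FeatureTable(df.set_index("feature_id"), dict(groups))


def write_feature_table(table: FeatureTable, csv_path, groups_path) -> None:
    df = table.features.copy()
    df.index.name = "feature_id"
    out = df.reset_index()
    out["mz"] = out["mz"].map(lambda v: f"{v:.4f}")
    out["rt"] = out["rt"].map(lambda v: f"{v:.3f}")
    for col in table.sample_ids:
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    out.to_csv(csv_path, index=False)
    with open(groups_path, "w") as fh:
        json.dump(table.groups, fh, indent=1)


def write_match_results(
    matched: Sequence[MatchResult],
    unmatched: Sequence[str],
    table: FeatureTable,
    matched_path,
    unmatched_path,
) -> None:
    rows = []
    for m in matched:
        for rank, c in enumerate(m.candidates, start=1):
            rows.append(
                {
                    "feature_id": m.feature_id,
                    "mz": f"{m.mz:.4f}",
                    "rt": f"{m.rt:.3f}",
                    "rank": rank,
                    "compound": c.compound,
                    "compound_class": c.compound_class,
                    "species": c.species,
                    "theoretical_mz": f"{c.theoretical_mz:.4f}",
                    "delta_mda": f"{c.delta_mda:.3f}",
                    "delta_ppm": f"{c.delta_ppm:.2f}",
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "feature_id", "mz", "rt", "rank", "compound", "compound_class",
            "species", "theoretical_mz", "delta_mda", "delta_ppm",
        ],
    ).to_csv(matched_path, index=False)
    sub = table.features.loc[list(unmatched), ["mz", "rt"]].copy()
    sub["mz"] = sub["mz"].map(lambda v: f"{v:.4f}")
    sub["rt"] = sub["rt"].map(lambda v: f"{v:.3f}")
    sub.index.name = "feature_id"
    sub.to_csv(unmatched_path)


def write_groups_json(groups: Sequence[MetaboliteGroup], path) -> None:
    payload = [
        {
            "compound": g.compound,
            "compound_class": g.compound_class,
            "consensus_rt": round(g.consensus_rt, 3),
            "member_ids": g.member_ids,
            "species": sorted(g.species),
            "representative_id": g.representative_id,
        }
        for g in groups
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---- MS2 peak lists ----------------------------------------------------


def read_spectra_mgf(path) -> dict[str, SpectrumPeaks]:
    """MGF-style peak lists (BEGIN IONS / TITLE / PEPMASS / m-i pairs)."""
    spectra: dict[str, SpectrumPeaks] = {}
    title, precursor, peaks = None, None, []
    inside = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                inside, title, precursor, peaks = True, None, None, []
            elif line == "END IONS":
                if precursor is None:
                    raise ValueError(f"{path}, line {lineno}: spectrum without PEPMASS")
                key = title or f"spectrum_{len(spectra) + 1}"
                spectra[key] = SpectrumPeaks(precursor_mz=precursor, peaks=peaks)
                inside = False
            elif inside and line.startswith("TITLE="):
                title = line[6:]
            elif inside and line.startswith("PEPMASS="):
                precursor = float(line[8:].split()[0])
            elif inside and "=" not in line:
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}, line {lineno}: malformed peak {line!r}")
                peaks.append((float(parts[0]), float(parts[1])))
    return spectra


def write_spectra_mgf(spectra: dict[str, SpectrumPeaks], path) -> None:
    with open(path, "w") as fh:
        for title, spec in spectra.items():
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={title}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.4f}\n")
            for mz, ri in spec.peaks:
                fh.write(f"{mz:.4f} {ri:.2f}\n")
            fh.write("END IONS\n")


def read_spectra_csv(path) -> dict[str, SpectrumPeaks]:
    """Long-format CSV: spectrum_id, precursor_mz, mz, intensity."""
    df = pd.read_csv(path)
    required = {"spectrum_id", "precursor_mz", "mz", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: MS2 CSV needs columns {sorted(required)}")
    spectra = {}
    for sid, grp in df.groupby("spectrum_id", sort=False):
        spectra[str(sid)] = SpectrumPeaks(
            precursor_mz=float(grp["precursor_mz"].iloc[0]),
            peaks=list(zip(grp["mz"].astype(float), grp["intensity"].astype(float))),
        )
    return spectra


def write_chains_json(chains: dict[str, LossChain], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: c.to_dict() for k, c in chains.items()}, fh, indent=1)


# ---- results matrices --------------------------------------------------

_MZ_LIKE = ("mz", "theoretical_mz", "consensus_rt")
_P_LIKE = ("p_value", "q_value")


def write_results_csv(results: pd.DataFrame, path) -> None:
    """Differential results with fixed precision for diffable output."""
    out = results.copy()
    for col in out.columns:
        if col in _P_LIKE:
            out[col] = out[col].map(lambda v: f"{v:.3e}")
        elif col in _MZ_LIKE:
            out[col] = out[col].map(lambda v: f"{v:.4f}")
        elif pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path)


def write_matrix_csv(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path)


def write_json(payload, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=1, default=_default) + "\n")
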