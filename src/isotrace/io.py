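"""Readers, writers and validation for the pipeline's plain-text formats.

Formats (all UTF-8, decimal point):

* ``series.csv`` — tidy isotope time series:
  soil_class, replicate, time_h, pool_id, delta13c_permil, c_content
* ``plfa.csv`` — sample_id, marker, ug_per_g
* ``taxa.tsv`` — tab-separated; first column ``lineage`` ("Domain;Phylum"),
  remaining columns samples, cells non-negative abundances
* ``meta.csv`` — sample_id, soil_class, treatment
* ``dose.yaml`` — litter_mass_mg, label_atom_percent, dose_ug13c, soil_mass_g
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .community import TaxonTable
from .isotope import Pool
from .pools import TracerDose

__all__ = [
    "SERIES_COLUMNS",
    "read_series",
    "read_plfa",
    "read_taxa",
    "read_dose",
    "validate_inputs",
]

SERIES_COLUMNS = ["soil_class", "replicate", "time_h", "pool_id", "delta13c_permil", "c_content"]
PLFA_COLUMNS = ["sample_id", "marker", "ug_per_g"]
META_COLUMNS = ["sample_id", "soil_class", "treatment"]
_POOL_IDS = {p.value for p in Pool}


def _check_header(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_series(path) -> pd.DataFrame:
    """Read and strictly validate a tidy isotope time-series CSV."""
    df = pd.read_csv(path)
    _check_header(df, SERIES_COLUMNS, path)
    violations = _validate_series(df, str(path))
    if violations:
        raise ValueError("invalid series file:\n" + "\n".join(violations))
    return df[SERIES_COLUMNS]


def read_plfa(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, PLFA_COLUMNS, path)
    violations = _validate_plfa(df, str(path))
    if violations:
        raise ValueError("invalid PLFA file:\n" + "\n".join(violations))
    return df[PLFA_COLUMNS]


def read_taxa(path, meta_path=None) -> TaxonTable:
    """Read a taxa × samples TSV (+ optional sidecar sample metadata CSV)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundance cells present")
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path)
        _check_header(meta, META_COLUMNS, meta_path)
        meta = meta.set_index("sample_id")
        unknown = [s for s in df.columns if s not in meta.index]
        if unknown:
            raise ValueError(f"{meta_path}: no metadata for sample(s) {unknown}")
        meta = meta.loc[list(df.columns)]
    return TaxonTable(df, meta)


def read_dose(path) -> TracerDose:
    """Read a tracer-dose YAML; missing keys fall back to the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    allowed = {"litter_mass_mg", "label_atom_percent", "dose_ug13c", "soil_mass_g"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown dose key(s) {sorted(unknown)}")
    return TracerDose(**raw)


# --------------------------------------------------------------------------
# validation (collects every violation rather than stopping at the first)


def _validate_series(df: pd.DataFrame, name: str) -> list[str]:
    v: list[str] = []
    bad_pool = ~df["pool_id"].isin(_POOL_IDS)
    for i in df.index[bad_pool]:
        v.append(f"{name} row {i}: unknown pool_id {df.at[i, 'pool_id']!r}")
    for i in df.index[df["c_content"] < 0]:
        v.append(f"{name} row {i}: negative c_content {df.at[i, 'c_content']}")
    for i in df.index[df["delta13c_permil"] <= -1000]:
        v.append(f"{name} row {i}: delta13c_permil {df.at[i, 'delta13c_permil']} <= -1000")
    for i in df.index[df["time_h"] < 0]:
        v.append(f"{name} row {i}: negative time_h {df.at[i, 'time_h']}")
    # per replicate × pool, times must be sorted without duplicates
    for (soil, rep, pool), grp in df.groupby(["soil_class", "replicate", "pool_id"]):
        t = grp["time_h"].to_numpy()
        if (pd.Series(t).diff().dropna() <= 0).any():
            v.append(
                f"{name}: non-increasing time_h for soil_class={soil} "
                f"replicate={rep} pool={pool} (rows {list(grp.index)})"
            )
    return v


def _validate_plfa(df: pd.DataFrame, name: str) -> list[str]:
    v: list[str] = []
    for i in df.index[df["ug_per_g"] < 0]:
        v.append(f"{name} row {i}: negative concentration {df.at[i, 'ug_per_g']}")
    dup = df.duplicated(subset=["sample_id", "marker"], keep=False)
    for i in df.index[dup]:
        v.append(f"{name} row {i}: duplicate (sample_id, marker) pair")
    return v


def validate_inputs(series_path=None, plfa_path=None, taxa_path=None, meta_path=None) -> list[str]:
    """Validate any subset of input files; returns the full list of violations."""
    violations: list[str] = []
    for path, required, validator, kind in [
        (series_path, SERIES_COLUMNS, _validate_series, "series"),
        (plfa_path, PLFA_COLUMNS, _validate_plfa, "plfa"),
    ]:
        if path is None:
            continue
        try:
            df = pd.read_csv(path)
        except OSError as exc:
            violations.append(f"{path}: unreadable ({exc})")
            continue
        missing = [c for c in required if c not in df.columns]
        if missing:
            violations.append(f"{path}: missing required column(s) {missing}")
            continue
        violations.extend(validator(df, str(path)))
    if taxa_path is not None:
        try:
            df = pd.read_csv(taxa_path, sep="\t", index_col=0)
            neg = (df.to_numpy() < 0)
            if neg.any():
                rows, cols = neg.nonzero()
                for r, c in zip(rows, cols):
                    violations.append(
                        f"{taxa_path}: negative abundance at taxon {df.index[r]!r}, "
                        f"sample {df.columns[c]!r}"
                    )
        except OSError as exc:
            violations.append(f"{taxa_path}: unreadable ({exc})")
    if meta_path is not None:
        try:
            meta = pd.read_csv(meta_path)
            missing = [c for c in META_COLUMNS if c not in meta.columns]
            if missing:
                violations.append(f"{meta_path}: missing required column(s) {missing}")
        except OSError as exc:
            violations.append(f"{meta_path}: unreadable ({exc})")
    return violations
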