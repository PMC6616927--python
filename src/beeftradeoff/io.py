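"""CSV interchange for herds, indicator tables and reports.

Everything the pipeline reads or writes is a small rectangular table, so CSV
(with a sidecar variable -> group map) is the only interchange format.  Values
are written with full ``repr`` precision so that a write/read round trip is
bit-exact for data produced by this package.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import pandas as pd

from .pretreat import IndicatorTable
from .synthdata import GROUPS, HerdTable

__all__ = [
    "read_herd",
    "write_herd",
    "read_indicators",
    "write_indicators",
    "write_model_bundle",
    "read_model_bundle",
]

BUNDLE_VERSION = 1


def _read_group_map(path: Path, columns: list[str]) -> dict[str, str]:
    gm = pd.read_csv(path)
    if list(gm.columns) != ["variable", "group"]:
        raise ValueError(f"group map {path} must have columns 'variable,group'")
    dup = gm["variable"][gm["variable"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated variable(s) in group map: {list(dup)}")
    mapping = dict(zip(gm["variable"], gm["group"]))
    missing = [c for c in columns if c not in mapping]
    if missing:
        raise ValueError(f"group map is missing variable(s): {missing}")
    unknown = [v for v in mapping if v not in columns]
    if unknown:
        raise ValueError(f"group map names unknown variable(s): {unknown}")
    bad = {v: g for v, g in mapping.items() if g not in GROUPS}
    if bad:
        raise ValueError(f"unknown group label(s): {bad}")
    return {c: mapping[c] for c in columns}


def _read_numeric(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    for col in df.columns:
        if df[col].dtype == object:
            mask = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            first = df.index[mask][0] if mask.any() else df.index[0]
            raise ValueError(f"non-numeric cell in column {col!r} (row {first!r})")
    if df.isna().any().any():
        na = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in column(s): {na}")
    return df.astype(float)


def read_herd(values_path: str | Path, group_map_path: str | Path) -> HerdTable:
    """Read a herd CSV (animals as rows) plus its variable -> group sidecar."""
    df = _read_numeric(Path(values_path))
    gm = _read_group_map(Path(group_map_path), list(df.columns))
    return HerdTable(df, gm, provenance={"source": str(values_path)})


def write_herd(herd: HerdTable, values_path: str | Path, group_map_path: str | Path) -> None:
    Path(values_path).parent.mkdir(parents=True, exist_ok=True)
    herd.values.to_csv(values_path)
    pd.DataFrame(
        {"variable": list(herd.values.columns),
         "group": [herd.group_map[c] for c in herd.values.columns]}
    ).to_csv(group_map_path, index=False)


def write_indicators(table: IndicatorTable, values_path: str | Path, group_map_path: str | Path) -> None:
    Path(values_path).parent.mkdir(parents=True, exist_ok=True)
    table.values.to_csv(values_path)
    pd.DataFrame(
        {"variable": table.indicator_names,
         "group": [table.group_map[c] for c in table.indicator_names]}
    ).to_csv(group_map_path, index=False)


def read_indicators(values_path: str | Path, group_map_path: str | Path) -> IndicatorTable:
    df = _read_numeric(Path(values_path))
    gm = _read_group_map(Path(group_map_path), list(df.columns))
    return IndicatorTable(df, gm, summary_rule={c: "unknown" for c in df.columns})


def write_model_bundle(models: dict, path: str | Path, meta: dict | None = None) -> None:
    """Serialize fitted models with a format version tag (pickle container)."""
    payload = {"format_version": BUNDLE_VERSION, "models": models, "meta": meta or {}}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def read_model_bundle(path: str | Path) -> tuple[dict, dict]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported model bundle version: {payload.get('format_version')}")
    return payload["models"], payload["meta"]
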