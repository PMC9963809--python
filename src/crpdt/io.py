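"""Config parsing, CSV readers/writers, and run manifests.

All array data travel as small headered CSVs with '.' decimal points and
deterministic column order; summaries are JSON.  Configuration files are
YAML mappings validated against the engine dataclasses: unknown keys are
rejected by name, and every physical invariant is checked at load time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine
from .clonostats import COUNT_COLUMNS, CloneCountTable
from .kinetics import KineticsSeries
from .spectra import Spectrum

__all__ = [
    "DataError",
    "load_config",
    "save_config",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_series_csv",
    "write_series_csv",
    "read_counts_csv",
    "write_counts_csv",
    "write_manifest",
    "write_tally_csv",
]


class DataError(ValueError):
    """Malformed data file (bad header, bad row, wrong columns)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "geometry": engine.Geometry,
    "source": engine.SourceConfig,
    "switches": engine.PhysicsSwitches,
    "transport": engine.TransportParams,
}
_TOP_KEYS = {"scenario_id", "seed", "primaries", *_SECTION_TYPES}


def _build_section(cls, mapping: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in config section {section!r}: {sorted(unknown)}"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return cls(**coerced)


def load_config(path) -> engine.ScenarioConfig:
    """Load and validate a scenario configuration from YAML.

    Unknown keys raise with the offending name; dataclass invariants
    (refractive index, probabilities, nesting of the geometry) raise with
    the violated constraint.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    if "scenario_id" not in raw:
        raise ValueError("config must name a scenario_id")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            kwargs[section] = _build_section(cls, raw[section] or {}, section)
    if "primaries" in raw and "source" not in kwargs:
        kwargs["source"] = engine.SourceConfig(primaries=int(raw["primaries"]))
    return engine.scenario_config(
        raw["scenario_id"], seed=int(raw.get("seed", 0)), **kwargs
    )


def save_config(cfg: engine.ScenarioConfig, path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    out = {
        "scenario_id": cfg.scenario_id,
        "seed": cfg.seed,
        "geometry": dataclasses.asdict(cfg.geometry),
        "source": dataclasses.asdict(cfg.source),
        "switches": dataclasses.asdict(cfg.switches),
        "transport": dataclasses.asdict(cfg.transport),
    }
    for section in ("geometry", "source"):
        out[section] = {
            k: list(v) if isinstance(v, tuple) else v for k, v in out[section].items()
        }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------


def _read_csv_strict(path, expected_columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"{path}: cannot parse CSV ({exc})") from exc
    if list(df.columns) != expected_columns:
        extra = [c for c in df.columns if c not in expected_columns]
        missing = [c for c in expected_columns if c not in df.columns]
        raise DataError(
            f"{path}: expected columns {expected_columns}; "
            f"missing {missing or 'none'}, unexpected {extra or 'none'}"
        )
    for col in expected_columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if col not in ("condition",) and bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise DataError(f"{path}: malformed value in column {col!r} at line {line}")
    return df


def read_spectrum_csv(path, kind: str = "emission") -> Spectrum:
    df = _read_csv_strict(path, ["wavelength_nm", "value"])
    return Spectrum(
        df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float), kind
    )


def write_spectrum_csv(spec: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths_nm, "value": spec.values}
    ).to_csv(path, index=False, float_format="%.10g")


def read_series_csv(path, **meta) -> KineticsSeries:
    df = _read_csv_strict(path, ["time_min", "signal"])
    return KineticsSeries(
        times_min=df["time_min"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        **meta,
    )


def write_series_csv(series: KineticsSeries, path) -> None:
    pd.DataFrame({"time_min": series.times_min, "signal": series.signal}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_counts_csv(path, **table_kwargs) -> CloneCountTable:
    df = _read_csv_strict(path, COUNT_COLUMNS)
    return CloneCountTable(data=df, **table_kwargs)


def write_counts_csv(table: CloneCountTable, path) -> None:
    table.data[COUNT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run products
# ---------------------------------------------------------------------------


def write_tally_csv(tally: engine.Tally, out_dir) -> list[Path]:
    """One CSV per phase-space surface with origin-tagged weight columns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    centers = 0.5 * (tally.edges_nm[1:] + tally.edges_nm[:-1])
    paths = []
    for surface in tally.SURFACES:
        cols = {"wavelength_nm": centers}
        for origin in sorted(tally.hist[surface]):
            cols[origin] = tally.hist[surface][origin]
        path = out_dir / f"spectrum_{surface}.csv"
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
        paths.append(path)
    return paths


def write_manifest(manifest: dict, path) -> None:
    payload = dict(manifest)
    payload["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    Path(path).write_text(json.dumps(payload, indent=2, default=str, sort_keys=True))
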