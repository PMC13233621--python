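"""Readers/writers for the on-disk formats and the run manifest.

Monthly fields round-trip through long-format CSV (cell_id, year, month,
value) and CF-style NetCDF (dims cell/time, written with xarray's
NetCDF-3 backend); networks through edge-list CSV (source_cell,
target_cell, year, month, mm_month; zero-weight links dropped on
write); land use and adaptation profiles through flat CSV.  A JSON run
manifest records the configuration, mode flags, seeds and input hashes
needed to regenerate any output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .adaptation import AdaptationProfile
from .hydro import MonthlyField
from .network import MoistureNetwork
from .synthetic import LanduseSeries

__all__ = [
    "read_field",
    "write_field",
    "read_network",
    "write_network",
    "read_landuse",
    "write_landuse",
    "write_profile",
    "read_profile",
    "write_manifest",
    "load_config",
    "save_config",
    "file_sha256",
]


def _check_complete_axis(years: np.ndarray, months: np.ndarray, where: str):
    lin = years * 12 + (months - 1)
    gaps = np.flatnonzero(np.diff(lin) != 1)
    if len(gaps):
        y, m = years[gaps[0]], months[gaps[0]]
        raise ValueError(
            f"{where}: missing month after {int(y)}-{int(m):02d}; "
            "refusing to fill silently"
        )


def write_field(path: str | Path, field: MonthlyField) -> Path:
    """Write a monthly field; format chosen by suffix (.csv or .nc)."""
    path = Path(path)
    if path.suffix == ".csv":
        field.to_frame().to_csv(path, index=False)
    elif path.suffix in (".nc", ".cdf"):
        ds = xr.Dataset(
            {field.name: (("cell", "time"), field.values)},
            coords={
                "cell": np.arange(field.n_cells),
                "year": ("time", field.years),
                "month": ("time", field.months),
            },
            attrs={"units": field.units},
        )
        ds.to_netcdf(path, engine="scipy")
    else:
        raise ValueError(f"unsupported field format {path.suffix!r}")
    return path


def read_field(path: str | Path, name: str | None = None) -> MonthlyField:
    """Read a monthly field written by :func:`write_field`."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        required = {"cell_id", "year", "month", "value"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        df = df.sort_values(["cell_id", "year", "month"], kind="stable")
        cells = df["cell_id"].unique()
        n_cells = len(cells)
        first = df[df["cell_id"] == cells[0]]
        years = first["year"].to_numpy()
        months = first["month"].to_numpy()
        if len(df) != n_cells * len(years):
            raise ValueError(f"{path}: ragged cell/time table")
        _check_complete_axis(years, months, str(path))
        values = df["value"].to_numpy().reshape(n_cells, len(years))
        return MonthlyField(values, years, months,
                           name=name or "precipitation")
    if path.suffix in (".nc", ".cdf"):
        with xr.open_dataset(path, engine="scipy") as ds:
            var = name or next(iter(ds.data_vars))
            years = ds["year"].values.astype(int)
            months = ds["month"].values.astype(int)
            _check_complete_axis(years, months, str(path))
            return MonthlyField(
                ds[var].values.astype(float), years, months, name=var,
                units=ds.attrs.get("units", "mm/month"),
            )
    raise ValueError(f"unsupported field format {path.suffix!r}")


def write_network(path: str | Path, net: MoistureNetwork) -> Path:
    """Edge-list CSV; zero-weight (link, month) rows are dropped."""
    net.to_frame(drop_zero=True).to_csv(Path(path), index=False)
    return Path(path)


def read_network(path: str | Path, n_cells: int | None = None) -> MoistureNetwork:
    """Read an edge-list CSV back into a dense-time network.

    Months absent for a link are zero-filled (they were dropped on
    write); duplicate (source, target, year, month) rows and negative
    weights are errors.
    """
    df = pd.read_csv(path)
    required = {"source_cell", "target_cell", "year", "month", "mm_month"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if (df["mm_month"] < 0).any():
        bad = df[df["mm_month"] < 0].iloc[0]
        raise ValueError(
            f"{path}: negative weight on link "
            f"{int(bad.source_cell)}->{int(bad.target_cell)}"
        )
    key = ["source_cell", "target_cell", "year", "month"]
    if df.duplicated(subset=key).any():
        raise ValueError(f"{path}: duplicate (source, target, year, month) rows")
    lin = df["year"] * 12 + df["month"] - 1
    lo, hi = int(lin.min()), int(lin.max())
    n_time = hi - lo + 1
    t = np.arange(lo, hi + 1)
    years, months = t // 12, t % 12 + 1
    pairs = df[["source_cell", "target_cell"]].drop_duplicates().to_numpy()
    index = {tuple(p): j for j, p in enumerate(map(tuple, pairs))}
    weights = np.zeros((len(pairs), n_time))
    rows = df.apply(
        lambda r: index[(r["source_cell"], r["target_cell"])], axis=1
    ).to_numpy()
    weights[rows, (lin - lo).to_numpy()] = df["mm_month"].to_numpy()
    cells = int(max(pairs.max() + 1, n_cells or 0))
    return MoistureNetwork(
        pairs[:, 0], pairs[:, 1], weights, years, months, cells
    )


def write_landuse(path: str | Path, lu: LanduseSeries) -> Path:
    n_years, n_cells = lu.fraction.shape
    pd.DataFrame(
        {
            "cell_id": np.tile(np.arange(n_cells), n_years),
            "year": np.repeat(lu.years, n_cells),
            "fraction": lu.fraction.ravel(),
        }
    ).to_csv(Path(path), index=False)
    return Path(path)


def read_landuse(path: str | Path) -> LanduseSeries:
    df = pd.read_csv(path).sort_values(["year", "cell_id"], kind="stable")
    years = df["year"].unique()
    n_cells = df["cell_id"].nunique()
    return LanduseSeries(years, df["fraction"].to_numpy().reshape(len(years), n_cells))


def write_profile(path: str | Path, profile: AdaptationProfile) -> Path:
    profile.to_frame().to_csv(Path(path), index=False)
    return Path(path)


def read_profile(path: str | Path) -> AdaptationProfile:
    df = pd.read_csv(path)
    def opt(col):
        a = df[col].to_numpy()
        return None if np.all(np.isnan(a)) else a
    return AdaptationProfile(
        mu_map=df["mu_map"].to_numpy(),
        delta_map=df["delta_map"].to_numpy(),
        mu_mcwd=df["mu_mcwd"].to_numpy(),
        delta_mcwd=df["delta_mcwd"].to_numpy(),
        sigma=opt("sigma"),
        map_crit=opt("map_crit"),
        mcwd_crit=opt("mcwd_crit"),
        guard=df["guard"].to_numpy(dtype=bool),
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    seeds: dict,
    inputs: dict[str, str | Path] | None = None,
    extra: dict | None = None,
) -> Path:
    """JSON run manifest: config snapshot, seeds, input file hashes."""
    manifest = {
        "version": 1,
        "config": config,
        "seeds": seeds,
        "input_hashes": {
            k: file_sha256(v) for k, v in (inputs or {}).items()
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (versioned flat mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(path: str | Path, cfg: dict) -> Path:
    Path(path).write_text(yaml.safe_dump({"schema_version": 1, **cfg}))
    return Path(path)
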