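"""File formats: self-described NetCDF grids, CSV tables, JSON, YAML.

One dialect per kind of artifact: gridded data travels as classic
NetCDF written through the scipy backend (layer names + CF-style unit
attributes), tables as plain CSV with documented headers, model ledgers
and summaries as JSON, configuration as YAML.  JSON is written with
sorted keys so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import xarray as xr
import yaml

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_json",
    "read_json",
    "load_yaml",
    "config_hash",
    "cleanup_on_error",
]

# classic NetCDF has no 64-bit ints or booleans
_DTYPE_FALLBACK = {np.dtype("int64"): np.int32, np.dtype("bool"): np.int8}


def write_dataset(ds: xr.Dataset, path: str | Path) -> Path:
    """Write a dataset as classic NetCDF (scipy backend)."""
    path = Path(path)
    ds = ds.copy()
    for name in list(ds.variables):
        dt = ds[name].dtype
        if dt in _DTYPE_FALLBACK:
            ds[name] = ds[name].astype(_DTYPE_FALLBACK[dt])
    ds.to_netcdf(path, engine="scipy")
    return path


def read_dataset(path: str | Path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return out


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    canon = json.dumps(config, sort_keys=True, default=_json_default)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


@contextmanager
def cleanup_on_error(*paths: str | Path):
    """Remove the named output files if the block raises."""
    try:
        yield
    except BaseException:
        for p in paths:
            Path(p).unlink(missing_ok=True)
        raise
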