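"""TIFF/CSV/config input-output and run manifests.

Images travel as 32-bit float TIFF in physical units (reflectance/ΔR), or
as 16-bit TIFF with the scale recorded in a plain-text sidecar
``<image>.scale.txt`` (value-per-count); 16-bit files without a sidecar are
returned in raw counts with ``meta["scaled"] = False``.  Result tables are
CSV with a fixed column order, re-readable losslessly to float precision.
Every CLI run writes a JSON manifest echoing the configuration, seed and
package version so runs can be reproduced.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .dispersion import BUILTIN_TABLES, DispersionTable
from .optics import OpticalLayer, OpticalStack

__all__ = [
    "read_image",
    "write_image",
    "write_results",
    "read_results",
    "write_manifest",
    "load_config",
    "stack_from_config",
]


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a grayscale TIFF as float64 plus metadata.

    16-bit inputs are rescaled by the sidecar ``<path>.scale.txt`` factor
    when present; otherwise returned in counts with ``meta["scaled"]``
    False.  Non-grayscale input and missing/corrupt files raise with the
    offending path in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read TIFF image {path}: {exc}") from exc
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single grayscale plane, got shape {data.shape}")
    meta = {"path": str(path), "dtype": str(data.dtype), "scaled": True}
    out = data.astype(np.float64)
    if data.dtype == np.uint16:
        sidecar = path.with_name(path.name + ".scale.txt")
        if sidecar.exists():
            scale = float(sidecar.read_text().strip())
            out = out * scale
            meta["scale"] = scale
        else:
            meta["scaled"] = False
    return out, meta


def write_image(path, array: np.ndarray, bits: int = 32) -> None:
    """Write a 2-D array as TIFF.

    ``bits=32``: float32, values as-is.  ``bits=16``: linearly scaled to
    the full uint16 range with the value-per-count factor recorded in the
    ``<path>.scale.txt`` sidecar (offset-free, so only for non-negative
    data).
    """
    path = Path(path)
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise ValueError("only single-plane grayscale images are written")
    if bits == 32:
        tifffile.imwrite(path, arr.astype(np.float32))
    elif bits == 16:
        vmax = float(arr.max())
        if arr.min() < 0:
            raise ValueError("16-bit output requires non-negative data")
        scale = vmax / 65535.0 if vmax > 0 else 1.0
        tifffile.imwrite(path, np.round(arr / scale).astype(np.uint16))
        path.with_name(path.name + ".scale.txt").write_text(f"{scale:.12e}\n")
    else:
        raise ValueError("bits must be 16 or 32")


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV (fixed column order, full precision)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(out_dir, config_echo: dict, seed: int) -> Path:
    """Write the reproducibility manifest for a CLI run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "sprimage",
        "version": __version__,
        "seed": seed,
        "config": config_echo,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


# ---------------------------------------------------------------------------
# plain-text configuration


def load_config(path) -> dict:
    """Load a YAML run configuration; see the config reference in README."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _layer_from_config(entry: dict, tables: dict[str, DispersionTable]) -> OpticalLayer:
    name = entry.get("name", entry.get("material", "layer"))
    thickness = entry.get("thickness_nm")
    if "material" in entry:
        mat = entry["material"]
        if mat not in tables:
            raise ValueError(f"unknown material '{mat}' (have {sorted(tables)})")
        return OpticalLayer(name, tables[mat], thickness)
    if "n" in entry:
        n = complex(entry["n"], entry.get("k", 0.0))
        return OpticalLayer(name, n * n, thickness)
    if "epsilon_real" in entry:
        eps = complex(entry["epsilon_real"], entry.get("epsilon_imag", 0.0))
        return OpticalLayer(name, eps, thickness)
    raise ValueError(f"layer '{name}': give material, n(+k) or epsilon_real(+imag)")


def _table_from_config(entry: dict) -> DispersionTable:
    return DispersionTable(
        wavelength_nm=entry["wavelength_nm"],
        n=entry["n"],
        k=entry.get("k", np.zeros(len(entry["n"]))),
        name=entry.get("name", "custom"),
    )


def stack_from_config(cfg: dict, wavelength_nm: float) -> OpticalStack:
    """Build an OpticalStack from the ``stack`` section of a config.

    Built-in dispersion tables (``gold``, ``water``) can be overridden or
    extended with a ``dispersion_tables`` section mapping material names to
    tabulated wavelength/n/k columns.
    """
    tables = dict(BUILTIN_TABLES)
    for key, entry in (cfg.get("dispersion_tables") or {}).items():
        tables[key] = _table_from_config(entry)
    layers = [_layer_from_config(e, tables) for e in cfg["stack"]["layers"]]
    return OpticalStack(layers, wavelength_nm)
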