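"""Readers and writers for the pipeline's standard formats.

* Spectra tables: tab-separated text; the header row lists the wavelengths
  in nm (plus a final ``class`` column when labels are present), one row
  per fruit.
* Hypercubes: ENVI format -- an ASCII ``.hdr`` with the layout and the
  wavelength list next to a flat binary file (bsq / bil / bip interleave,
  float32), the lingua franca of hyperspectral camera software.
* Label/mask images: plain PGM (P2) with a sidecar legend.
* Configuration: one YAML/JSON document; unknown keys are rejected so a
  typo in a candidate grid cannot silently vanish.

All writes go through a write-temp-then-rename helper, so readers never
observe a half-written file.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .types import BerryvisError, Hypercube, SpectraSet, validate_grid


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_bytes(path: str | Path, data: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# spectra tables


def write_spectra_table(data: SpectraSet, path: str | Path) -> None:
    """Tab-separated table: wavelength header, one row per fruit, final
    ``class`` column with the severity rank (1-4)."""
    cols = [f"{w:g}" for w in data.grid] + ["class"]
    df = pd.DataFrame(
        np.column_stack([data.reflectance, data.labels.astype(float)]),
        columns=cols,
    )
    df["class"] = df["class"].astype(int)
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def read_spectra_table(path: str | Path) -> SpectraSet:
    """Parse a spectra table, validating the wavelength header and labels."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    has_labels = cols and cols[-1].strip().lower() == "class"
    wl_cols = cols[:-1] if has_labels else cols
    try:
        grid = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise BerryvisError(f"non-numeric wavelength header in {path}") from exc
    if not np.all(np.diff(grid) > 0):
        raise BerryvisError(f"wavelength header not strictly increasing in {path}")
    validate_grid(grid)
    X = df[wl_cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise BerryvisError(f"ragged or non-numeric spectra rows in {path}")
    if has_labels:
        labels = df[cols[-1]].to_numpy()
        if not np.all(np.isin(labels, [1, 2, 3, 4])):
            raise BerryvisError(f"unknown class labels in {path} (expect 1-4)")
        labels = labels.astype(int)
    else:
        labels = np.ones(X.shape[0], dtype=int)
    return SpectraSet(X, grid, labels)


# ---------------------------------------------------------------------------
# ENVI cubes

_INTERLEAVES = ("bsq", "bil", "bip")


def write_envi_cube(
    cube: Hypercube, path: str | Path, interleave: str = "bsq"
) -> None:
    """Write ``<path>.hdr`` + ``<path>.img`` (float32, little-endian)."""
    if interleave not in _INTERLEAVES:
        raise BerryvisError(f"interleave must be one of {_INTERLEAVES}")
    base = Path(path)
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:g}" for w in cube.grid)
    hdr = (
        "ENVI\n"
        "description = {berryvis synthetic reflectance cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "reflectance scale factor = 1.0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    arr = cube.cube.astype("<f4")
    if interleave == "bsq":
        flat = np.transpose(arr, (2, 0, 1))
    elif interleave == "bil":
        flat = np.transpose(arr, (0, 2, 1))
    else:  # bip
        flat = arr
    atomic_write_text(base.with_suffix(".hdr"), hdr)
    atomic_write_bytes(base.with_suffix(".img"), flat.tobytes())


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    lines = iter(text.splitlines())
    for line in lines:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            parts = [val]
            for more in lines:
                parts.append(more)
                if "}" in more:
                    break
            val = " ".join(parts)
        fields[key] = val.strip().strip("{}").strip()
    return fields


def read_envi_cube(path: str | Path) -> Hypercube:
    """Read an ENVI header + binary pair into a reflectance hypercube.

    Values are divided by the header's ``reflectance scale factor`` when
    present, so the cube is always a reflectance fraction.
    """
    base = Path(path)
    hdr_path = base if base.suffix == ".hdr" else base.with_suffix(".hdr")
    if not hdr_path.exists():
        raise BerryvisError(f"ENVI header not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise BerryvisError(f"ENVI header missing field {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise BerryvisError(f"unsupported interleave {interleave!r}")
    if "wavelength" not in fields:
        raise BerryvisError("ENVI header has no wavelength list")
    grid = np.array([float(v) for v in fields["wavelength"].split(",")])
    dtype_code = int(fields.get("data type", 4))
    dtypes = {1: "u1", 2: "<i2", 3: "<i4", 4: "<f4", 5: "<f8", 12: "<u2"}
    if dtype_code not in dtypes:
        raise BerryvisError(f"unsupported ENVI data type {dtype_code}")
    img_path = hdr_path.with_suffix(".img")
    if not img_path.exists():
        raise BerryvisError(f"ENVI binary not found: {img_path}")
    raw = np.fromfile(img_path, dtype=dtypes[dtype_code])
    expected = rows * cols * bands
    if raw.size != expected:
        raise BerryvisError(
            f"ENVI size mismatch: header implies {expected} values, "
            f"binary holds {raw.size}"
        )
    if interleave == "bsq":
        arr = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip
        arr = raw.reshape(rows, cols, bands)
    arr = arr.astype(float)
    scale = float(fields.get("reflectance scale factor", 1.0))
    if scale != 1.0:
        arr = arr / scale
    return Hypercube(arr, grid)


# ---------------------------------------------------------------------------
# label / mask images


def write_pgm(image: np.ndarray, path: str | Path, legend: dict[int, str] | None = None) -> None:
    """Plain (P2) portable graymap plus optional sidecar legend text."""
    img = np.asarray(image, dtype=int)
    if img.ndim != 2 or img.min() < 0:
        raise BerryvisError("PGM image must be a 2-D non-negative int array")
    maxval = max(int(img.max()), 1)
    lines = [f"P2", f"{img.shape[1]} {img.shape[0]}", f"{maxval}"]
    lines += [" ".join(str(v) for v in row) for row in img]
    atomic_write_text(path, "\n".join(lines) + "\n")
    if legend is not None:
        ltxt = "\n".join(f"{k}\t{v}" for k, v in sorted(legend.items()))
        atomic_write_text(str(path) + ".legend.txt", ltxt + "\n")


def read_pgm(path: str | Path) -> np.ndarray:
    tokens = Path(path).read_text().split()
    if tokens[0] != "P2":
        raise BerryvisError("only plain (P2) PGM supported")
    w, h = int(tokens[1]), int(tokens[2])
    data = np.array(tokens[4: 4 + w * h], dtype=int)
    return data.reshape(h, w)


# ---------------------------------------------------------------------------
# configuration

_SCHEMA: dict[str, Any] = {
    "seed": int,
    "task": str,  # "two_class" | "four_class"
    "simulate": {
        "class_counts": list,
        "effect_carotenoid": float,
        "effect_water": float,
        "effect_sugar": float,
        "severity_sd": float,
        "scatter_sd": float,
        "baseline_sd": float,
        "noise_sd": float,
        "informative_bands": list,
        "informative_effect": float,
    },
    "scene": {
        "n_fruit": int,
        "rows": int,
        "cols": int,
        "defect_fraction": float,
        "glare_fraction": float,
    },
    "rdcv": {
        "n_outer": int,
        "n_inner": int,
        "n_runs": int,
        "stratified": bool,
        "selection": str,
        "lv_grid": list,
        "n_select_grid": list,
        "pipelines": list,
        "stability_threshold": float,
    },
}


def _check_keys(doc: dict, schema: dict, prefix: str = "") -> None:
    for key, val in doc.items():
        if key not in schema:
            raise BerryvisError(f"unknown config key {prefix}{key!r}")
        expect = schema[key]
        if isinstance(expect, dict):
            if not isinstance(val, dict):
                raise BerryvisError(f"config section {prefix}{key!r} must be a mapping")
            _check_keys(val, expect, prefix=f"{prefix}{key}.")


def validate_config(doc: dict) -> dict:
    """Schema-check a pipeline config document (unknown keys rejected)."""
    if not isinstance(doc, dict):
        raise BerryvisError("config must be a mapping")
    _check_keys(doc, _SCHEMA)
    rdcv = doc.get("rdcv", {})
    if rdcv.get("n_outer", 10) < 2 or rdcv.get("n_inner", 9) < 2:
        raise BerryvisError("rdcv.n_outer and rdcv.n_inner must be >= 2")
    task = doc.get("task", "two_class")
    if task not in ("two_class", "four_class"):
        raise BerryvisError("task must be 'two_class' or 'four_class'")
    return doc


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    return validate_config(doc)
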