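"""Readers and writers for the formats the pipeline consumes and emits.

Images: TIFF (via tifffile) and PNG (via Pillow).  Tables: CSV with a header
row, comma-separated, '.' decimal.  Configuration: YAML.  Reports: JSON.
Missing required CSV columns raise :class:`FormatError` naming the column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from chipscreen.doseresponse import DoseResponseData
from chipscreen.exceptions import FormatError
from chipscreen.fcs import FcsCurve
from chipscreen.transport import Molecule

_TIFF_EXTS = {".tif", ".tiff"}
_PNG_EXTS = {".png"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG image; dtype is preserved for TIFF."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _TIFF_EXTS:
        return tifffile.imread(path)
    if ext in _PNG_EXTS:
        return np.asarray(Image.open(path))
    raise FormatError(f"unsupported image extension {ext!r} (use .tif/.tiff/.png)")


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a TIFF (any dtype) or PNG (uint8/uint16) image."""
    path = Path(path)
    ext = path.suffix.lower()
    pixels = np.asarray(pixels)
    if ext in _TIFF_EXTS:
        tifffile.imwrite(path, pixels)
        return
    if ext in _PNG_EXTS:
        if pixels.dtype not in (np.uint8, np.uint16):
            pixels = np.clip(pixels, 0, 255).astype(np.uint8)
        Image.fromarray(pixels).save(path)
        return
    raise FormatError(f"unsupported image extension {ext!r} (use .tif/.tiff/.png)")


def _require_columns(frame: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_fcs_curve(path: str | Path) -> FcsCurve:
    """Read an autocorrelation curve from CSV with columns (lag_s, g)."""
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, ["lag_s", "g"], path)
    return FcsCurve(lags=frame["lag_s"].to_numpy(), g=frame["g"].to_numpy())


def write_fcs_curve(path: str | Path, curve: FcsCurve) -> None:
    pd.DataFrame({"lag_s": curve.lags, "g": curve.g}).to_csv(path, index=False)


def read_molecules(path: str | Path) -> list[Molecule]:
    """Read molecules from CSV with columns (name, mw_g_per_mol, density_g_per_cm3)."""
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, ["name", "mw_g_per_mol", "density_g_per_cm3"], path)
    return [
        Molecule(str(row["name"]), float(row["mw_g_per_mol"]), float(row["density_g_per_cm3"]))
        for _, row in frame.iterrows()
    ]


def read_dose_response(path: str | Path) -> DoseResponseData:
    """Read a dose-viability table from CSV with columns (dose, viability)."""
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, ["dose", "viability"], path)
    return DoseResponseData(
        concentrations=frame["dose"].to_numpy(), viabilities=frame["viability"].to_numpy()
    )


def write_dose_response(path: str | Path, data: DoseResponseData) -> None:
    pd.DataFrame({"dose": data.concentrations, "viability": data.viabilities}).to_csv(
        path, index=False
    )


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    try:
        with open(path) as fh:
            obj = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: malformed YAML: {exc}") from exc
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: expected a YAML mapping at top level")
    return obj


def write_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
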