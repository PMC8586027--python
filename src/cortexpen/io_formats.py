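"""File formats, configuration and run manifests.

Localization tables travel as ThunderSTORM-dialect CSV
(``frame, x [nm], y [nm], uncertainty [nm], intensity [photon], channel``),
images as TIFF with the pixel size stored in the resolution tags,
force curves as ``time [s], force [nN], z [um]`` CSV, configuration as
YAML, and every CLI run writes a JSON manifest (config, seeds,
versions) from which it can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .smlm_core import validate_localizations

logger = logging.getLogger(__name__)

# canonical column name -> CSV header (ThunderSTORM dialect)
_CSV_COLUMNS = {
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "uncertainty": "uncertainty [nm]",
    "intensity": "intensity [photon]",
    "channel": "channel",
}


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )


# ---------------------------------------------------------------------------
# Localization CSV
# ---------------------------------------------------------------------------


def write_localizations(table: pd.DataFrame, path) -> None:
    out = table[list(_CSV_COLUMNS)].rename(columns=_CSV_COLUMNS)
    out.to_csv(path, index=False)


def read_localizations(path) -> pd.DataFrame:
    """Read a ThunderSTORM-dialect localization CSV (header-driven).

    Rows with non-finite coordinates or uncertainty <= 0 are dropped
    with a logged count; a missing required column is a hard error.
    """
    raw = pd.read_csv(path)
    reverse = {v: k for k, v in _CSV_COLUMNS.items()}
    missing = [hdr for hdr in _CSV_COLUMNS.values() if hdr not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    table = raw.rename(columns=reverse)[list(_CSV_COLUMNS)]
    table["frame"] = table["frame"].astype(int)
    table["channel"] = table["channel"].astype(int)
    return validate_localizations(table)


# ---------------------------------------------------------------------------
# TIFF images
# ---------------------------------------------------------------------------


def write_image(path, data: np.ndarray, pixel_size_nm: float) -> None:
    """Write a single- or multi-channel TIFF with the pixel size in the resolution tags."""
    if pixel_size_nm <= 0:
        raise ValueError("pixel size must be positive")
    px_per_cm = 1e7 / pixel_size_nm
    tifffile.imwrite(
        path,
        np.asarray(data, np.float32),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def read_image(path, pixel_size_nm: float | None = None) -> tuple[np.ndarray, float]:
    """Read a TIFF; returns (array, pixel size nm).

    A ``pixel_size_nm`` override always wins over file metadata; if
    neither is available it is a hard error.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        page = tif.pages[0]
        meta_px = None
        try:
            xres = page.tags["XResolution"].value
            unit = page.tags.get("ResolutionUnit")
            per_unit = xres[0] / xres[1]
            # XResolution of 1 is the TIFF "no resolution set" default
            if per_unit > 0 and per_unit != 1:
                unit_cm = {2: 2.54, 3: 1.0}.get(getattr(unit, "value", unit) if unit else 3, 1.0)
                meta_px = 1e7 * unit_cm / per_unit
        except (KeyError, ZeroDivisionError, TypeError):
            meta_px = None
    if pixel_size_nm is not None:
        return data, float(pixel_size_nm)
    if meta_px is None:
        raise ValueError(f"{path}: pixel size not in metadata and no override given")
    return data, float(meta_px)


# ---------------------------------------------------------------------------
# Force-curve CSV
# ---------------------------------------------------------------------------

_FORCE_COLUMNS = {"time": "time [s]", "force": "force [nN]", "z": "z [um]"}


def write_force_curve(curve: pd.DataFrame, path) -> None:
    curve[list(_FORCE_COLUMNS)].rename(columns=_FORCE_COLUMNS).to_csv(path, index=False)


def read_force_curve(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    missing = [hdr for hdr in _FORCE_COLUMNS.values() if hdr not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    return raw.rename(columns={v: k for k, v in _FORCE_COLUMNS.items()})[list(_FORCE_COLUMNS)]


# ---------------------------------------------------------------------------
# Configuration and manifests
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their field-standard defaults."""

    smlm_pixel_size_nm: float = 10.0  # rendering pixel
    sim_pixel_size_nm: float = 40.0
    confocal_pixel_size_nm: float = 80.0
    bin_width_px: int = 20
    bin_width_nm: float = 200.0  # = 20 rendering pixels
    profile_half_width_nm: float = 600.0
    pairing_d_min_nm: float = 200.0
    pairing_d_max_nm: float = 400.0
    tail_radius_nm: float = 50.0
    reference_length_nm: float = 317.0
    psf_sigma_confocal_nm: float = 170.0
    psf_sigma_sim_nm: float = 60.0
    rcc_window_frames: int = 2000
    rcc_subpixel_nm: float = 20.0
    rollingball_radius_px: float = 50.0
    band_px: int = 8
    grouping_distance_px: float = 20.0
    relax_window_s: tuple = (20.0, 30.0)
    drug_pre_window_s: float = 20.0
    drug_post_window_s: float = 300.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "smlm_pixel_size_nm", "sim_pixel_size_nm", "confocal_pixel_size_nm",
            "bin_width_nm", "profile_half_width_nm", "pairing_d_min_nm",
            "pairing_d_max_nm", "tail_radius_nm", "reference_length_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def write_manifest(path, config: PipelineConfig, command: str, inputs=None, outputs=None) -> None:
    """JSON run manifest: command, config, seed and package versions."""
    import cortexpen

    manifest = {
        "command": command,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": list(map(str, inputs or [])),
        "outputs": list(map(str, outputs or [])),
        "versions": {
            "cortexpen": cortexpen.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
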