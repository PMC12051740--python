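"""File formats, configuration, and logging for the spheroid pipeline.

Brillouin maps travel as single-channel float32 TIFF (shift in GHz, pixel
size carried in the image description) or as plain CSV grids with a
commented metadata header.  Cohorts are indexed by a manifest CSV with one
row per spheroid (file, spheroid_id, line, day, seed).  Run configuration
is a schema-validated YAML file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger("mechspheroid")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MechSpheroidError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MechSpheroidError):
    """Unreadable or invalid map/manifest file."""


class ConfigurationError(MechSpheroidError):
    """Invalid or incomplete run configuration."""


class SizingError(MechSpheroidError):
    """Image extent too small for the requested spheroid geometry."""


class SegmentationError(MechSpheroidError):
    """Foreground segmentation produced an empty mask.

    Carries the threshold that was applied, for diagnosis.
    """

    def __init__(self, message: str, threshold: float | None = None):
        super().__init__(message)
        self.threshold = threshold


class DegenerateZoneError(MechSpheroidError):
    """Core/periphery split produced an empty zone."""


class UndefinedStatisticError(MechSpheroidError):
    """A statistic is undefined for the given sample (e.g. zero variance)."""


class PipelineStageError(MechSpheroidError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Core container
# ---------------------------------------------------------------------------

@dataclass
class BrillouinMap:
    """A 2D grid of Brillouin frequency shifts in GHz.

    Parameters
    ----------
    shifts
        2D float array of per-pixel Brillouin shifts (GHz).
    pixel_size
        Lateral pixel size in micrometres (the scan step).
    metadata
        Free-form key/value sidecar information (label, day, seed, ...).
    """

    shifts: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 2:
            raise FormatError("shift grid must be 2D")
        if min(self.shifts.shape) < 16:
            raise FormatError("shift grid must be at least 16x16")
        if not np.all(np.isfinite(self.shifts)):
            raise FormatError("shift grid contains non-finite values")
        if not self.pixel_size > 0:
            raise FormatError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.shifts.shape


# ---------------------------------------------------------------------------
# Map I/O
# ---------------------------------------------------------------------------

_CSV_FMT = "%.12g"  # 12 significant digits for exact textual round trips


def write_map(brillouin_map: BrillouinMap, path: str | Path) -> Path:
    """Write a map as float32 TIFF (.tif/.tiff) or CSV grid (.csv)."""
    path = Path(path)
    meta = dict(brillouin_map.metadata)
    meta["pixel_size_um"] = brillouin_map.pixel_size
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            brillouin_map.shifts.astype(np.float32),
            description=json.dumps(meta),
        )
    elif path.suffix.lower() == ".csv":
        header = "\n".join(f"{k}={v}" for k, v in sorted(meta.items()))
        np.savetxt(path, brillouin_map.shifts, fmt=_CSV_FMT,
                   delimiter=",", header=header)
    else:
        raise FormatError(f"unsupported map extension: {path.suffix!r}")
    return path


def read_map(path: str | Path) -> BrillouinMap:
    """Read a map written by :func:`write_map`.

    Raises :class:`FormatError` for unsupported extensions, unparseable
    content, or grids containing NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict = {}
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tif:
                arr = tif.asarray()
                desc = tif.pages[0].tags.get("ImageDescription")
                if desc is not None:
                    try:
                        meta = json.loads(desc.value)
                    except (json.JSONDecodeError, TypeError):
                        meta = {}
        except (tifffile.TiffFileError, ValueError) as exc:
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    elif path.suffix.lower() == ".csv":
        try:
            arr = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                stripped = line.lstrip("# ").strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    meta[key.strip()] = _coerce(val.strip())
    else:
        raise FormatError(f"unsupported map extension: {path.suffix!r}")
    if np.isnan(np.asarray(arr, dtype=float)).any():
        raise FormatError(f"{path}: shift grid contains NaN")
    pixel_size = float(meta.pop("pixel_size_um", 1.0))
    return BrillouinMap(np.asarray(arr, dtype=np.float64), pixel_size, meta)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["file", "spheroid_id", "line", "day", "seed"]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such manifest: {path}")
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    if manifest["spheroid_id"].duplicated().any():
        raise FormatError("manifest contains duplicate spheroid IDs")
    if check_files:
        base = path.parent
        for f in manifest["file"]:
            candidate = Path(f)
            if not candidate.is_absolute():
                candidate = base / candidate
            if not candidate.exists():
                raise FormatError(f"manifest references missing file: {f}")
    return manifest


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_normal": 83,
        "n_cancer": 85,
        "days": [2, 5, 8],
        "pixel_size": 1.0,
        "image_extent": None,  # None -> sized automatically per phenotype
    },
    "segment": {
        "background_quantile": 0.25,
        "k_sigma": 3.0,
    },
    "features": {
        "core_fraction": 0.4,
    },
    "classify": {
        "n_runs": 100,
        "n_folds": 10,
        "inner_folds": 5,
        "C_grid": [0.1, 1.0, 10.0, 100.0],
        "gamma_grid": [0.001, 0.01, 0.1, 1.0],
    },
    "report": {
        "posthoc": "tukey",
    },
}

_REQUIRED_KEYS = {
    "seed": None,
    "simulate": ["n_normal", "n_cancer", "days", "pixel_size"],
    "segment": ["background_quantile", "k_sigma"],
    "features": ["core_fraction"],
    "classify": ["n_runs", "n_folds", "inner_folds", "C_grid", "gamma_grid"],
    "report": ["posthoc"],
}


def validate_config(config: dict) -> dict:
    """Validate a full pipeline configuration, naming any missing key."""
    for section, keys in _REQUIRED_KEYS.items():
        if section not in config:
            raise ConfigurationError(f"config missing required key: {section!r}")
        if keys is None:
            continue
        for key in keys:
            if key not in config[section]:
                raise ConfigurationError(
                    f"config missing required key: {section!r}.{key!r}"
                )
    if not config["simulate"]["days"]:
        raise ConfigurationError("simulate.days must be non-empty")
    return config


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, fill unspecified values from defaults, validate."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError("config root must be a mapping")
        for section, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(section), dict):
                config[section].update(value)
            else:
                config[section] = value
    return validate_config(config)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration, for run logs."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def setup_logging(out_dir: str | Path | None = None,
                  verbose: bool = False) -> logging.Logger:
    """Configure the package logger, optionally adding a per-run log file."""
    logger = logging.getLogger("mechspheroid")
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(stream)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    return logger
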