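"""Mechanical features and core/periphery zonal statistics.

The three mechanical descriptors of a spheroid are the mean, the SD and
the skewness of the Brillouin shifts of all pixels inside its mask.  All
three use the biased (population, divisor N) moment convention:

    S_k = m3 / m2^(3/2),   m_i = (1/N) * sum((x - mean)^i)

so the SD is consistent with the skewness denominator.  Negative skewness
marks a left (low-stiffness) tail.

The zonal decomposition splits the mask into a core — pixels within 40%
of the spheroid's radius from its center — and a periphery (the rest).
For irregular shapes "radius" is the equivalent-circle radius
sqrt(area/pi) and distances are Euclidean from the binary centroid;
pixels exactly on the boundary belong to the core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import (BrillouinMap, DegenerateZoneError, MechSpheroidError,
                 UndefinedStatisticError)
from .segment import SpheroidMask, morphological_features, segment_spheroid

DEFAULT_CORE_FRACTION = 0.4


def skewness(values) -> float:
    """Biased-moment sample skewness m3 / m2^(3/2).

    Requires n >= 3 and a non-constant sample; invariant under positive
    affine maps, sign-flipped by negative scaling.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise UndefinedStatisticError("skewness requires at least 3 values")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("skewness undefined for constant sample")
    return float(stats.skew(x, bias=True))


@dataclass(frozen=True)
class MechanicalFeatures:
    """Mean (GHz), population SD (GHz) and skewness of masked shifts."""
    mean_shift: float
    sd_shift: float
    skewness: float

    def __post_init__(self):
        if self.sd_shift < 0:
            raise MechSpheroidError("sd_shift must be >= 0")
        for v in (self.mean_shift, self.sd_shift, self.skewness):
            if not np.isfinite(v):
                raise MechSpheroidError("mechanical features must be finite")


def mechanical_features(brillouin_map: BrillouinMap, mask) -> MechanicalFeatures:
    """Mean, population SD and skewness over masked pixels only."""
    m = mask.mask if isinstance(mask, SpheroidMask) else np.asarray(mask, bool)
    if m.shape != brillouin_map.shifts.shape:
        raise MechSpheroidError("mask shape does not match map")
    values = brillouin_map.shifts[m]
    if values.size < 2:
        raise MechSpheroidError("mask must cover at least 2 pixels")
    if np.ptp(values) == 0:
        raise UndefinedStatisticError(
            "skewness undefined for constant region")
    return MechanicalFeatures(
        mean_shift=float(values.mean()),
        sd_shift=float(values.std()),          # population convention
        skewness=float(stats.skew(values, bias=True)),
    )


def zonal_split(mask: SpheroidMask,
                core_fraction: float = DEFAULT_CORE_FRACTION
                ) -> tuple[np.ndarray, np.ndarray]:
    """Partition a mask into core and periphery boolean arrays.

    Core: Euclidean distance from the centroid <= core_fraction times the
    equivalent radius (<= on the exact boundary).  The two zones partition
    the mask exactly.
    """
    if not 0 < core_fraction < 1:
        raise MechSpheroidError("core_fraction must be in (0, 1)")
    rows, cols = np.indices(mask.mask.shape)
    dist_px = np.hypot(rows - mask.centroid[0], cols - mask.centroid[1])
    core_radius_px = core_fraction * mask.equivalent_radius / mask.pixel_size
    core = mask.mask & (dist_px <= core_radius_px)
    periphery = mask.mask & ~core
    if not core.any():
        raise DegenerateZoneError("core zone is empty (mask too small)")
    return core, periphery


@dataclass(frozen=True)
class ZonalStats:
    """Per-zone mechanical features of a spheroid."""
    core: MechanicalFeatures
    periphery: MechanicalFeatures
    core_fraction: float


def zonal_stats(brillouin_map: BrillouinMap, mask: SpheroidMask,
                core_fraction: float = DEFAULT_CORE_FRACTION) -> ZonalStats:
    """Mechanical features computed separately for core and periphery."""
    core, periphery = zonal_split(mask, core_fraction)
    if not periphery.any():
        raise DegenerateZoneError("periphery zone is empty")
    return ZonalStats(
        core=mechanical_features(brillouin_map, core),
        periphery=mechanical_features(brillouin_map, periphery),
        core_fraction=core_fraction,
    )


# ---------------------------------------------------------------------------
# Batch feature extraction
# ---------------------------------------------------------------------------

FEATURE_COLUMNS_MORPH = ["area", "circularity", "solidity", "aspect_ratio",
                         "cv_hull_radii"]
FEATURE_COLUMNS_MECH = ["mean_shift", "sd_shift", "skewness"]
FEATURE_COLUMNS_ZONAL = ["core_mean", "core_sd", "core_skew",
                         "peri_mean", "peri_sd", "peri_skew"]


def extract_features(maps_with_meta,
                     background_quantile: float = 0.25,
                     k_sigma: float = 3.0,
                     core_fraction: float = DEFAULT_CORE_FRACTION
                     ) -> pd.DataFrame:
    """Segment each map and extract all morphological, mechanical and
    zonal features into a tidy table (one row per spheroid).

    ``maps_with_meta`` yields ``(spheroid_id, line, day, BrillouinMap)``
    tuples or objects with those attributes plus ``.map`` (as produced by
    the simulator's cohorts).
    """
    rows = []
    for item in maps_with_meta:
        if hasattr(item, "map"):
            sid, line, day, bmap = item.spheroid_id, item.line, item.day, item.map
        else:
            sid, line, day, bmap = item
        mask = segment_spheroid(bmap, background_quantile, k_sigma)
        morph = morphological_features(mask)
        mech = mechanical_features(bmap, mask)
        zonal = zonal_stats(bmap, mask, core_fraction)
        rows.append({
            "spheroid_id": sid, "line": line, "day": day,
            "area": morph.area, "circularity": morph.circularity,
            "solidity": morph.solidity, "aspect_ratio": morph.aspect_ratio,
            "cv_hull_radii": morph.cv_hull_radii,
            "mean_shift": mech.mean_shift, "sd_shift": mech.sd_shift,
            "skewness": mech.skewness,
            "core_mean": zonal.core.mean_shift,
            "core_sd": zonal.core.sd_shift,
            "core_skew": zonal.core.skewness,
            "peri_mean": zonal.periphery.mean_shift,
            "peri_sd": zonal.periphery.sd_shift,
            "peri_skew": zonal.periphery.skewness,
        })
    return pd.DataFrame(rows)
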