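"""Synthetic Brillouin-shift maps of spheroid cross-sections.

The forward physics is the Brillouin scattering relation

    omega_B = (2 n / lambda) * sqrt(M' / rho) * sin(theta / 2)

linking the measured frequency shift (GHz) to the elastic longitudinal
modulus M' through the refractive index n, mass density rho, incident
wavelength lambda, and scattering angle theta (180 degrees for a confocal
instrument).

The generator emulates the group-, day- and zone-level structure reported
for MCF10-series spheroids imaged over eight days of 3D culture:

* normal (MCF10A / M1) spheroids stiffen monotonically Day 2 -> 8, while
  cancerous (MCF10CA1h / M3) spheroids stiffen to Day 5 and soften by
  Day 8, staying below the normal line throughout;
* the core (inner 40% of the radius) is stiffer than the periphery;
* mechanical heterogeneity (SD of shift) and the negative left tail of the
  shift histogram are concentrated in the periphery;
* cancerous spheroids grow invasive peripheral protrusions by Day 8.

Absolute shift levels are NOT published for these spheroids; the default
levels here are invented, water-adjacent values (background 5.00 GHz, zone
means 5.18-5.36 GHz) and are fully configurable.  Every map comes with its
ground-truth foreground and core masks.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (BrillouinMap, ConfigurationError, SizingError,
                 write_manifest, write_map)

GHZ = 1e9

#: Maximum |skewness| representable by the skew-normal family (alpha -> inf).
_SKEWNORM_MAX_ABS_SKEW = 0.9952


# ---------------------------------------------------------------------------
# Forward physics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcousticMaterial:
    """Acoustic description of a material probed by Brillouin scattering.

    Attributes
    ----------
    longitudinal_modulus
        Elastic longitudinal modulus M' in Pa (uniaxial stress over
        uniaxial strain under confined compression).
    refractive_index
        Refractive index n (dimensionless, >= 1).
    mass_density
        Mass density rho in kg/m^3.
    """

    longitudinal_modulus: float
    refractive_index: float
    mass_density: float

    def __post_init__(self):
        if not self.longitudinal_modulus > 0:
            raise ValueError("longitudinal_modulus must be positive")
        if not self.refractive_index >= 1:
            raise ValueError("refractive_index must be >= 1")
        if not self.mass_density > 0:
            raise ValueError("mass_density must be positive")


@dataclass(frozen=True)
class OpticsConfig:
    """Illumination geometry: wavelength (m) and scattering angle (deg)."""

    wavelength: float = 660e-9
    scattering_angle: float = 180.0

    def __post_init__(self):
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.scattering_angle <= 180:
            raise ValueError("scattering_angle must be in (0, 180] degrees")


def brillouin_shift_from_modulus(material: AcousticMaterial,
                                 optics: OpticsConfig = OpticsConfig()
                                 ) -> float:
    """Brillouin frequency shift (GHz) of a material.

    omega_B = (2 n / lambda) * sqrt(M'/rho) * sin(theta/2); strictly
    increasing in modulus and refractive index, decreasing in wavelength
    and density.
    """
    theta = math.radians(optics.scattering_angle)
    shift_hz = (
        2.0 * material.refractive_index / optics.wavelength
        * math.sqrt(material.longitudinal_modulus / material.mass_density)
        * math.sin(theta / 2.0)
    )
    return shift_hz / GHZ


def modulus_from_shift(shift_ghz: float,
                       refractive_index: float,
                       mass_density: float,
                       optics: OpticsConfig = OpticsConfig()) -> float:
    """Longitudinal modulus (Pa) from a Brillouin shift (GHz).

    Exact algebraic inverse of :func:`brillouin_shift_from_modulus`.
    """
    if not shift_ghz > 0:
        raise ValueError("shift must be positive")
    if not refractive_index >= 1:
        raise ValueError("refractive_index must be >= 1")
    if not mass_density > 0:
        raise ValueError("mass_density must be positive")
    theta = math.radians(optics.scattering_angle)
    denom = 2.0 * refractive_index * math.sin(theta / 2.0)
    if denom <= 0:
        raise ValueError("scattering geometry gives zero shift; not invertible")
    speed = shift_ghz * GHZ * optics.wavelength / denom
    return mass_density * speed * speed


# ---------------------------------------------------------------------------
# Phenotype parameterisation
# ---------------------------------------------------------------------------

LINES = ("normal", "cancer")
DAYS = (2, 5, 8)


@dataclass(frozen=True)
class PhenotypeParams:
    """Generative parameters for one (cell line, day) condition.

    Shift statistics are in GHz, lengths in micrometres.  The three
    ``*_jitter`` fields control between-spheroid variability: without them
    every spheroid of a condition would differ only by pixel-sampling
    noise.  ``mean_jitter_sd`` shifts both zone means of a spheroid by a
    common normal offset; ``sd_scale_jitter`` multiplies both zone SDs by
    a common log-normal factor; ``skew_jitter_sd`` perturbs the target
    periphery skewness (clipped to the representable skew-normal range).
    """

    cell_line: str
    day: int
    core_mean_shift: float
    periphery_mean_shift: float
    core_sd: float
    periphery_sd: float
    periphery_skew: float
    radius_mean: float
    radius_sd: float
    boundary_roughness: float = 0.0
    protrusion_count: int = 0
    protrusion_length: float = 0.0
    background_mean_shift: float = 5.00
    background_sd: float = 0.015
    mean_jitter_sd: float = 0.03
    sd_scale_jitter: float = 0.10
    skew_jitter_sd: float = 0.10

    def __post_init__(self):
        if self.cell_line not in LINES:
            raise ValueError(f"cell_line must be one of {LINES}")
        if self.core_mean_shift < self.periphery_mean_shift:
            raise ValueError("core_mean_shift must be >= periphery_mean_shift")
        if self.periphery_sd < self.core_sd:
            raise ValueError("periphery_sd must be >= core_sd")
        if self.periphery_skew > 0:
            raise ValueError("periphery_skew must be <= 0")
        if abs(self.periphery_skew) >= _SKEWNORM_MAX_ABS_SKEW:
            raise ValueError(
                f"|periphery_skew| must be < {_SKEWNORM_MAX_ABS_SKEW} "
                "(skew-normal representable range)")
        for name in ("core_mean_shift", "periphery_mean_shift", "core_sd",
                     "periphery_sd", "radius_mean", "background_mean_shift",
                     "background_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.radius_sd < 0:
            raise ValueError("radius_sd must be non-negative")
        if self.protrusion_count < 0 or self.protrusion_length < 0:
            raise ValueError("protrusion parameters must be non-negative")


def default_phenotype_table() -> dict[tuple[str, int], PhenotypeParams]:
    """Default generative parameters for all six (line, day) conditions.

    Shift levels are invented (only relative structure is published);
    radius distributions are identical between lines so that projection
    area alone is weakly discriminative, and cancer Day 8 carries two
    peripheral protrusions.
    """
    rows = {
        # line,   day: core_mu, peri_mu, core_sd, peri_sd, skew, r_mu, r_sd, rough, n_prot, l_prot
        ("normal", 2): (5.26, 5.21, 0.030, 0.060, -0.65, 16.0, 3.0, 0.050, 0, 0.0),
        ("normal", 5): (5.31, 5.25, 0.035, 0.075, -0.85, 30.0, 5.0, 0.040, 0, 0.0),
        ("normal", 8): (5.36, 5.30, 0.040, 0.090, -0.80, 44.0, 7.0, 0.040, 0, 0.0),
        ("cancer", 2): (5.22, 5.18, 0.030, 0.055, -0.35, 16.0, 3.0, 0.060, 0, 0.0),
        ("cancer", 5): (5.275, 5.225, 0.035, 0.070, -0.50, 30.0, 5.0, 0.060, 0, 0.0),
        ("cancer", 8): (5.24, 5.19, 0.040, 0.065, -0.55, 44.0, 7.0, 0.045, 2, 3.0),
    }
    table = {}
    for (line, day), vals in rows.items():
        (core_mu, peri_mu, core_sd, peri_sd, skew,
         r_mu, r_sd, rough, n_prot, l_prot) = vals
        table[(line, day)] = PhenotypeParams(
            cell_line=line, day=day,
            core_mean_shift=core_mu, periphery_mean_shift=peri_mu,
            core_sd=core_sd, periphery_sd=peri_sd, periphery_skew=skew,
            radius_mean=r_mu, radius_sd=r_sd, boundary_roughness=rough,
            protrusion_count=n_prot, protrusion_length=l_prot,
        )
    return table


@dataclass(frozen=True)
class CohortSpec:
    """Size and sampling grid of a simulated cohort.

    Default cohort sizes follow the published study (83 normal, 85
    cancerous spheroids); the default 1 um pixel sits inside the
    instrument's 0.5-2 um scan-step range.  ``image_extent`` of ``None``
    sizes each image automatically from its phenotype's geometry.
    """

    n_normal: int = 83
    n_cancer: int = 85
    days: tuple[int, ...] = DAYS
    pixel_size: float = 1.0
    image_extent: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_normal < 1 or self.n_cancer < 1:
            raise ValueError("cohort counts must be >= 1")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not 0.1 <= self.pixel_size <= 4.0:
            raise ValueError("pixel_size far outside plausible scan steps")
        object.__setattr__(self, "days", tuple(self.days))


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

def skewnorm_from_moments(mean: float, sd: float, skew: float):
    """Skew-normal (a, loc, scale) whose first three moments match.

    Solves the standard moment-matching equations; ``skew=0`` degrades to
    a plain normal.  |skew| must be below the family's representable
    maximum (~0.9952).
    """
    if abs(skew) >= _SKEWNORM_MAX_ABS_SKEW:
        raise ValueError("|skew| outside skew-normal representable range")
    if not sd > 0:
        raise ValueError("sd must be positive")
    if skew == 0.0:
        return 0.0, mean, sd
    b = math.sqrt(2.0 / math.pi)
    g = abs(skew) ** (2.0 / 3.0)
    delta_sq = (math.pi / 2.0) * g / (g + ((4.0 - math.pi) / 2.0) ** (2.0 / 3.0))
    delta = math.copysign(math.sqrt(delta_sq), skew)
    alpha = delta / math.sqrt(1.0 - delta_sq)
    scale = sd / math.sqrt(1.0 - b * b * delta_sq)
    loc = mean - scale * delta * b
    return alpha, loc, scale


def _sample_zone(rng: np.random.Generator, n: int,
                 mean: float, sd: float, skew: float) -> np.ndarray:
    alpha, loc, scale = skewnorm_from_moments(mean, sd, skew)
    if alpha == 0.0:
        return rng.normal(loc, scale, size=n)
    return stats.skewnorm.rvs(alpha, loc=loc, scale=scale,
                              size=n, random_state=rng)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


# ---------------------------------------------------------------------------
# Spheroid map generation
# ---------------------------------------------------------------------------

def required_extent(params: PhenotypeParams, pixel_size: float,
                    margin_um: float = 6.0) -> int:
    """Smallest even image extent (pixels) that safely contains the shape."""
    reach = (params.radius_mean + 3.0 * params.radius_sd
             + params.protrusion_length + margin_um)
    extent = int(math.ceil(2.0 * reach / pixel_size))
    return extent + extent % 2


def generate_spheroid_map(params: PhenotypeParams, pixel_size: float = 1.0,
                          extent: int | None = None, seed: int = 0
                          ) -> tuple[BrillouinMap, np.ndarray, np.ndarray]:
    """Render one synthetic spheroid cross-section.

    Returns ``(map, foreground_mask, core_mask)`` where the masks are the
    generator's ground truth.  The spheroid is a disk whose boundary is
    perturbed by low-order Fourier modes (relative amplitude set by
    ``boundary_roughness``) plus optional radial Gaussian protrusions;
    core pixels carry symmetric noise, periphery pixels left-skewed
    skew-normal noise, blended smoothly over a ~3 px annulus at 40% of the
    equivalent radius.  Identical ``(params, seed)`` gives bit-identical
    output.
    """
    if extent is None:
        extent = required_extent(params, pixel_size)
    min_extent = required_extent(params, pixel_size, margin_um=2.0)
    if extent < min_extent:
        raise SizingError(
            f"extent {extent} px cannot contain radius_mean + 3*radius_sd "
            f"+ protrusion_length (need >= {min_extent} px)")

    rng = np.random.default_rng(seed)

    # --- per-spheroid draws -------------------------------------------------
    radius = max(6.0, rng.normal(params.radius_mean, params.radius_sd))  # um
    mean_offset = rng.normal(0.0, params.mean_jitter_sd) \
        if params.mean_jitter_sd > 0 else 0.0
    sd_factor = math.exp(rng.normal(0.0, params.sd_scale_jitter)) \
        if params.sd_scale_jitter > 0 else 1.0
    skew_target = params.periphery_skew
    if params.skew_jitter_sd > 0:
        skew_target += rng.normal(0.0, params.skew_jitter_sd)
    skew_target = float(np.clip(skew_target, -0.95, 0.0))

    center = extent / 2.0 - 0.5 + rng.uniform(-1.5, 1.5, size=2)  # px

    n_modes = 5
    mode_orders = np.arange(2, 2 + n_modes)
    amplitudes = rng.normal(0.0, params.boundary_roughness / math.sqrt(n_modes),
                            size=n_modes)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=n_modes)

    prot_angles = rng.uniform(0.0, 2.0 * math.pi, size=params.protrusion_count)
    prot_lengths = params.protrusion_length * rng.uniform(
        0.75, 1.25, size=params.protrusion_count)

    # --- geometry ------------------------------------------------------------
    rows, cols = np.mgrid[0:extent, 0:extent].astype(np.float64)
    dy = (rows - center[0]) * pixel_size
    dx = (cols - center[1]) * pixel_size
    rho = np.hypot(dy, dx)                      # um
    phi = np.arctan2(dy, dx)

    boundary = np.full_like(phi, radius)
    for k, amp, ph in zip(mode_orders, amplitudes, phases):
        boundary += radius * amp * np.cos(k * phi + ph)
    for ang, length in zip(prot_angles, prot_lengths):
        dphi = np.angle(np.exp(1j * (phi - ang)))
        sigma_phi = 4.0 / radius            # ~4 um lateral width at the rim
        boundary += length * np.exp(-0.5 * (dphi / sigma_phi) ** 2)

    mask = rho <= boundary
    if not mask.any():
        raise SizingError("generated spheroid has empty foreground")

    # --- zone fields ---------------------------------------------------------
    area_px = int(mask.sum())
    r_equiv_px = math.sqrt(area_px / math.pi)
    centroid = np.array(np.nonzero(mask), dtype=float).mean(axis=1)
    dist_px = np.hypot(rows - centroid[0], cols - centroid[1])
    core_mask = mask & (dist_px <= 0.4 * r_equiv_px)

    shifts = rng.normal(params.background_mean_shift, params.background_sd,
                        size=(extent, extent))
    n_fg = area_px
    core_vals = _sample_zone(rng, n_fg, params.core_mean_shift + mean_offset,
                             params.core_sd * sd_factor, 0.0)
    peri_vals = _sample_zone(rng, n_fg,
                             params.periphery_mean_shift + mean_offset,
                             params.periphery_sd * sd_factor, skew_target)
    blend_px = 3.0
    w = _smoothstep((dist_px[mask] - (0.4 * r_equiv_px - blend_px / 2.0))
                    / blend_px)
    shifts[mask] = (1.0 - w) * core_vals + w * peri_vals

    brillouin_map = BrillouinMap(
        shifts.astype(np.float32).astype(np.float64), pixel_size,
        metadata={"cell_line": params.cell_line, "day": params.day,
                  "seed": int(seed)},
    )
    return brillouin_map, mask, core_mask


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def spheroid_seed(base_seed: int, line: str, day: int, index: int) -> int:
    """Deterministic per-spheroid seed from a stable string hash."""
    tag = f"{line}:{day}:{index}".encode()
    return int((base_seed + zlib.crc32(tag)) % (2 ** 31))


@dataclass
class SimulatedSpheroid:
    """One simulated spheroid with its ground truth."""
    spheroid_id: str
    line: str
    day: int
    seed: int
    map: BrillouinMap
    mask: np.ndarray
    core_mask: np.ndarray
    file: str = ""


@dataclass
class CohortDataset:
    """A labelled simulated cohort plus its manifest."""
    spheroids: list[SimulatedSpheroid]
    manifest: pd.DataFrame
    spec: CohortSpec = field(default=None)

    def __len__(self) -> int:
        return len(self.spheroids)


def generate_cohort(spec: CohortSpec,
                    phenotype_table: dict[tuple[str, int], PhenotypeParams]
                    | None = None,
                    out_dir=None) -> CohortDataset:
    """Generate a labelled cohort of spheroid maps.

    ``n_normal + n_cancer`` maps per day, with per-spheroid seeds derived
    deterministically from ``spec.seed``.  If ``out_dir`` is given, maps
    are written as float32 TIFF and a ``manifest.csv`` is emitted; the
    dataset is returned in memory either way.
    """
    if phenotype_table is None:
        phenotype_table = default_phenotype_table()
    counts = {"normal": spec.n_normal, "cancer": spec.n_cancer}
    for day in spec.days:
        for line in LINES:
            if (line, day) not in phenotype_table:
                raise ConfigurationError(
                    f"phenotype table has no entry for ({line!r}, {day})")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    spheroids: list[SimulatedSpheroid] = []
    rows = []
    for day in spec.days:
        for line in LINES:
            params = phenotype_table[(line, day)]
            extent = spec.image_extent or required_extent(params,
                                                          spec.pixel_size)
            for i in range(counts[line]):
                seed_i = spheroid_seed(spec.seed, line, day, i)
                bmap, mask, core = generate_spheroid_map(
                    params, spec.pixel_size, extent, seed_i)
                sid = f"{line}_d{day}_{i:03d}"
                fname = f"{sid}.tif"
                if out_dir is not None:
                    bmap.metadata["spheroid_id"] = sid
                    write_map(bmap, out_dir / fname)
                spheroids.append(SimulatedSpheroid(
                    sid, line, day, seed_i, bmap, mask, core, fname))
                rows.append({"file": fname, "spheroid_id": sid, "line": line,
                             "day": day, "seed": seed_i})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        write_manifest(manifest, out_dir / "manifest.csv")
    return CohortDataset(spheroids, manifest, spec)
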