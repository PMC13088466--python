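"""Synthetic hyperspectral root scenes with known per-pixel biomass.

The generator emulates imaging of hydroponic root systems from below
through a transparent baseplate, against a blue-painted panel, so the whole
estimation pipeline can be exercised against exact ground truth.

Optical model
-------------
A two-term Beer-Lambert mixture.  For dry-mass areal density ``d`` (mg per
pixel) the noiseless reflectance at wavelength ``lambda`` is

    R(lambda, d) = bg(lambda) * exp(-2 * mu_a(lambda) * d)
                 + root(lambda) * (1 - exp(-mu_s(lambda) * d))

The first term is light crossing the root layer twice and reflecting off
the blue panel (hence the factor 2 in the path length); the second is
diffuse build-up of light scattered back by root tissue.  Coefficients are
smooth sums of Gaussian/sigmoid components chosen so that with increasing
density the blue band (450 nm) darkens toward saturation, the near-infrared
(750 nm) brightens with tissue scattering, and 950 nm dims under the water
absorption band — the three spectral mechanisms the estimation model relies
on.

Scene structure
---------------
Each plant is a seeded branching random walk ("roots grow downstream from
the base at the top of the image") with Gaussian-profile thickness and a
density that tapers away from the base.  Per-pixel affine scatter artifacts
(gain/offset) and relative Gaussian sensor noise are applied, then the
reflectance is re-encoded to digital numbers through synthetic white and
dark reference frames, exactly the signal chain the calibration step inverts.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import InvalidInputError
from .segmentation import SegmentGrid

__all__ = [
    "OpticalModel",
    "RootArchitecture",
    "RawScene",
    "SceneConfig",
    "default_wavelengths",
    "build_optics",
    "grow_architecture",
    "grow_scene",
    "render_scene",
    "reflectance_model",
    "truth_segment_weights",
    "write_scene",
]

MG_PER_G = 1000.0


def default_wavelengths(n_bands: int = 204) -> np.ndarray:
    """Band centres of the emulated sensor: 400-1000 nm in ``n_bands`` steps."""
    return np.linspace(400.0, 1000.0, n_bands)


def _gauss(lam: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-(((lam - centre) / width) ** 2))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class OpticalModel:
    """Smooth per-band optical coefficients of panel and root tissue.

    absorption/scattering coefficients are per (mg / pixel) of root dry
    mass along the optical path.
    """

    wavelengths_nm: np.ndarray
    background_reflectance: np.ndarray
    root_reflectance: np.ndarray
    absorption_coeff: np.ndarray
    scattering_coeff: np.ndarray

    def band_nearest(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))


def build_optics(wavelengths_nm: np.ndarray) -> OpticalModel:
    """Construct the default optical model on the given band grid.

    The blue panel peaks at 450 nm with a broad NIR shoulder (blue paints
    reflect strongly in the NIR); root tissue is dark in the blue, rises
    across the red edge to a NIR plateau and dips at the 970 nm water band;
    absorption is strongest in the blue with a water bump near 965 nm;
    scattering decreases monotonically with wavelength.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    if lam.ndim != 1 or lam.size < 2 or not np.all(np.diff(lam) > 0):
        raise InvalidInputError("wavelengths must be a strictly increasing vector")
    if lam.min() < 400.0 - 1e-9 or lam.max() > 1000.0 + 1e-9:
        raise InvalidInputError("wavelengths must lie within 400-1000 nm")
    background = 0.10 + 0.45 * _gauss(lam, 450.0, 34.0) + 0.38 * _sigmoid((lam - 800.0) / 40.0)
    root = 0.05 + 0.42 * _sigmoid((lam - 720.0) / 30.0) - 0.16 * _gauss(lam, 965.0, 40.0)
    absorption = 1.5 + 43.5 * _gauss(lam, 440.0, 110.0) + 2.5 * _gauss(lam, 965.0, 45.0)
    scattering = 2.5 + 90.0 * _gauss(lam, 440.0, 95.0)
    return OpticalModel(
        wavelengths_nm=lam,
        background_reflectance=background,
        root_reflectance=root,
        absorption_coeff=absorption,
        scattering_coeff=scattering,
    )


@dataclass
class SceneConfig:
    """Study conditions of the emulated acquisition.

    Defaults reproduce the imaging geometry of the greenhouse system: a
    25 x 25 cm field of view at 512 x 512 pixels, 204 bands over
    400-1000 nm, five plants side by side (one per 5 cm column), 5%/0.01
    affine scatter artifacts and 1% relative sensor noise.  ``mass_scale``
    (mg/pixel deposited per skeleton step at maturity) is set so segment
    dry weights span roughly 0-0.3 g/segment; ``mass_cv`` is the
    plant-to-plant log-normal variation of tissue density (root systems of
    equal extent differ in thickness), which decouples dry weight from
    root coverage the way real stands do.
    """

    image_size_px: tuple[int, int] = (512, 512)
    field_cm: tuple[float, float] = (25.0, 25.0)
    n_bands: int = 204
    n_plants: int = 5
    noise_sd: float = 0.01
    scatter_gain_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    mass_scale: float = 0.024
    mass_cv: float = 0.3
    seed: int = 0

    @property
    def pixel_size_cm(self) -> float:
        return self.field_cm[0] / self.image_size_px[0]

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return default_wavelengths(self.n_bands)

    def __post_init__(self) -> None:
        if min(self.image_size_px) < 8 or min(self.field_cm) <= 0:
            raise InvalidInputError("image/field geometry must be positive")
        for name in ("noise_sd", "scatter_gain_sd", "scatter_offset_sd", "mass_scale", "mass_cv"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.n_plants < 1:
            raise InvalidInputError("n_plants must be >= 1")


@dataclass
class RootArchitecture:
    """Skeleton paths and per-pixel dry-mass density of one plant."""

    density_map: np.ndarray  # H x W, mg/pixel
    skeleton: list  # list of (n, 2) float arrays of (row, col)
    base_position: tuple[int, int]
    stage: float

    @property
    def total_mass_mg(self) -> float:
        return float(self.density_map.sum())


@dataclass
class RawScene:
    """Digital-number cube plus reference frames and exact ground truth."""

    dn_cube: np.ndarray  # H x W x B
    white_frame: np.ndarray  # B
    dark_frame: np.ndarray  # B
    truth_density: np.ndarray  # H x W mg/pixel
    truth_mask: np.ndarray  # H x W bool
    optics: OpticalModel
    seed: int
    pixel_size_cm: float = 25.0 / 512.0
    plant_labels: np.ndarray | None = None  # H x W int, -1 = background


# ---------------------------------------------------------------------------
# root architecture
# ---------------------------------------------------------------------------

N_PRIMARY_AXES = 3
BRANCH_PROBABILITY = 0.03
PRIMARY_SIGMA_PX = 2.8
BRANCH_SIGMA_PX = 1.7
MASS_MULTIPLIER_RANGE = (0.7, 1.6)  # clip for the per-plant density multiplier
TAPER = 0.55  # density at the root tip relative to the base: 1 - TAPER
BASE_BLOB_GAIN = 1.5
# Gaussian cross-sections have faint tails.  Pixels below this fraction of
# mass_scale would be optically indistinguishable from bare panel (their
# blue-band attenuation is inside the noise/scatter spread), i.e. below the
# detection limit of the emulated system; they are floored to zero so the
# truth mask has crisp support a thresholding segmenter can recover.  The
# floor is pixelwise and pixel density is non-decreasing in stage, so
# flooring preserves mass monotonicity in stage.
DENSITY_FLOOR_FRACTION = 0.3


def _logistic_stage(stage: float) -> float:
    # gentle logistic: young roots are thinner but still optically dense,
    # so per-pixel density rises ~1.5x from establishment to maturity
    return 1.0 / (1.0 + math.exp(-3.0 * (stage - 0.2)))


def _deposit(density: np.ndarray, r: float, c: float, amp: float, sigma: float) -> None:
    h, w = density.shape
    rad = int(math.ceil(3 * sigma))
    r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - r
    cc = np.arange(c0, c1)[None, :] - c
    density[r0:r1, c0:c1] += amp * np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))


def _walk(rng, start, heading, length, wiggle, drift, row_range, col_range):
    """One random-walk path of unit steps; heading 0 points down-image.

    The heading wiggles but mean-reverts to its initial direction, so long
    paths stay roughly straight (roots keep their growth direction) while
    curving locally.
    """
    pts = np.empty((length, 2))
    r, c = start
    theta = heading
    for i in range(length):
        theta += drift + rng.normal(0.0, wiggle) + 0.04 * (heading - theta)
        r += math.cos(theta)
        c += math.sin(theta)
        r = min(max(r, row_range[0]), row_range[1])
        c = min(max(c, col_range[0]), col_range[1])
        pts[i] = (r, c)
    return pts


def grow_architecture(
    config: SceneConfig,
    stage: float,
    seed: int,
    base_position: tuple[int, int] | None = None,
    column_bounds: tuple[int, int] | None = None,
    mode: str = "linear",
    mass_multiplier: float = 1.0,
) -> RootArchitecture:
    """Grow one plant's root system to ``stage`` in [0, 1].

    ``mode="linear"`` emulates roots guided downstream by partition boards:
    primary axes head down-image from a base on the top edge.  ``mode=
    "radial"`` emulates natural development: axes radiate in all directions
    from a base at the plant centre.

    The full-length skeleton is generated deterministically from ``seed``
    and then truncated to a stage-dependent fraction, so the architectures
    at two stages of the same seed are nested and total mass is
    non-decreasing in stage.  Density along each path is a Gaussian
    cross-section whose amplitude tapers away from the base and scales with
    ``mass_scale * logistic(stage)``.
    """
    if not 0.0 <= stage <= 1.0:
        raise InvalidInputError(f"stage must be in [0, 1], got {stage}")
    if mode not in ("linear", "radial"):
        raise InvalidInputError(f"mode must be 'linear' or 'radial', got {mode!r}")
    h, w = config.image_size_px
    if base_position is None:
        base_position = (0, w // 2) if mode == "linear" else (h // 2, w // 2)
    if column_bounds is None:
        column_bounds = (0, w)
    density = np.zeros((h, w), dtype=np.float64)
    if stage == 0.0:
        return RootArchitecture(density, [], base_position, stage)

    rng = substream(seed, "architecture")
    base_r, base_c = base_position
    lo_c, hi_c = column_bounds
    row_range = (1.0, h - 2.0)
    col_range = (lo_c + 1.0, hi_c - 2.0)
    amp = config.mass_scale * mass_multiplier * _logistic_stage(stage)
    if mode == "linear":
        max_len = h - base_r - 1
    else:
        max_len = (min(h, hi_c - lo_c) - 2) // 2

    # full-length paths first (seed-stable), then truncate by stage
    paths: list[tuple[np.ndarray, float]] = []  # (points, relative amplitude)
    for axis in range(N_PRIMARY_AXES):
        length = int(round(max_len * rng.uniform(0.70, 0.95)))
        if mode == "linear":
            heading = rng.uniform(-0.25, 0.25)  # near straight down
        else:
            heading = rng.uniform(0.0, 2.0 * math.pi)
        drift = rng.uniform(-0.01, 0.01)
        pts = _walk(rng, (float(base_r), float(base_c)), heading, length, 0.12, drift,
                    row_range, col_range)
        for i in range(length):
            if rng.random() < BRANCH_PROBABILITY:
                blen = int((length - i) * rng.uniform(0.3, 0.8))
                if blen > 2:
                    bheading = heading + rng.uniform(-0.7, 0.7)
                    bpts = _walk(rng, tuple(pts[i]), bheading, blen, 0.12,
                                 rng.uniform(-0.02, 0.02), row_range, col_range)
                    paths.append((bpts, 0.4))
        paths.append((pts, 1.0))

    kept: list[np.ndarray] = []
    for pts, rel in paths:
        n_keep = int(math.ceil(len(pts) * stage))
        if n_keep == 0:
            continue
        sub = pts[:n_keep]
        kept.append(sub)
        sigma = PRIMARY_SIGMA_PX if rel == 1.0 else BRANCH_SIGMA_PX
        # taper with arc length from the base along the full-length path
        arc_frac = np.arange(1, n_keep + 1) / max(len(pts), 1)
        amps = amp * rel * (1.0 - TAPER * arc_frac)
        for (r, c), a in zip(sub, amps):
            _deposit(density, r, c, a, sigma)
    _deposit(density, base_r + 1.0 if mode == "linear" else base_r, base_c,
             BASE_BLOB_GAIN * amp, 3.0)
    density[density < DENSITY_FLOOR_FRACTION * config.mass_scale] = 0.0
    return RootArchitecture(density, kept, base_position, stage)


def grow_scene(
    config: SceneConfig,
    stages,
    seed: int,
    mode: str = "linear",
) -> tuple[RootArchitecture, np.ndarray]:
    """Grow ``config.n_plants`` plants side by side (one per column strip).

    ``stages`` is a scalar or a per-plant sequence; ``mode`` as in
    :func:`grow_architecture` (linear plants base on the top edge, radial
    plants base at the strip centre).  Returns the combined architecture
    (densities summed, all skeletons) and an H x W integer label map
    assigning each pixel to the plant strip containing it.
    """
    h, w = config.image_size_px
    stages = np.broadcast_to(np.asarray(stages, dtype=float), (config.n_plants,))
    strip = w / config.n_plants
    density = np.zeros((h, w))
    skeleton: list[np.ndarray] = []
    labels = np.empty((h, w), dtype=np.int32)
    for p in range(config.n_plants):
        lo = int(round(p * strip))
        hi = int(round((p + 1) * strip))
        labels[:, lo:hi] = p
        base = (0, (lo + hi) // 2) if mode == "linear" else (h // 2, (lo + hi) // 2)
        # per-plant tissue-density multiplier, deterministic in (seed, plant)
        if config.mass_cv > 0:
            sd = math.sqrt(math.log(1.0 + config.mass_cv**2))
            mult = float(
                np.clip(
                    np.exp(substream(seed * 1000 + p, "mass").normal(-0.5 * sd**2, sd)),
                    *MASS_MULTIPLIER_RANGE,
                )
            )
        else:
            mult = 1.0
        arch = grow_architecture(
            config,
            float(stages[p]),
            seed=seed * 1000 + p,
            base_position=base,
            column_bounds=(lo, hi),
            mode=mode,
            mass_multiplier=mult,
        )
        density += arch.density_map
        skeleton.extend(arch.skeleton)
    combined = RootArchitecture(density, skeleton, (0, w // 2), float(stages.max()))
    return combined, labels


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def reflectance_model(optics: OpticalModel, density: np.ndarray) -> np.ndarray:
    """Noiseless reflectance cube for a density map (closed form)."""
    d = np.asarray(density, dtype=np.float32)[..., None]
    bg = optics.background_reflectance.astype(np.float32)
    rt = optics.root_reflectance.astype(np.float32)
    mu_a = optics.absorption_coeff.astype(np.float32)
    mu_s = optics.scattering_coeff.astype(np.float32)
    return bg * np.exp(-2.0 * mu_a * d) + rt * (1.0 - np.exp(-mu_s * d))


def _white_dark_frames(wavelengths_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # halogen lamps: radiance rising with wavelength over 400-1000 nm
    lam = np.asarray(wavelengths_nm, dtype=float)
    white = 1000.0 + 2800.0 * (lam - 400.0) / 600.0
    dark = np.full_like(lam, 96.0)
    return white, dark


def render_scene(
    architecture: RootArchitecture,
    optics: OpticalModel,
    config: SceneConfig,
    seed: int,
    plant_labels: np.ndarray | None = None,
) -> RawScene:
    """Render a raw digital-number scene from an architecture.

    Signal chain: closed-form reflectance -> per-pixel affine scatter
    artifact (gain ~ N(1, scatter_gain_sd), offset ~ N(0, scatter_offset_sd))
    -> relative Gaussian noise -> DN = dark + R * (white - dark).  Scatter
    and noise come from independent sub-streams of ``seed``.
    """
    density = architecture.density_map
    h, w = density.shape
    if (h, w) != tuple(config.image_size_px):
        raise InvalidInputError("architecture and config image sizes differ")
    refl = reflectance_model(optics, density)
    if config.scatter_gain_sd > 0 or config.scatter_offset_sd > 0:
        rng = substream(seed, "scatter")
        gain = 1.0 + config.scatter_gain_sd * rng.standard_normal((h, w), dtype=np.float32)
        offset = config.scatter_offset_sd * rng.standard_normal((h, w), dtype=np.float32)
        refl = refl * gain[..., None] + offset[..., None]
    if config.noise_sd > 0:
        rng = substream(seed, "noise")
        noise = rng.standard_normal(refl.shape, dtype=np.float32)
        noise *= config.noise_sd
        noise += 1.0
        refl = refl * noise
    white, dark = _white_dark_frames(optics.wavelengths_nm)
    dn = dark.astype(np.float32) + refl * (white - dark).astype(np.float32)
    np.clip(dn, 0.0, None, out=dn)
    return RawScene(
        dn_cube=dn,
        white_frame=white,
        dark_frame=dark,
        truth_density=density,
        truth_mask=density > 0,
        optics=optics,
        seed=seed,
        pixel_size_cm=config.pixel_size_cm,
        plant_labels=plant_labels,
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def truth_segment_weights(truth_density: np.ndarray, grid: SegmentGrid) -> pd.DataFrame:
    """Exact dry weight (g) of each grid segment: sum(mg/pixel) / 1000.

    Returns a frame with columns grid_row, grid_col, row0, col0,
    dry_weight_g; segment sums over a plant's cells equal the plant total
    over the gridded area by construction.
    """
    d = np.asarray(truth_density, dtype=float)
    rows = []
    for i, j, (r0, c0, r1, c1) in grid.cells():
        if r1 > d.shape[0] or c1 > d.shape[1]:
            raise InvalidInputError("grid extends outside the density map")
        rows.append(
            {
                "grid_row": i,
                "grid_col": j,
                "row0": r0,
                "col0": c0,
                "dry_weight_g": d[r0:r1, c0:c1].sum() / MG_PER_G,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_scene(scene: RawScene, config: SceneConfig, grid: SegmentGrid, out_dir: str) -> None:
    """Write the scene as ENVI cube + truth-weight CSV + JSON config echo."""
    from .cube import SpectralCube, write_cube

    os.makedirs(out_dir, exist_ok=True)
    cube = SpectralCube(
        reflectance=np.clip(scene.dn_cube, 0, None),
        wavelengths_nm=scene.optics.wavelengths_nm,
        pixel_size_cm=scene.pixel_size_cm,
        provenance="raw digital numbers (uncalibrated)",
    )
    write_cube(cube, os.path.join(out_dir, "scene_dn"))
    np.savetxt(
        os.path.join(out_dir, "white_frame.csv"),
        np.column_stack([scene.optics.wavelengths_nm, scene.white_frame, scene.dark_frame]),
        delimiter=",",
        header="wavelength_nm,white_dn,dark_dn",
        comments="",
    )
    weights = truth_segment_weights(scene.truth_density, grid)
    if scene.plant_labels is not None:
        plant = [
            int(np.bincount(scene.plant_labels[r0 : r0 + 1, c0 : c0 + grid.seg_width_px].ravel()).argmax())
            for r0, c0 in zip(weights["row0"], weights["col0"])
        ]
        weights.insert(0, "plant_id", plant)
    weights.rename(columns={"grid_row": "segment_id", "grid_col": "column"}).to_csv(
        os.path.join(out_dir, "truth_segments.csv"), index=False
    )
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
    cfg["scene_seed"] = scene.seed
    with open(os.path.join(out_dir, "scene_config.json"), "w") as f:
        json.dump(cfg, f, indent=2)


def scene_with(config: SceneConfig, **overrides) -> SceneConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
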