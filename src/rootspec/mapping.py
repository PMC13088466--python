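"""Pixel-level biomass mapping, per-plant totals, and growth monitoring.

A segment-level spectral model predicts grams per 5 x 2.5 cm segment from a
segment-mean spectrum.  To map biomass at pixel resolution, each root
pixel's spectrum is treated as if it were a segment-mean spectrum and the
resulting g/segment prediction is divided by the number of pixels in a
segment, giving a per-pixel weight proposal.  Because a single pixel's
spectrum (pure root tissue, un-averaged noise) lies at the edge of the
segment-mean training manifold, these proposals order pixels well but can
be mis-scaled; by default each grid segment's proposals are therefore
rescaled to sum to the model's prediction for that segment's area-mean
spectrum, which is squarely on the training manifold.  For a homogeneous
fully-rooted segment the rescale is the identity, so the map sums to the
segment prediction exactly; pixels outside any complete grid cell keep
their raw proposals.

Per-plant totals are sums of the map over user-supplied plant regions, and
a time series of daily cubes yields the growth trajectory of each plant.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cube import SpectralCube
from .errors import InvalidInputError, SegmentationError
from .pls import PLSRModel, predict
from .segmentation import RootMask, SegmentGrid, root_mask_from_cube

__all__ = [
    "BiomassMap",
    "pixel_biomass_map",
    "plant_total",
    "growth_series",
    "render_false_color",
]


@dataclass
class BiomassMap:
    """Per-pixel predicted dry weight (g/pixel); zero outside the root mask."""

    values: np.ndarray
    total_g: float
    model_id: str = ""
    date_or_dap: int | str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise InvalidInputError("biomass map must be non-negative")


def pixel_biomass_map(
    cube: SpectralCube,
    model: PLSRModel,
    mask: RootMask | np.ndarray,
    grid: SegmentGrid,
    model_id: str = "plsr",
    date_or_dap=None,
    anchor: str = "segment",
    smooth_px: int = 3,
) -> BiomassMap:
    """Predict g/pixel for every root pixel (see module docstring for units).

    ``anchor="segment"`` (default) rescales each grid cell to its
    segment-mean prediction; ``anchor="none"`` keeps the raw per-pixel
    proposals.  ``smooth_px`` spatially averages proposals over root pixels
    in a square window before anchoring, suppressing single-pixel sensor
    noise (0 or 1 disables; the mean over root neighbours of a uniform
    field is the field itself, so homogeneous segments are unaffected).
    """
    if anchor not in ("segment", "none"):
        raise InvalidInputError(f"anchor must be 'segment' or 'none', got {anchor!r}")
    m = mask.mask if isinstance(mask, RootMask) else np.asarray(mask, dtype=bool)
    if m.shape != cube.shape[:2]:
        raise InvalidInputError("mask and cube shapes differ")
    values = np.zeros(m.shape, dtype=float)
    if m.any():
        spectra = cube.reflectance[m].astype(float)
        per_segment = predict(model, spectra)
        values[m] = per_segment / grid.pixels_per_cell
        if smooth_px and smooth_px > 1:
            from scipy.ndimage import uniform_filter

            num = uniform_filter(values, size=smooth_px)
            den = uniform_filter(m.astype(float), size=smooth_px)
            values = np.where(m, num / np.maximum(den, 1e-12), 0.0)
        if anchor == "segment":
            for _, _, (r0, c0, r1, c1) in grid.cells():
                cell_mask = m[r0:r1, c0:c1]
                if not cell_mask.any():
                    continue
                sub = values[r0:r1, c0:c1]
                proposal = float(sub.sum())
                area_mean = cube.reflectance[r0:r1, c0:c1, :].reshape(-1, cube.shape[2]).mean(axis=0)
                w_seg = float(predict(model, area_mean[None, :])[0])
                if proposal > 0:
                    values[r0:r1, c0:c1] = sub * (w_seg / proposal)
                else:  # all proposals zero: distribute uniformly over root pixels
                    sub[cell_mask] = w_seg / int(cell_mask.sum())
                    values[r0:r1, c0:c1] = sub
        np.clip(values, 0.0, None, out=values)  # guard fp round-off from filtering
    return BiomassMap(
        values=values,
        total_g=float(values.sum()),
        model_id=model_id,
        date_or_dap=date_or_dap,
    )


def plant_total(bmap: BiomassMap, plant_region) -> float:
    """Total predicted dry weight (g/plant) inside a region.

    ``plant_region`` is either a boolean mask of the map's shape or a
    rectangle ``(row0, col0, row1, col1)`` (half-open).
    """
    v = bmap.values
    if isinstance(plant_region, (tuple, list)) and len(plant_region) == 4:
        r0, c0, r1, c1 = plant_region
        if not (0 <= r0 < r1 <= v.shape[0] and 0 <= c0 < c1 <= v.shape[1]):
            raise InvalidInputError(f"region {plant_region} outside map {v.shape}")
        return float(v[r0:r1, c0:c1].sum())
    region = np.asarray(plant_region, dtype=bool)
    if region.shape != v.shape:
        raise InvalidInputError("region mask shape differs from map")
    if not region.any():
        raise InvalidInputError("empty plant region")
    return float(v[region].sum())


def growth_series(
    day_cubes,
    model: PLSRModel,
    regions: dict,
    grid: SegmentGrid,
    observed_final: dict | None = None,
) -> pd.DataFrame:
    """Per-plant daily biomass totals from an ordered series of cubes.

    Parameters
    ----------
    day_cubes : sequence of (dap, SpectralCube), strictly increasing dap.
    regions : plant_id -> region (mask or rectangle) passed to plant_total.
    observed_final : optional plant_id -> observed harvest weight (g); when
        given, the relative error |pred - obs| / obs * 100 at the final day
        is added to the last row of each plant.

    Days whose scene contains no detectable roots contribute zero totals.
    Because roots do not retract, the detected root mask is accumulated
    (logical OR) across days: this stabilises cells at the root frontier
    that would otherwise flicker in and out of detection between
    consecutive days.
    """
    day_cubes = list(day_cubes)
    if len(day_cubes) < 2:
        raise InvalidInputError("need at least 2 timepoints")
    daps = [d for d, _ in day_cubes]
    if any(b <= a for a, b in zip(daps, daps[1:])):
        raise InvalidInputError("days must be strictly increasing")
    rows = []
    cumulative: np.ndarray | None = None
    for dap, cube in day_cubes:
        try:
            mask = root_mask_from_cube(cube).mask
        except SegmentationError:
            mask = None
        if mask is not None:
            cumulative = mask if cumulative is None else (cumulative | mask)
        if cumulative is not None:
            bmap = pixel_biomass_map(cube, model, cumulative, grid, date_or_dap=dap)
        else:
            bmap = BiomassMap(np.zeros(cube.shape[:2]), 0.0, date_or_dap=dap)
        for plant_id, region in regions.items():
            rows.append(
                {"plant_id": plant_id, "dap": dap, "total_g": plant_total(bmap, region)}
            )
    frame = pd.DataFrame(rows).sort_values(["plant_id", "dap"]).reset_index(drop=True)
    if observed_final is not None:
        frame["relative_error_pct"] = np.nan
        last_dap = daps[-1]
        for plant_id, obs in observed_final.items():
            if obs <= 0:
                raise InvalidInputError("observed weight must be positive")
            sel = (frame["plant_id"] == plant_id) & (frame["dap"] == last_dap)
            pred = float(frame.loc[sel, "total_g"].iloc[0])
            frame.loc[sel, "relative_error_pct"] = abs(pred - obs) / obs * 100.0
    return frame


def render_false_color(
    bmap: BiomassMap,
    out_path: str,
    colormap: str = "inferno",
    vmin: float = 0.0,
    vmax: float | None = None,
) -> None:
    """Write a deterministic false-color PNG plus a JSON scale sidecar.

    Pass a shared ``vmax`` (e.g. the global maximum of a day series) to keep
    one colour scale across frames.
    """
    import matplotlib

    from PIL import Image

    v = bmap.values
    if vmax is None:
        vmax = float(v.max())
    span = vmax - vmin
    norm = np.zeros_like(v) if span <= 0 else np.clip((v - vmin) / span, 0.0, 1.0)
    cmap = matplotlib.colormaps[colormap]
    rgb = (cmap(norm)[:, :, :3] * 255).astype(np.uint8)
    Image.fromarray(rgb).save(out_path, format="PNG")
    sidecar = {
        "vmin": vmin,
        "vmax": vmax,
        "colormap": colormap,
        "units": "g/pixel",
        "total_g": bmap.total_g,
        "model_id": bmap.model_id,
        "dap": bmap.date_or_dap,
    }
    with open(os.path.splitext(out_path)[0] + "_scale.json", "w") as f:
        json.dump(sidecar, f, indent=2, sort_keys=True)
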