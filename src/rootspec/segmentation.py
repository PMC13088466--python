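"""Root/background segmentation and segment-grid geometry.

Roots are imaged against a blue hydroponic panel, so the background is
bright in the blue while root tissue attenuates it: thresholding the band
nearest 450 nm with Otsu's method separates the two classes.  The scene is
then tiled into 5 cm x 2.5 cm segments (the sampling unit whose dry weight
is measured), and per-segment root coverage and mean reflectance spectra
are extracted as model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cube import SpectralCube
from .errors import InvalidInputError, SegmentationError

__all__ = [
    "RootMask",
    "SegmentGrid",
    "SegmentRecord",
    "otsu_threshold",
    "root_mask_from_cube",
    "partition_grid",
    "coverage_percent",
    "mean_segment_spectrum",
    "extract_segments",
    "segments_to_frame",
]

BORDER_TOUCH_FLAG_FRACTION = 0.5


@dataclass
class RootMask:
    mask: np.ndarray  # H x W boolean, True = root
    method: str
    threshold: float


@dataclass
class SegmentGrid:
    """Contiguous non-overlapping tiling into segment cells.

    Cells are ``seg_height_px`` rows x ``seg_width_px`` columns, tiled
    row-major from ``origin_px``; partial cells at the far edges are dropped.
    """

    origin_px: tuple[int, int]
    seg_height_px: int
    seg_width_px: int
    n_rows: int
    n_cols: int

    def cell_bounds(self, i: int, j: int) -> tuple[int, int, int, int]:
        """(row0, col0, row1, col1) of cell (i, j), half-open."""
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise InvalidInputError(f"cell ({i}, {j}) outside grid")
        r0 = self.origin_px[0] + i * self.seg_height_px
        c0 = self.origin_px[1] + j * self.seg_width_px
        return r0, c0, r0 + self.seg_height_px, c0 + self.seg_width_px

    def cells(self):
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                yield i, j, self.cell_bounds(i, j)

    @property
    def pixels_per_cell(self) -> int:
        return self.seg_height_px * self.seg_width_px


@dataclass
class SegmentRecord:
    """One 5 x 2.5 cm root segment with its image-derived descriptors."""

    plant_id: int
    segment_id: int
    bounds_px: tuple[int, int, int, int]
    coverage_pct: float
    mean_spectrum: np.ndarray
    dry_weight_g: float | None = None
    flag: str = ""


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray) -> float:
    """Between-class-variance-maximising threshold of Otsu.

    A 256-bin histogram is built over [min, max]; candidate thresholds are
    the 255 interior bin edges, each splitting the data into ``x < t`` and
    ``x >= t``.  The edge maximising the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2`` is returned; ties break to the lowest
    qualifying threshold.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise InvalidInputError("need at least 2 values")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise InvalidInputError("constant input: no separable classes")
    edges = np.linspace(lo, hi, 257)
    # bin index such that values equal to an edge fall in the bin to its right
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, 255)
    counts = np.bincount(idx, minlength=256).astype(float)
    sums = np.bincount(idx, weights=x, minlength=256)
    n = x.size
    total = sums.sum()
    c0 = np.cumsum(counts)[:-1]  # class 0 = bins 0..k-1 for threshold edges[k]
    s0 = np.cumsum(sums)[:-1]
    w0 = c0 / n
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(c0 > 0, s0 / c0, 0.0)
        mu1 = np.where(n - c0 > 0, (total - s0) / (n - c0), 0.0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(sigma_b))  # argmax takes the first maximum -> lowest edge
    return float(edges[k + 1])


# minimum relative contrast between the dark (root) and bright (panel)
# Otsu classes; below this the "classes" are just sensor noise on bare panel
MIN_CLASS_CONTRAST = 0.2


def root_mask_from_cube(cube: SpectralCube, wavelength_nm: float = 450.0) -> RootMask:
    """Threshold the band nearest ``wavelength_nm`` (default the blue band).

    The blue panel is bright at 450 nm while roots attenuate it, so root
    pixels are those BELOW the Otsu threshold.  If the two classes differ
    by less than the detection-limit contrast (Otsu will split pure sensor
    noise on a root-free panel), the scene is reported as containing no
    roots.
    """
    b = cube.band_nearest(wavelength_nm)
    band = cube.reflectance[:, :, b]
    try:
        t = otsu_threshold(band)
    except InvalidInputError as e:
        raise SegmentationError(f"no roots detected: {e}") from e
    mask = band < t
    mu_root = float(band[mask].mean()) if mask.any() else 0.0
    mu_panel = float(band[~mask].mean()) if (~mask).any() else 0.0
    if mu_panel <= 0 or (mu_panel - mu_root) / mu_panel < MIN_CLASS_CONTRAST:
        raise SegmentationError(
            "no roots detected: class contrast below the detection limit"
        )
    return RootMask(mask=mask, method=f"otsu@{cube.wavelengths_nm[b]:.0f}nm", threshold=t)


# ---------------------------------------------------------------------------
# grid geometry
# ---------------------------------------------------------------------------

def partition_grid(
    cube: SpectralCube,
    seg_cm: tuple[float, float] = (2.5, 5.0),
    origin: tuple[int, int] = (0, 0),
) -> SegmentGrid:
    """Tile the image into segment cells of ``seg_cm`` = (length, width) cm.

    Length runs along rows (the root growth direction, plant base at row 0),
    width along columns.  Cell size in pixels is ``round(cm / pixel_size)``;
    only complete cells are kept.
    """
    h, w, _ = cube.shape
    seg_h = int(round(seg_cm[0] / cube.pixel_size_cm))
    seg_w = int(round(seg_cm[1] / cube.pixel_size_cm))
    if seg_h < 1 or seg_w < 1:
        raise InvalidInputError("segment smaller than one pixel")
    if seg_h > h - origin[0] or seg_w > w - origin[1]:
        raise SegmentationError("empty grid: segment larger than image below origin")
    n_rows = (h - origin[0]) // seg_h
    n_cols = (w - origin[1]) // seg_w
    if n_rows < 1 or n_cols < 1:
        raise SegmentationError("empty grid")
    return SegmentGrid(
        origin_px=(int(origin[0]), int(origin[1])),
        seg_height_px=seg_h,
        seg_width_px=seg_w,
        n_rows=n_rows,
        n_cols=n_cols,
    )


def _check_bounds(shape_hw: tuple[int, int], bounds: tuple[int, int, int, int]) -> None:
    r0, c0, r1, c1 = bounds
    if not (0 <= r0 < r1 <= shape_hw[0] and 0 <= c0 < c1 <= shape_hw[1]):
        raise InvalidInputError(f"bounds {bounds} outside image {shape_hw}")


def coverage_percent(mask: np.ndarray, bounds: tuple[int, int, int, int]) -> float:
    """Percentage of pixels inside ``bounds`` that are root."""
    mask = np.asarray(mask, dtype=bool)
    _check_bounds(mask.shape, bounds)
    r0, c0, r1, c1 = bounds
    sub = mask[r0:r1, c0:c1]
    return 100.0 * float(sub.sum()) / sub.size


def mean_segment_spectrum(
    cube: SpectralCube,
    mask: np.ndarray,
    bounds: tuple[int, int, int, int],
    pixels: str = "root",
) -> tuple[np.ndarray, bool]:
    """Per-band mean reflectance of a segment.

    With ``pixels="root"`` the mean runs over root pixels only; if the
    segment contains none, the mean over all segment pixels is returned
    with ``fallback=True`` instead of raising, so empty segments survive
    batch processing and can be filtered by the caller.  With
    ``pixels="all"`` the mean runs over the whole segment area, blending
    root and background in proportion to coverage — the area-mean spectrum
    a segment-level reflectance extraction yields, and the default used by
    the dataset pipeline because it encodes both root density and root
    coverage (the two factors of segment dry weight).
    """
    _check_bounds(cube.shape[:2], bounds)
    r0, c0, r1, c1 = bounds
    sub = cube.reflectance[r0:r1, c0:c1, :]
    if pixels == "all":
        return sub.reshape(-1, sub.shape[-1]).mean(axis=0), False
    if pixels != "root":
        raise InvalidInputError(f"pixels must be 'root' or 'all', got {pixels!r}")
    m = np.asarray(mask, dtype=bool)[r0:r1, c0:c1]
    if m.any():
        return sub[m].mean(axis=0), False
    return sub.reshape(-1, sub.shape[-1]).mean(axis=0), True


def _border_touch_fraction(mask_cell: np.ndarray) -> float:
    border = np.concatenate(
        [mask_cell[0, :], mask_cell[-1, :], mask_cell[:, 0], mask_cell[:, -1]]
    )
    return float(border.mean())


def extract_segments(
    cube: SpectralCube,
    mask: RootMask | np.ndarray,
    grid: SegmentGrid,
    plant_of_column=None,
    truth_weights: dict[tuple[int, int], float] | None = None,
    spectrum_pixels: str = "all",
) -> list[SegmentRecord]:
    """Build one :class:`SegmentRecord` per grid cell.

    ``plant_of_column`` maps a grid column index to a plant id (defaults to
    the identity: one plant per column, the layout used by the simulator).
    ``spectrum_pixels`` selects area-mean (``"all"``, default) or
    root-pixel-mean (``"root"``) segment spectra.  Segments whose root mask
    occupies more than half of the cell border are flagged ``"border"``
    (the analogue of roots escaping their partition); segments with no
    detected root pixels are flagged ``"empty"``.
    """
    m = mask.mask if isinstance(mask, RootMask) else np.asarray(mask, dtype=bool)
    records = []
    for i, j, (r0, c0, r1, c1) in grid.cells():
        bounds = (r0, c0, r1, c1)
        cov = coverage_percent(m, bounds)
        spec, fell_back = mean_segment_spectrum(cube, m, bounds, pixels=spectrum_pixels)
        flag = ""
        if fell_back or cov == 0.0:
            flag = "empty"
        elif _border_touch_fraction(m[r0:r1, c0:c1]) > BORDER_TOUCH_FLAG_FRACTION:
            flag = "border"
        plant = int(plant_of_column(j)) if plant_of_column is not None else j
        weight = None
        if truth_weights is not None:
            weight = truth_weights.get((i, j))
        records.append(
            SegmentRecord(
                plant_id=plant,
                segment_id=i,
                bounds_px=bounds,
                coverage_pct=cov,
                mean_spectrum=np.asarray(spec, dtype=float),
                dry_weight_g=weight,
                flag=flag,
            )
        )
    return records


def segments_to_frame(records: list[SegmentRecord], wavelengths_nm: np.ndarray) -> pd.DataFrame:
    """Tabulate segment records; one ``wl_<nm>`` column per band."""
    rows = []
    for r in records:
        row = {
            "plant_id": r.plant_id,
            "segment_id": r.segment_id,
            "row0": r.bounds_px[0],
            "col0": r.bounds_px[1],
            "height_px": r.bounds_px[2] - r.bounds_px[0],
            "width_px": r.bounds_px[3] - r.bounds_px[1],
            "coverage_pct": r.coverage_pct,
            "flag": r.flag,
            "dry_weight_g": np.nan if r.dry_weight_g is None else r.dry_weight_g,
        }
        for wl, v in zip(wavelengths_nm, r.mean_spectrum):
            row[f"wl_{wl:.1f}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
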