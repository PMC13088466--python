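"""End-to-end workflows: synthetic dataset assembly and the full demo.

``simulate_dataset`` renders seeded multi-plant scenes, calibrates and trims
them, segments roots at 450 nm, tiles the 5 x 2.5 cm grid and returns one
row per root-bearing segment with coverage, mean root-pixel spectrum and the
exact ground-truth dry weight — the synthetic stand-in for a greenhouse
training campaign.

``run_demo`` chains everything: training-set simulation, 36-spec grid search
with LOOCV, evaluation against the area baseline on a held-out 20% split,
an independent multi-plant validation batch scored in g/plant, pixel-level
biomass maps and a daily growth series.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import subseed, substream
from .cube import SpectralCube, calibrate, trim_bands
from .errors import InvalidInputError
from .evaluation import (
    evaluate_predictions,
    fit_area_model,
    predict_area,
    r_squared,
    split_train_test,
)
from .mapping import growth_series, pixel_biomass_map, plant_total, render_false_color
from .pls import grid_search, predict, save_model
from .preprocessing import SpectrumTable
from .scene import (
    SceneConfig,
    build_optics,
    grow_scene,
    render_scene,
    truth_segment_weights,
)
from .segmentation import (
    extract_segments,
    partition_grid,
    root_mask_from_cube,
    segments_to_frame,
)

logger = logging.getLogger("rootspec")

__all__ = [
    "simulate_dataset",
    "simulate_growth_days",
    "frame_to_table",
    "run_demo",
    "MIN_SEGMENT_WEIGHT_G",
]

# a segment counts as root-bearing (and enters the dataset, as in a harvest
# campaign where only rooted segments are cut and weighed) above this truth weight
MIN_SEGMENT_WEIGHT_G = 1e-3

TRIM_LO_NM = 450.0
TRIM_HI_NM = 950.0


def _segment_scene(raw, config: SceneConfig, scene_idx: int, plant_offset: int) -> pd.DataFrame:
    """Calibrate, trim, segment one raw scene; attach truth weights."""
    cube = trim_bands(calibrate(raw), TRIM_LO_NM, TRIM_HI_NM)
    grid = partition_grid(cube)
    mask = root_mask_from_cube(cube)
    truth = truth_segment_weights(raw.truth_density, grid)
    weights = {
        (int(r.grid_row), int(r.grid_col)): float(r.dry_weight_g)
        for r in truth.itertuples()
    }
    # one plant per 5 cm grid column in the simulated layout
    records = extract_segments(
        cube,
        mask,
        grid,
        plant_of_column=lambda j: plant_offset + j,
        truth_weights=weights,
    )
    frame = segments_to_frame(records, cube.wavelengths_nm)
    frame.insert(0, "scene", scene_idx)
    return frame


def simulate_dataset(
    n_plants: int = 60,
    config: SceneConfig | None = None,
    seed: int = 0,
    stage_range: tuple[float, float] = (0.35, 1.0),
    keep_all_segments: bool = False,
):
    """Generate a segment-level dataset from ``ceil(n_plants / plants-per-scene)``
    scenes.

    Plant growth stages are drawn uniformly from ``stage_range`` so the
    dataset spans sparse distal to dense basal segments.  Unless
    ``keep_all_segments``, only root-bearing segments (truth weight above
    ``MIN_SEGMENT_WEIGHT_G``) are kept, mirroring a sampling campaign in
    which only rooted segments are harvested.

    Returns ``(frame, wavelengths_nm)``.
    """
    if config is None:
        config = SceneConfig()
    n_scenes = int(np.ceil(n_plants / config.n_plants))
    optics = build_optics(config.wavelengths_nm)
    rng = substream(seed, "stages")
    frames = []
    plants_done = 0
    for s in range(n_scenes):
        n_here = min(config.n_plants, n_plants - plants_done)
        stages = rng.uniform(stage_range[0], stage_range[1], size=config.n_plants)
        if n_here < config.n_plants:
            stages[n_here:] = 0.0
        arch, labels = grow_scene(config, stages, seed=subseed(seed, "scene", s))
        raw = render_scene(arch, optics, config, seed=subseed(seed, "render", s), plant_labels=labels)
        frame = _segment_scene(raw, config, s, plant_offset=plants_done)
        frames.append(frame)
        plants_done += n_here
    data = pd.concat(frames, ignore_index=True)
    if not keep_all_segments:
        data = data[data["dry_weight_g"] > MIN_SEGMENT_WEIGHT_G].reset_index(drop=True)
    wavelengths = np.array(
        [float(c[3:]) for c in data.columns if c.startswith("wl_")]
    )
    return data, wavelengths


def frame_to_table(frame: pd.DataFrame, wavelengths_nm: np.ndarray) -> SpectrumTable:
    """Extract the spectral matrix and dry-weight target from a segment frame."""
    cols = [c for c in frame.columns if c.startswith("wl_")]
    if len(cols) != len(wavelengths_nm):
        raise InvalidInputError("frame band columns do not match wavelengths")
    y = frame["dry_weight_g"].to_numpy() if "dry_weight_g" in frame else None
    if y is not None and np.all(np.isnan(y)):
        y = None
    return SpectrumTable(
        X=frame[cols].to_numpy(),
        wavelengths_nm=wavelengths_nm,
        y=y,
        ids=frame.index.to_numpy(),
    )


def simulate_growth_days(
    n_days: int,
    config: SceneConfig,
    seed: int,
    final_stage: float = 1.0,
):
    """Yield (dap, raw_scene, stage) for a logistic growth trajectory.

    Stage follows a logistic curve in time (slow establishment, rapid
    mid-season growth, late saturation), the canonical biomass trajectory.
    Day 0 is planting (stage 0).  Plants develop radially (natural
    conditions, no partition boards).
    """
    days = np.arange(n_days + 1)
    z = (days - 0.45 * n_days) / (0.12 * n_days)
    stage = final_stage / (1.0 + np.exp(-z))
    stage[0] = 0.0
    optics = build_optics(config.wavelengths_nm)
    for dap in days:
        arch, labels = grow_scene(
            config, float(stage[dap]), seed=subseed(seed, "series"), mode="radial"
        )
        raw = render_scene(
            arch, optics, config, seed=subseed(seed, "series-noise", int(dap)),
            plant_labels=labels,
        )
        yield int(dap), raw, float(stage[dap])


# ---------------------------------------------------------------------------
# demo
# ---------------------------------------------------------------------------

@dataclass
class DemoSizes:
    """Problem sizes of the demo pipeline (see docs/methods.md)."""

    n_train_plants: int = 60
    n_validation_plants: int = 104
    n_series_days: int = 50
    n_series_plants: int = 4


def run_demo(
    config: SceneConfig | None = None,
    seed: int = 1,
    out_dir: str = "demo_out",
    sizes: DemoSizes | None = None,
    train_frac: float = 0.8,
    max_lv: int = 16,
    baseline_form: str = "power",
) -> dict:
    """Run the full pipeline end to end; returns (and writes) a report dict."""
    config = config or SceneConfig()
    sizes = sizes or DemoSizes()
    os.makedirs(out_dir, exist_ok=True)
    logger.info("simulating %d training plants", sizes.n_train_plants)
    data, wavelengths = simulate_dataset(sizes.n_train_plants, config, seed=subseed(seed, "train"))
    train, test = split_train_test(data, train_frac=train_frac, seed=subseed(seed, "split"))
    logger.info("grid search over 36 preprocessing specs (n_train=%d)", len(train))
    model, cv, ranking = grid_search(frame_to_table(train, wavelengths), max_lv=max_lv)
    ranking.to_csv(os.path.join(out_dir, "ranking.csv"), index=False)
    save_model(model, os.path.join(out_dir, "model.json"))

    test_table = frame_to_table(test, wavelengths)
    yhat_pls = predict(model, test_table.X)
    area = fit_area_model(train["coverage_pct"], train["dry_weight_g"], form=baseline_form)
    yhat_area = predict_area(area, test["coverage_pct"].to_numpy())
    report_eval = evaluate_predictions(
        test_table.y, {"plsr": yhat_pls, "area": yhat_area}, units="g/segment"
    )
    logger.info("test metrics:\n%s", report_eval)

    # independent validation batch in g/plant
    logger.info("simulating %d validation plants", sizes.n_validation_plants)
    val_truth, val_pred = validation_batch(
        sizes.n_validation_plants, config, model, seed=subseed(seed, "validation")
    )
    val_r2 = r_squared(val_truth, val_pred)

    # daily growth series of a single plant at reduced field of view
    from dataclasses import replace

    series_cfg = replace(config, image_size_px=(256, 256), field_cm=(12.5, 12.5), n_plants=1)
    series_rows = []
    for p in range(sizes.n_series_plants):
        frame = demo_growth_series(
            sizes.n_series_days, series_cfg, model, seed=subseed(seed, "series", p), plant_id=p
        )
        series_rows.append(frame)
    series = pd.concat(series_rows, ignore_index=True)
    series.to_csv(os.path.join(out_dir, "growth_series.csv"), index=False)

    best = ranking.loc[ranking["rmsecv"].idxmin()]
    report = {
        "seed": seed,
        "n_segments": int(len(data)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "best_preproc": f"{best.layer1}/{best.layer2}/{best.layer3}",
        "selected_lv": int(cv.selected_lv),
        "rmsecv_sqrt_g": cv.min_rmsecv,
        "evaluation": report_eval.to_dict(),
        "ranking_rows": int(len(ranking)),
        "validation_r2_g_per_plant": val_r2,
        "series_final_relative_error_pct": series.groupby("plant_id")["relative_error_pct"]
        .last()
        .mean(),
    }
    with open(os.path.join(out_dir, "report.json"), "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    return report


def validation_batch(n_plants: int, config: SceneConfig, model, seed: int):
    """Render an independent batch, map biomass per plant strip, return
    (truth totals, predicted totals) in g/plant over the gridded area."""
    optics = build_optics(config.wavelengths_nm)
    rng = substream(seed, "stages")
    n_scenes = int(np.ceil(n_plants / config.n_plants))
    truths, preds = [], []
    done = 0
    for s in range(n_scenes):
        n_here = min(config.n_plants, n_plants - done)
        stages = rng.uniform(0.4, 1.0, size=config.n_plants)
        if n_here < config.n_plants:
            stages[n_here:] = 0.0
        arch, labels = grow_scene(config, stages, seed=subseed(seed, "vscene", s))
        raw = render_scene(arch, optics, config, seed=subseed(seed, "vrender", s))
        cube = trim_bands(calibrate(raw), TRIM_LO_NM, TRIM_HI_NM)
        grid = partition_grid(cube)
        mask = root_mask_from_cube(cube)
        bmap = pixel_biomass_map(cube, model, mask, grid)
        h = grid.origin_px[0] + grid.n_rows * grid.seg_height_px
        w_cell = grid.seg_width_px
        for p in range(n_here):
            c0 = grid.origin_px[1] + p * w_cell
            if c0 + w_cell > cube.shape[1]:
                break
            region = (grid.origin_px[0], c0, h, c0 + w_cell)
            preds.append(plant_total(bmap, region))
            truths.append(
                raw.truth_density[region[0]:region[2], region[1]:region[3]].sum() / 1000.0
            )
        done += n_here
    return np.array(truths), np.array(preds)


def demo_growth_series(
    n_days: int,
    config: SceneConfig,
    model,
    seed: int,
    plant_id: int = 0,
) -> pd.DataFrame:
    """Daily biomass totals for one simulated plant, with final-day truth."""
    day_cubes = []
    final_truth = None
    for dap, raw, _stage in simulate_growth_days(n_days, config, seed):
        cube = trim_bands(calibrate(raw), TRIM_LO_NM, TRIM_HI_NM)
        day_cubes.append((dap, cube))
        final_truth = raw.truth_density
    grid = partition_grid(day_cubes[-1][1])
    h, w = day_cubes[-1][1].shape[:2]
    gh = grid.origin_px[0] + grid.n_rows * grid.seg_height_px
    gw = grid.origin_px[1] + grid.n_cols * grid.seg_width_px
    region = (grid.origin_px[0], grid.origin_px[1], gh, gw)
    obs = final_truth[region[0]:region[2], region[1]:region[3]].sum() / 1000.0
    frame = growth_series(
        day_cubes, model, regions={plant_id: region}, grid=grid,
        observed_final={plant_id: obs},
    )
    return frame
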