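"""End-to-end orchestration: simulate -> classify -> tiles -> fit -> depletion.

A :class:`RunConfig` names the input mode (synthetic scenes, raster files, or
pre-built tile tables), the scene parameters, classification settings and the
model questions to run.  :func:`run_pipeline` executes the stages in order,
writes every intermediate artifact under the output directory and records a
manifest (stage, outputs, SHA-256 checksums, seed, package versions) so a run
is reproducible from its config and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import depletion as dep
from . import io as vio
from . import models as hm
from . import tiles as tl
from .scene import SceneParams, simulate_series, true_mound_cover

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("volehabitat")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # synthetic | rasters | tables
    out_dir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "classify", "tiles", "fit", "depletion")
    scene: SceneParams = field(default_factory=SceneParams)
    n_quadrats: int = 2
    min_pixels: int = 4
    questions: tuple[str, ...] = ("q1", "q2", "q3")
    ladder: bool = True
    raster_dir: str | None = None
    tables_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "rasters", "tables"):
            raise ValueError("mode must be synthetic, rasters or tables")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _versions() -> dict[str, str]:
    import numpy, pandas, scipy, skimage, statsmodels  # noqa: PLC0415

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-image": skimage.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "versions": _versions(),
        "stages": [],
    }
    artifacts: dict[str, Path] = {}
    state: dict = {}

    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("simulate", "classify", "tiles", "fit", "depletion"), ss.spawn(5)
        )
    }

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": stage_seeds.get(stage),
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
            }
        )

    for stage in config.stages:
        try:
            outputs = _STAGES[stage](config, out, state, stage_seeds.get(stage, 0))
        except Exception as err:
            manifest["failed_stage"] = {"stage": stage, "error": str(err)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
        record(stage, outputs)
        for p in outputs:
            artifacts[p.name] = p

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(config: RunConfig, out: Path, state: dict, seed: int) -> list[Path]:
    outputs = []
    state["series"] = {}
    for q in range(config.n_quadrats):
        qid = f"q{q:02d}"
        series = simulate_series(config.scene, seed + q, render=True)
        state["series"][qid] = series
        for label, scene, truth in series:
            if scene is not None:
                p = out / f"{qid}_{label}.tif"
                vio.write_scene(scene, p)
                outputs.append(p)
            for key in ("flowers", "mounds"):
                pts = truth[key]
                if pts is not None and len(pts):
                    p = out / f"{qid}_{label}_{key}.csv"
                    vio.write_points(pts, p)
                    outputs.append(p)
    log.info("simulated %d quadrats", config.n_quadrats)
    return outputs


def _stage_classify(config: RunConfig, out: Path, state: dict, seed: int) -> list[Path]:
    outputs = []
    state["masks"] = {}
    rng = np.random.default_rng(seed)
    for qid, series in state.get("series", {}).items():
        for label, scene, truth in series:
            if scene is None:
                continue
            ym = cls.filter_small_components(cls.classify_yellow(scene), config.min_pixels)
            masks = {"yellow": ym}
            if len(truth["mounds"]):
                # training pixels: sample mapped mound centres (synthetic mode
                # plays the operator marking bare earth)
                train = truth["mounds"].sample(
                    n=min(50, len(truth["mounds"])), random_state=int(rng.integers(2**31))
                )
                win = cls.calibrate_brown_window(scene, train)
                masks["brown"] = cls.classify_brown(scene, win)
            state["masks"][(qid, label)] = masks
            for name, m in masks.items():
                p = out / f"{qid}_{label}_{name}.tif"
                vio.write_mask(m, p)
                outputs.append(p)
    return outputs


def _stage_tiles(config: RunConfig, out: Path, state: dict, seed: int) -> list[Path]:
    sc = config.scene
    grid = tl.build_tile_grid(sc.quadrat_width, sc.quadrat_height, sc.tile_size)
    frames = []
    for qid, series in state.get("series", {}).items():
        cover = {}
        heads = {}
        for label, scene, truth in series:
            masks = state.get("masks", {}).get((qid, label), {})
            if "brown" in masks:
                cover[label] = tl.tile_mound_cover(masks["brown"], grid)
            elif len(truth["mounds"]):
                cover[label] = true_mound_cover(truth["mounds"], sc)
            else:
                cover[label] = np.zeros((grid.ny, grid.nx))
            if "yellow" in masks and label.startswith("may"):
                heads[label] = tl.tile_flower_heads(masks["yellow"], grid)
        frames.append(tl.tile_table(qid, grid, cover, heads))
    table = pd.concat(frames, ignore_index=True)
    state["tiles"] = table
    p = out / "tile_table.csv"
    table.to_csv(p, index=False)
    log.info("tile table: %d rows", len(table))
    return [p]


def _stage_fit(config: RunConfig, out: Path, state: dict, seed: int) -> list[Path]:
    table = state.get("tiles")
    if table is None and config.tables_path:
        table = pd.read_csv(config.tables_path)
    if table is None:
        raise ValueError("fit stage needs a tile table (run 'tiles' first or give tables_path)")
    outputs = []

    if "q1" in config.questions:
        subset, response = tl.label_new_colonization(
            table["col_march_y1"].to_numpy(bool), table["col_october_y1"].to_numpy(bool)
        )
        df = table.loc[subset].copy()
        df["Col"] = response[subset].astype(int)
        df = df.rename(columns={"Anom_may_y1": "Anom", "D_t_may_y1": "D_t", "D_q_may_y1": "D_q"})
        df = df.dropna(subset=["Anom"])
        log.info("Q1 subset: %d tiles, %d colonized", len(df), int(df["Col"].sum()))
        if df["Col"].nunique() > 1:
            if config.ladder:
                ladder = hm.aic_ladder(df, hm.COLONIZATION_LADDER)
                p = out / "q1_aic_ladder.csv"
                ladder.rows.to_csv(p, index=False)
                outputs.append(p)
            fit = hm.fit_colonization_model(df)
            p = out / "q1_coefficients.csv"
            fit.coef_table().to_csv(p)
            outputs.append(p)
            curves = hm.predict_response_curves(fit, df, "Anom", "D_q")
            p = out / "q1_prediction_curves.csv"
            curves.to_csv(p, index=False)
            outputs.append(p)

    if "q2" in config.questions:
        subset, response = tl.label_reuse(
            table["col_october_y1"].to_numpy(bool),
            table["col_march_y2"].to_numpy(bool),
            table["col_october_y2"].to_numpy(bool),
        )
        df = table.loc[subset].copy()
        df["Reuse"] = response[subset].astype(int)
        df = df.rename(columns={"Anom_may_y2": "Anom", "D_t_may_y2": "D_t", "D_q_may_y2": "D_q"})
        log.info("Q2 subset: %d tiles, %d reused", len(df), int(df["Reuse"].sum()))
        if len(df) and df["Reuse"].nunique() > 1:
            fit = hm.fit_reuse_model(df)
            p = out / "q2_coefficients.csv"
            fit.coef_table().to_csv(p)
            outputs.append(p)

    if "q3" in config.questions:
        df = table.copy()
        df["DPGR"] = tl.compute_dpgr(
            df["heads_may_y1"].to_numpy(), df["heads_may_y2"].to_numpy()
        )
        df["Cover"] = df["cover_march_y2"].to_numpy() * 100.0  # percent
        df = df.loc[~table["col_may_y1"].astype(bool) if "col_may_y1" in table else ~table["col_march_y1"].astype(bool)]
        df = df.dropna(subset=["DPGR"])
        log.info("Q3 subset: %d tiles with defined DPGR", len(df))
        if len(df) and df["Cover"].var() > 0:
            fit = hm.fit_dpgr_model(df)
            p = out / "q3_coefficients.csv"
            fit.coef_table().to_csv(p)
            outputs.append(p)
    return outputs


def _stage_depletion(config: RunConfig, out: Path, state: dict, seed: int) -> list[Path]:
    # carve colony-centred subplots out of the simulated quadrats
    sc = config.scene
    subplots = []
    for qid, series in state.get("series", {}).items():
        truth = {label: t for label, _, t in series}
        mounds = truth["march_y2"]["mounds"]
        flowers = truth["may_y2"]["flowers"]
        if mounds is None or not len(mounds):
            continue
        for cid, grp in mounds.groupby("colony_id"):
            cx, cy = grp["x_m"].mean(), grp["y_m"].mean()
            half = 10.0
            if not (half <= cx <= sc.quadrat_width - half and half <= cy <= sc.quadrat_height - half):
                continue
            ext = (cx - half, cy - half, cx + half, cy + half)
            fsel = flowers[
                flowers["x_m"].between(ext[0], ext[2]) & flowers["y_m"].between(ext[1], ext[3])
            ]
            if len(fsel) == 0:
                continue
            subplots.append(
                dep.SubplotData(f"{qid}_c{cid}", grp.reset_index(drop=True), fsel.reset_index(drop=True), ext)
            )
    if len(subplots) < 5:
        log.info("depletion stage skipped: only %d usable subplots", len(subplots))
        return []
    records = pd.concat([dep.depletion_profile(sp) for sp in subplots], ignore_index=True)
    p_rec = out / "depletion_buffers.csv"
    records.to_csv(p_rec, index=False)
    fit = dep.fit_depletion_gam(records)
    curve = fit.predict_curve(np.geomspace(0.06, 5.0, 100))
    p_curve = out / "depletion_curve.csv"
    curve.to_csv(p_curve, index=False)
    ladder = dep.depletion_ladder(records)
    p_lad = out / "depletion_aic_ladder.csv"
    ladder.rows.to_csv(p_lad, index=False)
    return [p_rec, p_curve, p_lad]


_STAGES = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "tiles": _stage_tiles,
    "fit": _stage_fit,
    "depletion": _stage_depletion,
}
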