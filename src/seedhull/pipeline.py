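"""End-to-end orchestration: images -> calibration -> traits -> statistics.

The two entry points mirror the two halves of the workflow:

* :func:`run_reconstruction` — per-seed image directories plus a rig
  calibration JSON in, one trait row per seed out (plus meshes and a run
  report),
* :func:`run_stats` — a trait table plus a variety design table in,
  summary / nested-ANOVA / GVF tables out.

Both fail fast with stage-attributed errors and are deterministic given
(inputs, config, random seed).
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import BoardSpec, CalibrationResult
from .errors import SeedHullError
from .silhouette import extract_silhouettes
from .traits import measure_all
from .variation import TRAIT_COLUMNS, gvf_table, nested_anova, summarize_traits
from .visual_hull import VoxelGrid, carve, mesh_from_grid

__all__ = [
    "RunConfig",
    "PipelineError",
    "load_view_images",
    "reconstruct_seed",
    "run_reconstruction",
    "run_stats",
    "save_grid",
    "load_grid",
]


class PipelineError(SeedHullError):
    """Stage-attributed pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration for a full run; defaults match the reference rig."""

    images_dir: str = "."
    calibration: str = "calib.json"
    output_dir: str = "out"
    board_rows: int = 9
    board_cols: int = 9
    pitch_mm: float = 0.5
    step_deg: float = 9.0
    n_views: int = 40
    resolution: int = 128
    threshold: str | float = "auto"
    change_fraction: float = 0.30
    traits_csv: str = "traits.csv"
    design_csv: str = "design.csv"
    random_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.step_deg * self.n_views > 360.0 + 1e-6 + self.step_deg:
            raise ValueError("step_deg * n_views exceeds one revolution")

    @property
    def board(self) -> BoardSpec:
        return BoardSpec(rows=self.board_rows, cols=self.board_cols, pitch=self.pitch_mm)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


_VIEW_RE = re.compile(r"_(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


def load_view_images(directory) -> list[np.ndarray]:
    """Grayscale view images ``<prefix>_<viewindex>.(png|tif)``, index order."""
    import imageio.v3 as iio

    directory = Path(directory)
    files = []
    for f in sorted(directory.iterdir()):
        m = _VIEW_RE.search(f.name)
        if m:
            files.append((int(m.group(1)), f))
    if not files:
        raise PipelineError("io", f"no view images found in {directory}")
    files.sort()
    out = []
    for _, f in files:
        img = np.asarray(iio.imread(f), dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        out.append(img / max(img.max(), 1e-12))
    return out


def reconstruct_seed(
    images: list[np.ndarray],
    projections,
    resolution: int = 128,
    threshold="auto",
    change_fraction: float = 0.30,
    nozzle: bool = True,
):
    """Silhouettes -> carve -> mesh -> traits for one seed.

    Returns (traits, mesh, grid).
    """
    sils = extract_silhouettes(
        images, threshold=threshold, change_fraction=change_fraction, nozzle=nozzle
    )
    grid = carve(sils, projections, resolution=resolution)
    mesh = mesh_from_grid(grid)
    return measure_all(grid, mesh), mesh, grid


def run_reconstruction(config: RunConfig) -> pd.DataFrame:
    """Reconstruct every seed directory under ``config.images_dir``.

    Each subdirectory of ``images_dir`` holding view images is one seed (a
    flat directory is treated as a single seed).  Writes one mesh per seed,
    a traits CSV, and a JSON run report with per-stage timings.
    """
    calib_path = Path(config.calibration)
    if not calib_path.exists():
        raise PipelineError("calibration", f"calibration file not found: {calib_path}")
    try:
        calib = CalibrationResult.load(calib_path)
    except (json.JSONDecodeError, KeyError) as exc:
        raise PipelineError("calibration", f"invalid calibration JSON: {exc}") from exc

    images_root = Path(config.images_dir)
    if not images_root.exists():
        raise PipelineError("io", f"image directory not found: {images_root}")
    seed_dirs = sorted(d for d in images_root.iterdir() if d.is_dir()) or [images_root]

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, report_stages = [], []
    for d in seed_dirs:
        t0 = time.perf_counter()
        images = load_view_images(d)
        if len(images) != len(calib.projections):
            raise PipelineError(
                "reconstruct",
                f"{d.name}: {len(images)} images but {len(calib.projections)} views calibrated",
            )
        try:
            traits, mesh, grid = reconstruct_seed(
                images,
                calib.projections,
                resolution=config.resolution,
                threshold=config.threshold,
                change_fraction=config.change_fraction,
            )
        except SeedHullError as exc:
            raise PipelineError("reconstruct", f"{d.name}: {exc}") from exc
        mesh.export(out_dir / f"{d.name}.ply")
        rows.append({"seed_id": d.name, **traits.as_dict()})
        report_stages.append({"seed": d.name, "seconds": time.perf_counter() - t0})

    table = pd.DataFrame(rows)
    traits_path = out_dir / config.traits_csv
    table.to_csv(traits_path, index=False, float_format="%.6g")
    report = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "n_seeds": len(rows),
        "stages": report_stages,
    }
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return table


def _validate_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PipelineError("stats", f"{what} is missing columns {missing}")


def run_stats(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Summary, nested-ANOVA and GVF tables from a traits + design CSV pair.

    The design CSV needs columns variety, group, role (parent/offspring).
    With a single variety the ANOVA and GVF stages are skipped with an
    explicit notice in the returned dict (key ``notices``).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traits_path = Path(config.traits_csv)
    design_path = Path(config.design_csv)
    for p, what in ((traits_path, "traits CSV"), (design_path, "design CSV")):
        if not p.exists():
            raise PipelineError("stats", f"{what} not found: {p}")
    traits = pd.read_csv(traits_path)
    _validate_columns(traits, ["seed_id"] + TRAIT_COLUMNS, "traits CSV")
    design = pd.read_csv(design_path)
    _validate_columns(design, ["variety", "group", "role"], "design CSV")
    if "variety" in traits.columns:
        table = traits.merge(design.drop_duplicates("variety"), on="variety", how="left",
                             suffixes=("", "_design"))
    else:
        _validate_columns(design, ["seed_id"], "design CSV (no variety in traits)")
        table = traits.merge(design, on="seed_id", how="left")
    if table["variety"].isna().any():
        bad = table.loc[table["variety"].isna(), "seed_id"].tolist()[:5]
        raise PipelineError("stats", f"seeds without a design row: {bad}")

    notices: list[str] = []
    results: dict[str, pd.DataFrame] = {}
    summary = summarize_traits(table, scope="pooled").sort_values("pcv", ascending=False)
    summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.6g")
    results["summary"] = summary

    offspring = table[table["role"] == "offspring"]
    if offspring["group"].nunique() >= 2:
        anova = nested_anova(offspring).table
        anova.to_csv(out_dir / "anova.csv", index=False, float_format="%.6g")
        results["anova"] = anova
    else:
        notices.append("ANOVA skipped: fewer than 2 offspring germplasm groups")

    parents = table.loc[table["role"] == "parent", "variety"].unique()
    if len(parents) == 2:
        res = gvf_table(table, parent_labels=tuple(parents))
        out = res.matrix.copy()
        out.loc["average"] = res.averages
        out.to_csv(out_dir / "gvf.csv", float_format="%.6g")
        results["gvf"] = out
        results["gvf_ranking"] = pd.DataFrame({"variety": res.ranking})
    else:
        notices.append(f"GVF skipped: found {len(parents)} parent varieties, need 2")

    if notices:
        (out_dir / "notices.txt").write_text("\n".join(notices) + "\n")
        results["notices"] = pd.DataFrame({"notice": notices})
    return results


# ---------------------------------------------------------------------------
# voxel grid I/O (raw uint8 + JSON header)
# ---------------------------------------------------------------------------


def save_grid(grid: VoxelGrid, path) -> None:
    """Write occupancy as raw uint8 alongside a JSON header ``<path>.json``."""
    path = Path(path)
    grid.occupancy.astype(np.uint8).tofile(path)
    header = {
        "origin": grid.origin.tolist(),
        "spacing": grid.spacing,
        "dims": list(grid.dims),
        "dtype": "uint8",
        "order": "C",
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(header, fh)


def load_grid(path) -> VoxelGrid:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        header = json.load(fh)
    occ = np.fromfile(path, dtype=np.uint8).reshape(header["dims"]).astype(bool)
    return VoxelGrid(origin=np.array(header["origin"]), spacing=header["spacing"], occupancy=occ)
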