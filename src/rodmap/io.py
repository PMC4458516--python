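"""File formats, run configuration and artefact writing.

All tabular outputs are tab-delimited text with a header row; images are
standard multi-page TIFF (one page per channel); rendered maps are
additionally saved as raster PNGs for inspection.  Every run directory
gets a machine-readable JSON manifest recording inputs, parameters (and
their hash) and package versions.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import tifffile
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cyclemap import DEFAULT_N_CLASSES, DEFAULT_WINDOW_UM, ProfileMap
from .defects import (
    DEFAULT_AREA_MAX_UM2,
    DEFAULT_BLEB_QUANTILE,
    DEFAULT_LEAK_QUANTILE,
    DEFAULT_PROXIMITY_MAX_UM,
    BlebCall,
    LeakageCall,
)
from .profile import DEFAULT_CONTOUR_SPACING_UM, AxialProfile, ContourTrace
from .synthgen import DEFAULT_PIXEL_SIZE_UM, GroundTruth, Scene


@dataclass
class RunConfig:
    """Validated parameters for a pipeline run."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_bins: int = 50
    n_cols: int = 50
    n_classes: int = DEFAULT_N_CLASSES
    ring_window_um: float = DEFAULT_WINDOW_UM
    flank_um: float = DEFAULT_WINDOW_UM
    contour_spacing_um: float = DEFAULT_CONTOUR_SPACING_UM
    subtract_contour_background: bool = True
    leakage_quantile: float = DEFAULT_LEAK_QUANTILE
    bleb_quantile: float = DEFAULT_BLEB_QUANTILE
    bleb_area_max_um2: float = DEFAULT_AREA_MAX_UM2
    bleb_proximity_max_um: float = DEFAULT_PROXIMITY_MAX_UM
    min_area_um2: float = 0.5
    max_area_um2: float = 30.0
    seed: int = 0
    n_cells: int = 200

    def __post_init__(self):
        for name in (
            "pixel_size_um", "ring_window_um", "flank_um", "contour_spacing_um",
            "bleb_area_max_um2", "bleb_proximity_max_um", "min_area_um2",
            "max_area_um2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("leakage_quantile", "bleb_quantile"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {q}")
        for name in ("n_bins", "n_cols", "n_classes", "n_cells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(run_dir: Path, config: RunConfig, inputs: list[str],
                   extra: dict | None = None) -> Path:
    from . import __version__

    manifest = {
        "package": "rodmap",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "inputs": sorted(inputs),
    }
    if extra:
        manifest.update(extra)
    path = run_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


# ---------------------------------------------------------------------------
# scenes


def write_scene(scene: Scene, run_dir: str | Path) -> dict[str, Path]:
    """Write a scene as multi-page TIFF + ground-truth tables + channel list."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    names = list(scene.images)
    stack = np.stack([scene.images[name] for name in names])
    tiff_path = run_dir / "scene.tif"
    tifffile.imwrite(tiff_path, stack, photometric="minisblack",
                     metadata={"axes": "CYX"})
    channels_path = run_dir / "channels.txt"
    channels_path.write_text("\n".join(names) + "\n")
    paths = {"scene": tiff_path, "channels": channels_path}
    paths["truth_cells"] = run_dir / "truth_cells.tsv"
    scene.truth.cells.to_csv(paths["truth_cells"], sep="\t", index=False)
    paths["truth_blebs"] = run_dir / "truth_blebs.tsv"
    scene.truth.blebs.to_csv(paths["truth_blebs"], sep="\t", index=False)
    if scene.truth.labels is not None:
        paths["labels"] = run_dir / "labels.tif"
        tifffile.imwrite(paths["labels"], scene.truth.labels.astype(np.int32),
                         photometric="minisblack")
    return paths


def read_scene(run_dir: str | Path) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Read back a scene written by :func:`write_scene`."""
    run_dir = Path(run_dir)
    names = (run_dir / "channels.txt").read_text().split()
    stack = tifffile.imread(run_dir / "scene.tif")
    if stack.ndim == 2:
        stack = stack[None]
    images = {name: stack[i] for i, name in enumerate(names)}
    cells = pd.read_csv(run_dir / "truth_cells.tsv", sep="\t")
    blebs_path = run_dir / "truth_blebs.tsv"
    blebs = pd.read_csv(blebs_path, sep="\t") if blebs_path.exists() else pd.DataFrame()
    labels = None
    if (run_dir / "labels.tif").exists():
        labels = tifffile.imread(run_dir / "labels.tif")
    return images, GroundTruth(cells=cells, blebs=blebs, labels=labels)


# ---------------------------------------------------------------------------
# tables


def cells_table(cells) -> pd.DataFrame:
    rows = []
    for cell in cells:
        cy, cx = cell.centroid
        rows.append(
            {
                "cell_id": cell.cell_id,
                "length_um": cell.length_um,
                "area_um2": cell.area_um2,
                "centroid_row": cy,
                "centroid_col": cx,
            }
        )
    return pd.DataFrame(rows)


def profiles_table(profiles: list[AxialProfile]) -> pd.DataFrame:
    """Long-format table: cell_id, channel, bin, value."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": p.cell_id,
                    "channel": p.channel,
                    "bin": np.arange(p.n_bins),
                    "value": p.values,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["cell_id", "channel", "bin", "value"])
    return pd.concat(frames, ignore_index=True)


def traces_table(traces: list[ContourTrace]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": t.cell_id,
            "channel": t.channel,
            "n_samples": len(t.samples),
            "spacing_um": t.spacing_um,
            "median_value": t.median_value,
        }
        for t in traces
    ]
    return pd.DataFrame(rows)


def leakage_table(calls: list[LeakageCall]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in calls])


def blebs_table(calls: list[BlebCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "bleb_id": c.bleb_id,
                "y_um": c.centroid_um[0],
                "x_um": c.centroid_um[1],
                "area_um2": c.area_um2,
                "mean_brightness": c.mean_brightness,
                "distance_um": c.distance_to_nearest_cell_um,
                "cell_id": c.cell_id,
            }
        )
    return pd.DataFrame(rows)


def write_profile_map(pmap: ProfileMap, run_dir: str | Path, stem: str) -> dict[str, Path]:
    """Matrix as TSV plus a rendered raster for inspection."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    tsv = run_dir / f"{stem}.tsv"
    header = "\t".join(f"col{i}" for i in range(pmap.n_cols))
    body = pd.DataFrame(pmap.matrix)
    body.insert(0, "cell_id", pmap.cell_ids)
    body.insert(1, "length_um", pmap.lengths_um)
    body.insert(2, "age", pmap.ages)
    body.columns = ["cell_id", "length_um", "age"] + header.split("\t")
    body.to_csv(tsv, sep="\t", index=False)

    png = run_dir / f"{stem}.png"
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(pmap.matrix, aspect="auto", cmap="inferno", origin="upper",
              interpolation="nearest")
    ax.set_xlabel("normalized axial position")
    ax.set_ylabel("cells, ascending length (% cell cycle)")
    ax.set_title(pmap.channel)
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return {"tsv": tsv, "png": png}
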