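"""End-to-end orchestration: frames -> ROIs -> cells -> normalized patches
-> dataset -> training/evaluation -> predictions -> shape report.

Each stage is resumable: outputs are cached under the run directory, keyed
by a hash of the configuration, and reused when the hash matches.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn, dataset, evaluation, normalization, roi, separation, shapes, synthetic
from .synthetic import CLASS_NAMES, SceneConfig

logger = logging.getLogger(__name__)

#: Walker sharpness used on synthetic scenes. The classical beta=130 value
#: assumes natural-image contrast; the synthetic renderer's dark rims are
#: far steeper and a gentler coupling lets geometry dominate the cut.
SYNTHETIC_BETA = 5.0


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published values where one
    exists (tau=5.0, A_min=600, batch=20, weight decay=0.01, p=0.5, 78x78
    input, k=5, epochs=60)."""

    out_dir: str = "run"
    # synthetic generation (None -> read frames from frames_dir)
    scene: SceneConfig | None = None
    n_frames: int = 5
    frames_dir: str | None = None
    # ROI stage
    tau: float = 5.0
    block_size: int = 32
    stride: int = 16
    min_area: int = 600
    # separation
    beta: float = SYNTHETIC_BETA
    h_depth: float = 2.0
    # dataset / training
    scheme: str = "refined8"
    augment: bool = True
    kfold: int = 5
    train: bool = False
    network: cnn.NetworkSpec | None = None
    train_config: cnn.TrainConfig | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        # paths are excluded: the hash keys the science, not the filesystem
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("frames_dir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    counts: dict = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "counts": self.counts,
                "stages_completed": self.stages_completed,
                "outputs": self.outputs,
            },
            indent=2,
        )


@dataclass
class ExtractedCell:
    """A single cell traced through the pipeline."""

    cell_id: int
    frame_index: int
    roi_id: int
    roi_kind: str
    mask: np.ndarray  # cropped to bbox
    bbox: tuple[int, int, int, int]  # frame coords, inclusive
    patch: np.ndarray  # raw intensity crop
    net_input: np.ndarray | None = None
    true_class: str | None = None
    predicted_class: str | None = None


def extract_cells_from_frame(
    frame: np.ndarray,
    config: PipelineConfig,
    frame_index: int = 0,
    margin: int = 3,
) -> tuple[list[ExtractedCell], dict]:
    """ROI detection + separation for one grayscale frame.

    Returns the single-cell records and per-frame stage counts.
    """
    gray = roi.to_grayscale(frame)
    emap = roi.entropy_map(gray, config.block_size, config.stride)
    mask = roi.threshold_and_refine(emap, gray.shape, config.tau, config.min_area)
    regions = roi.extract_rois(
        mask, gray, min_area=config.min_area, h_depth=config.h_depth, beta=config.beta
    )
    counts = {"rois": len(regions), "single": 0, "touching": 0, "overlapped": 0}
    cells: list[ExtractedCell] = []
    h, w = gray.shape
    for region in regions:
        counts[region.kind] += 1
        if region.kind == "overlapped":
            continue
        r0, c0, r1, c1 = region.bbox
        if region.kind == "single":
            local_masks = [separation.CellMask(1, region.mask, (0, 0, r1 - r0, c1 - c0))]
        else:
            dmap = separation.distance_transform(np.pad(region.mask, 1))[1:-1, 1:-1]
            seeds = separation.generate_seeds(
                dmap, h_depth=config.h_depth, min_area=config.min_area
            )
            sub_img = gray[r0 : r1 + 1, c0 : c1 + 1]
            if len(seeds) > 1:
                _, lmap = separation.random_walk_segment(
                    sub_img, region.mask, seeds, beta=config.beta
                )
            else:
                lmap = np.where(region.mask, 1, 0)
            local_masks = separation.split_cells(
                lmap, region.mask, min_area=config.min_area, parent_roi=region.region_id
            )
        for cm in local_masks:
            mr0, mc0, mr1, mc1 = cm.bbox
            fr0, fc0 = r0 + mr0, c0 + mc0
            fr1, fc1 = r0 + mr1, c0 + mc1
            pr0, pc0 = max(fr0 - margin, 0), max(fc0 - margin, 0)
            pr1, pc1 = min(fr1 + margin, h - 1), min(fc1 + margin, w - 1)
            cells.append(
                ExtractedCell(
                    cell_id=len(cells) + 1,
                    frame_index=frame_index,
                    roi_id=region.region_id,
                    roi_kind=region.kind,
                    mask=cm.mask[mr0 : mr1 + 1, mc0 : mc1 + 1],
                    bbox=(fr0, fc0, fr1, fc1),
                    patch=gray[pr0 : pr1 + 1, pc0 : pc1 + 1].copy(),
                )
            )
    return cells, counts


def label_cells_from_truth(
    cells: list[ExtractedCell], truth: synthetic.GroundTruth
) -> None:
    """Assign each extracted cell the majority ground-truth class over its
    mask footprint (synthetic runs only)."""
    id_to_class = {c.cell_id: c.class_name for c in truth.cells}
    for cell in cells:
        r0, c0, r1, c1 = cell.bbox
        window = truth.label_image[r0 : r1 + 1, c0 : c1 + 1]
        ids = window[cell.mask]
        ids = ids[ids > 0]
        if ids.size:
            cell.true_class = id_to_class.get(int(np.bincount(ids).argmax()))


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline; every stage logs its counts and caches
    outputs in ``out_dir`` keyed by the config hash."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        cached = json.loads(manifest_path.read_text())
        if cached.get("config_hash") == chash:
            logger.info("run already complete for config %s; reusing", chash)
            m = RunManifest(chash, cached["version"], cached["counts"],
                            cached["stages_completed"], cached["outputs"])
            return m

    manifest = RunManifest(config_hash=chash, version=__version__)

    # stage 1: frames
    frames: list[np.ndarray] = []
    truths: list[synthetic.GroundTruth | None] = []
    if config.scene is not None:
        for i in range(config.n_frames):
            scfg = SceneConfig(**{**asdict(config.scene), "seed": config.scene.seed + i})
            frame, truth = synthetic.render_scene(scfg)
            frames.append(frame)
            truths.append(truth)
        manifest.counts["frames"] = len(frames)
    elif config.frames_dir is not None:
        frames = load_frames(config.frames_dir)
        truths = [None] * len(frames)
        manifest.counts["frames"] = len(frames)
    else:
        raise ValueError("config needs either a scene (synthetic) or frames_dir")
    manifest.stages_completed.append("frames")

    # stage 2+3: ROI extraction and separation
    all_cells: list[ExtractedCell] = []
    stage_counts = {"rois": 0, "single": 0, "touching": 0, "overlapped": 0}
    for i, frame in enumerate(frames):
        cells, counts = extract_cells_from_frame(frame, config, frame_index=i)
        if truths[i] is not None:
            label_cells_from_truth(cells, truths[i])
        for key in stage_counts:
            stage_counts[key] += counts[key]
        all_cells.extend(cells)
    manifest.counts.update(stage_counts)
    manifest.counts["cells"] = len(all_cells)
    manifest.stages_completed.append("extract")

    # stage 4: normalization
    bg_mask = normalization.select_background_mask(roi.to_grayscale(frames[0]))
    for cell in all_cells:
        norm = normalization.normalize_patch(cell.patch, bg_mask)
        cell.net_input = normalization.resize_for_net(norm)
    manifest.counts["patches"] = sum(1 for c in all_cells if c.net_input is not None)
    manifest.stages_completed.append("normalize")

    scheme = dataset.get_scheme(config.scheme)
    labeled = [c for c in all_cells if c.true_class is not None]

    # stage 5-6: dataset + training + prediction
    if config.train and labeled:
        ds = dataset.assemble(
            [c.net_input for c in labeled],
            [c.true_class for c in labeled],
            scheme,
            augment_data=config.augment,
        )
        manifest.counts["dataset_items"] = len(ds)
        spec = config.network or cnn.NetworkSpec(n_classes=scheme.n_classes())
        tcfg = config.train_config or cnn.TrainConfig(seed=config.seed)
        try:
            plan = dataset.kfold_split(ds, k=config.kfold, seed=config.seed)
            tr = plan.train_indices(0)
        except ValueError as exc:  # too few sources per class to hold a fold out
            logger.warning("k-fold split unavailable (%s); training on all items", exc)
            tr = np.arange(len(ds))
        params, history = cnn.train(ds.X[tr], ds.y[tr], spec, tcfg)
        cnn.save_checkpoint(out / "model.ckpt.npz", spec, params)
        manifest.outputs["model"] = str(out / "model.ckpt.npz")
        preds, probs = cnn.predict(
            spec, params, np.stack([c.net_input for c in all_cells])
        )
        for cell, p in zip(all_cells, preds):
            cell.predicted_class = scheme.classes[int(p)]
        manifest.counts["predictions"] = len(preds)
        manifest.stages_completed.append("train")

        hist_df = pd.DataFrame(
            {"epoch": range(1, len(history.loss) + 1),
             "loss": history.loss, "train_error": history.train_error}
        )
        hist_df.to_csv(out / "train_history.csv", index=False)

        dist = report_class_distribution(
            [c.predicted_class for c in all_cells],
            [c.frame_index for c in all_cells],
        )
        dist.to_csv(out / "class_distribution.csv")
        plot_class_distribution(dist, out / "class_distribution.png")
        manifest.outputs["class_distribution"] = str(out / "class_distribution.csv")
        manifest.stages_completed.append("predict")

    # stage 7: shape factors
    report = shapes.shape_report(
        [c.mask for c in all_cells],
        classes=[c.predicted_class or c.true_class or "unclassified" for c in all_cells],
        cell_ids=[c.cell_id for c in all_cells],
    )
    report.to_csv(out / "shape_factors.csv", index=False)
    manifest.outputs["shape_factors"] = str(out / "shape_factors.csv")
    manifest.stages_completed.append("shapes")

    manifest_path.write_text(manifest.to_json())
    return manifest


def report_class_distribution(predictions, groups=None) -> pd.DataFrame:
    """Histogram table: counts per class (per group when given)."""
    df = pd.DataFrame({"class": list(predictions)})
    if groups is not None:
        df["group"] = list(groups)
        table = df.groupby(["group", "class"]).size().unstack(fill_value=0)
    else:
        table = df.groupby("class").size().to_frame("count").T
    return table


def plot_class_distribution(table: pd.DataFrame, path: str | Path) -> None:
    """Bar-plot companion to the class-distribution CSV."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    table.sum(axis=0).plot.bar(ax=ax, color="#4878d0")
    ax.set_ylabel("cell count")
    ax.set_xlabel("predicted class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def load_frames(frames_dir: str | Path) -> list[np.ndarray]:
    """Read TIFF/PNG frames, sorted by name."""
    import imageio.v3 as iio
    import tifffile

    paths = sorted(
        p for p in Path(frames_dir).iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    frames = []
    for p in paths:
        if p.suffix.lower() in (".tif", ".tiff"):
            frames.append(tifffile.imread(p))
        else:
            frames.append(iio.imread(p))
    return frames
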