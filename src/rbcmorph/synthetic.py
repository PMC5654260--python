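"""Synthetic brightfield microscopy scenes with per-cell ground truth.

Renders frames that mimic the relevant statistics of brightfield RBC
imagery — bright, slowly varying background, dark-rimmed cell bodies of
eight morphology classes, touching (but not overlapping) cell clusters
and small debris artifacts — so that every downstream stage of the
pipeline can be exercised against known truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

#: Canonical base morphology classes, in the conventional table order.
CLASS_NAMES = (
    "discocyte",
    "echinocyte",
    "elongated",
    "granular",
    "oval",
    "reticulocyte",
    "sickle",
    "stomatocyte",
)

#: Short codes used in manifests and label tables.
CLASS_CODES = {
    "discocyte": "Dic",
    "echinocyte": "Ech",
    "elongated": "El",
    "granular": "Grl",
    "oval": "Ovl",
    "reticulocyte": "Ret",
    "sickle": "Sk",
    "stomatocyte": "Sto",
}

# Per-class diameter multiplier so that rasterized area stays above the
# debris prior (600 px) for crescents and high-aspect ellipses.
_SIZE_BOOST = {"sickle": 1.45, "elongated": 1.25}


@dataclass
class SceneConfig:
    """Parameters of one synthetic frame."""

    frame_width: int = 512
    frame_height: int = 512
    n_cells: int = 12
    class_mix: dict[str, float] | None = None
    touching_fraction: float = 0.0
    background_level: float = 190.0
    background_gradient: float = 10.0
    noise_sd: float = 3.0
    artifact_count: int = 0
    cell_diameter: float = 42.0
    min_cell_area: int = 620
    seed: int = 0

    def resolved_mix(self) -> np.ndarray:
        if self.class_mix is None:
            return np.full(len(CLASS_NAMES), 1.0 / len(CLASS_NAMES))
        probs = np.array([self.class_mix.get(c, 0.0) for c in CLASS_NAMES], float)
        total = probs.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")
        return probs

    def validate(self) -> None:
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level outside [0, 255]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        self.resolved_mix()


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    cell_id: int
    class_name: str
    center: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1) inclusive
    cluster_id: int
    area: int


@dataclass
class GroundTruth:
    """Per-frame ground truth: label image plus per-cell records."""

    label_image: np.ndarray
    cells: list[CellTruth] = field(default_factory=list)

    def mask_for(self, cell_id: int) -> np.ndarray:
        return self.label_image == cell_id

    def to_manifest(self) -> dict:
        return {
            "cells": [
                {
                    "id": c.cell_id,
                    "class": c.class_name,
                    "center": [float(c.center[0]), float(c.center[1])],
                    "bbox": list(map(int, c.bbox)),
                    "cluster_id": c.cluster_id,
                    "area": int(c.area),
                }
                for c in self.cells
            ]
        }


# ---------------------------------------------------------------------------
# single-cell geometry
# ---------------------------------------------------------------------------

def make_cell_mask(
    shape_class: str,
    size_px: float,
    orientation: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one cell of ``shape_class`` with characteristic diameter
    ``size_px`` rotated by ``orientation`` radians.

    Returns ``(mask, texture)`` where ``mask`` is a boolean array (single
    8-connected component) and ``texture`` holds signed grey-level offsets
    applied to the cell interior at render time.
    """
    if shape_class not in CLASS_NAMES:
        raise ValueError(
            f"unknown morphology class {shape_class!r}; expected one of {CLASS_NAMES}"
        )
    if size_px < 8:
        raise ValueError("size_px must be >= 8")

    r = size_px / 2.0
    half = int(math.ceil(size_px * 1.1)) + 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    # local frame: u along the major axis, v across it
    cos_t, sin_t = math.cos(orientation), math.sin(orientation)
    u = xx * cos_t + yy * sin_t
    v = -xx * sin_t + yy * cos_t
    rho = np.hypot(xx, yy)
    texture = np.zeros_like(u)

    if shape_class == "discocyte":
        mask = rho <= r
        texture = 22.0 * np.exp(-((rho / (0.36 * r)) ** 2))
    elif shape_class == "oval":
        q = rng.uniform(1.3, 1.8)
        a, b = r * math.sqrt(q), r / math.sqrt(q)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    elif shape_class == "elongated":
        q = rng.uniform(2.6, 3.2)
        a, b = r * math.sqrt(q), r / math.sqrt(q)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    elif shape_class == "sickle":
        # crescent: disc minus an offset disc
        cut_r = 0.85 * r
        cut_u, cut_v = 0.0, 0.62 * r
        outer = rho <= r
        inner = (u - cut_u) ** 2 + (v - cut_v) ** 2 <= cut_r**2
        mask = outer & ~inner
    elif shape_class == "echinocyte":
        k = int(rng.integers(9, 13))
        phase = rng.uniform(0, 2 * math.pi)
        theta = np.arctan2(v, u)
        mask = rho <= r * (1.0 + 0.13 * np.cos(k * theta + phase))
    elif shape_class == "granular":
        mask = rho <= r
        speckle = rng.normal(0.0, 22.0, size=u.shape)
        texture = ndimage.uniform_filter(speckle, size=2)
    elif shape_class == "reticulocyte":
        mask = rho <= r
        k1 = rng.uniform(0.55, 0.8)
        k2 = rng.uniform(0.55, 0.8)
        p1, p2 = rng.uniform(0, 2 * math.pi, size=2)
        strands = np.sin(k1 * u + p1) * np.sin(k2 * v + p2)
        texture = np.where(strands > 0.35, -28.0, 10.0)
    else:  # stomatocyte
        mask = rho <= r
        slit = (np.abs(v) < 0.18 * r) & (np.abs(u) < 0.6 * r)
        texture = np.where(slit, 24.0, 0.0)

    mask = _largest_component(mask)
    texture = np.where(mask, texture, 0.0)
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    return mask[r0 : r1 + 1, c0 : c1 + 1], texture[r0 : r1 + 1, c0 : c1 + 1]


_STRUCT8 = np.ones((3, 3), bool)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    if n <= 1:
        return mask.astype(bool)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _make_sized_cell(
    shape_class: str, diameter: float, min_area: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    size = diameter * _SIZE_BOOST.get(shape_class, 1.0)
    for _ in range(8):
        orientation = rng.uniform(0, math.pi)
        mask, tex = make_cell_mask(shape_class, size, orientation, rng)
        if mask.sum() >= min_area:
            return mask, tex
        size *= 1.15
    raise RuntimeError(f"could not rasterize {shape_class} above {min_area} px")


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def render_scene(config: SceneConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame. Deterministic in (config, config.seed).

    Returns the uint8 grayscale frame and its :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_height, config.frame_width

    # background: level + linear gradient + noise
    gdir = rng.uniform(0, 2 * math.pi)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    ramp = (xx / max(w - 1, 1) - 0.5) * math.cos(gdir) + (
        yy / max(h - 1, 1) - 0.5
    ) * math.sin(gdir)
    background = config.background_level + config.background_gradient * ramp

    label = np.zeros((h, w), np.int32)
    depth = np.zeros((h, w), float)  # grey levels subtracted from background
    texmap = np.zeros((h, w), float)

    mix = config.resolved_mix()
    classes = [
        CLASS_NAMES[i] for i in rng.choice(len(CLASS_NAMES), size=config.n_cells, p=mix)
    ]

    # cluster plan: touching cells grouped 2-4, rest singles
    n_touch = int(round(config.touching_fraction * config.n_cells))
    if n_touch == 1:
        n_touch = 2 if config.n_cells >= 2 else 0
    plan: list[int] = []
    remaining = n_touch
    while remaining >= 2:
        size = int(rng.integers(2, 5))
        size = min(size, remaining)
        if size < 2:
            break
        plan.append(size)
        remaining -= size
    plan.extend([1] * (config.n_cells - sum(plan)))

    truth = GroundTruth(label_image=label)
    margin = int(config.cell_diameter)
    if 2 * margin >= min(h, w):
        raise ValueError("frame too small for requested cell diameter")

    cell_id = 0
    cluster_id = 0
    for group_size in plan:
        cluster_id += 1
        placed: list[tuple[float, float, float]] = []  # (row, col, eff_radius)
        cluster_ids: list[int] = []
        for member in range(group_size):
            shape_class = classes[cell_id]
            ok = False
            for _ in range(200):
                mask, tex = _make_sized_cell(
                    shape_class, config.cell_diameter, config.min_cell_area, rng
                )
                mh, mw = mask.shape
                eff_r = math.sqrt(mask.sum() / math.pi)
                if member == 0:
                    cr = rng.uniform(margin, h - margin)
                    cc = rng.uniform(margin, w - margin)
                else:
                    anchor_i = int(rng.integers(0, len(placed)))
                    ar, ac, arad = placed[anchor_i]
                    ang = rng.uniform(0, 2 * math.pi)
                    d = rng.uniform(0.9, 0.98) * (arad + eff_r)
                    cr = ar + d * math.sin(ang)
                    cc = ac + d * math.cos(ang)
                    # keep clusters chain-like: non-anchor members must stay
                    # clearly apart so no deep central pocket forms
                    if any(
                        math.hypot(cr - pr, cc - pc) < 1.25 * (prad + eff_r)
                        for i, (pr, pc, prad) in enumerate(placed)
                        if i != anchor_i
                    ):
                        continue
                r0 = int(round(cr)) - mh // 2
                c0 = int(round(cc)) - mw // 2
                if r0 < 1 or c0 < 1 or r0 + mh > h - 1 or c0 + mw > w - 1:
                    continue
                window = label[r0 : r0 + mh, c0 : c0 + mw]
                free = mask & (window == 0)
                if free.sum() < 0.9 * mask.sum() or free.sum() < config.min_cell_area:
                    continue
                if member == 0 and group_size == 1:
                    # singles must not touch anything already placed
                    dil = ndimage.binary_dilation(
                        np.pad(mask, 3), _STRUCT8, iterations=3
                    )
                    wr0, wc0 = r0 - 3, c0 - 3
                    cr0, cc0 = max(wr0, 0), max(wc0, 0)
                    cr1 = min(r0 + mh + 3, h)
                    cc1 = min(c0 + mw + 3, w)
                    sub = label[cr0:cr1, cc0:cc1]
                    dsub = dil[
                        cr0 - wr0 : cr0 - wr0 + sub.shape[0],
                        cc0 - wc0 : cc0 - wc0 + sub.shape[1],
                    ]
                    if np.any(sub[dsub] != 0):
                        continue
                lab_free = _largest_component(free)
                if lab_free.sum() < config.min_cell_area:
                    continue
                if member > 0:
                    # cluster members must actually touch the cluster
                    ring = ndimage.binary_dilation(lab_free, _STRUCT8) & ~lab_free
                    if not np.any(np.isin(window[ring], cluster_ids)):
                        continue
                cell_id += 1
                cluster_ids.append(cell_id)
                window[lab_free] = cell_id
                edt = ndimage.distance_transform_edt(lab_free)
                rim = lab_free & (edt <= 2.5)
                dwin = depth[r0 : r0 + mh, c0 : c0 + mw]
                dwin[lab_free] = 32.0 + rng.uniform(-3, 3)
                dwin[rim] = 48.0 + rng.uniform(-5, 5)
                twin = texmap[r0 : r0 + mh, c0 : c0 + mw]
                # class texture plus baseline interior speckle; the latter
                # gives every cell enough grey-level diversity for the
                # entropy detector to fire at its published threshold
                speckle = rng.normal(0.0, 7.0, size=lab_free.shape)
                twin[lab_free] = tex[lab_free] + speckle[lab_free]
                rows = np.any(lab_free, axis=1)
                cols = np.any(lab_free, axis=0)
                br0, br1 = np.where(rows)[0][[0, -1]]
                bc0, bc1 = np.where(cols)[0][[0, -1]]
                com = ndimage.center_of_mass(lab_free)
                truth.cells.append(
                    CellTruth(
                        cell_id=cell_id,
                        class_name=shape_class,
                        center=(r0 + com[0], c0 + com[1]),
                        bbox=(r0 + br0, c0 + bc0, r0 + br1, c0 + bc1),
                        cluster_id=cluster_id,
                        area=int(lab_free.sum()),
                    )
                )
                placed.append((cr, cc, eff_r))
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place cell {cell_id + 1}/{config.n_cells}; "
                    "scene too dense"
                )

    # debris artifacts: small dark blobs below the area prior
    for _ in range(config.artifact_count):
        for _ in range(100):
            ar = rng.uniform(3.0, 6.0)
            cr = rng.uniform(10, h - 10)
            cc = rng.uniform(10, w - 10)
            rad = int(math.ceil(ar))
            r0, c0 = int(cr) - rad, int(cc) - rad
            sz = 2 * rad + 1
            if r0 < 0 or c0 < 0 or r0 + sz > h or c0 + sz > w:
                continue
            if np.any(label[r0 : r0 + sz, c0 : c0 + sz] != 0):
                continue
            gy, gx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
            blob = gy**2 + gx**2 <= ar**2
            depth[r0 : r0 + sz, c0 : c0 + sz][blob] = 55.0
            break

    frame = background - depth + texmap
    if config.noise_sd > 0:
        frame = frame + rng.normal(0.0, config.noise_sd, size=frame.shape)
    frame = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return frame, truth


def to_multichannel(frame: np.ndarray, channels: int = 4) -> np.ndarray:
    """Replicate a grayscale frame into an (H, W, C) image; channel 4 is a
    fully opaque alpha plane, mimicking 4-channel TIFF sources."""
    if channels not in (3, 4):
        raise ValueError("channels must be 3 or 4")
    planes = [frame] * 3
    if channels == 4:
        planes.append(np.full_like(frame, 255))
    return np.stack(planes, axis=-1)


# ---------------------------------------------------------------------------
# patch-level generation (classifier training material)
# ---------------------------------------------------------------------------

def render_patch(
    shape_class: str,
    rng: np.random.Generator,
    patch_size: int = 78,
    background_level: float | None = None,
    noise_sd: float = 3.0,
) -> np.ndarray:
    """Render a single centered cell on a uniform background patch.

    Produces uint8 patches directly at the classifier input scale; used for
    fast synthetic training datasets without full scene rendering.
    """
    if background_level is None:
        background_level = rng.uniform(175, 205)
    diameter = patch_size * rng.uniform(0.52, 0.62)
    size = diameter * _SIZE_BOOST.get(shape_class, 1.0)
    orientation = rng.uniform(0, math.pi)
    mask, tex = make_cell_mask(shape_class, size, orientation, rng)
    while max(mask.shape) > patch_size - 4:
        size *= 0.88
        mask, tex = make_cell_mask(shape_class, size, orientation, rng)
    mh, mw = mask.shape
    patch = np.full((patch_size, patch_size), background_level, float)
    r0 = (patch_size - mh) // 2
    c0 = (patch_size - mw) // 2
    edt = ndimage.distance_transform_edt(mask)
    rim = mask & (edt <= 2.5)
    win = patch[r0 : r0 + mh, c0 : c0 + mw]
    speckle = rng.normal(0.0, 7.0, size=mask.shape)
    win[mask] = background_level - 32.0 + tex[mask] + speckle[mask]
    win[rim] = background_level - 48.0
    patch += rng.normal(0.0, noise_sd, size=patch.shape)
    return np.clip(np.rint(patch), 0, 255).astype(np.uint8)


def make_patch_dataset(
    n_per_class: int | dict[str, int],
    classes: tuple[str, ...] = CLASS_NAMES,
    patch_size: int = 78,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build (patches, base-label indices, class list) for classifier tests."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for ci, cname in enumerate(classes):
        n = n_per_class if isinstance(n_per_class, int) else n_per_class[cname]
        for _ in range(n):
            xs.append(render_patch(cname, rng, patch_size=patch_size))
            ys.append(ci)
    return np.stack(xs), np.array(ys, np.int64), list(classes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_scene(
    out_dir: str | Path,
    name: str,
    frame: np.ndarray,
    truth: GroundTruth,
    fmt: str = "tiff",
    channels: int = 1,
) -> dict[str, str]:
    """Write frame, label image, and JSON manifest; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image = frame if channels == 1 else to_multichannel(frame, channels)
    if fmt == "tiff":
        frame_path = out / f"{name}.tif"
        tifffile.imwrite(frame_path, image)
    elif fmt == "png":
        frame_path = out / f"{name}.png"
        iio.imwrite(frame_path, image)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    label_path = out / f"{name}_labels.png"
    iio.imwrite(label_path, truth.label_image.astype(np.uint16))
    manifest_path = out / f"{name}_truth.json"
    manifest_path.write_text(json.dumps(truth.to_manifest(), indent=2))
    return {
        "frame": str(frame_path),
        "labels": str(label_path),
        "manifest": str(manifest_path),
    }
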