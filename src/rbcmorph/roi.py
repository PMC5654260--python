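"""Entropy-based ROI detection and per-region patch extraction.

Frames are scanned with an overlapping sliding window; the grey-level
entropy of each block separates textured cell regions from the smooth
background. Thresholded blocks are refined (hole filling, debris removal)
into an ROI mask whose connected components become single/touching/
overlapped-tagged regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import separation

#: Default entropy threshold (bits) for foreground blocks.
DEFAULT_TAU = 5.0
#: Default debris area prior in px^2 (6*10*10).
DEFAULT_MIN_AREA = 600

_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class EntropyMap:
    """Per-block entropies on a stride lattice with clamped edge windows."""

    values: np.ndarray  # (n_rows, n_cols) entropies
    row_origins: np.ndarray
    col_origins: np.ndarray
    block_size: int
    stride: int
    levels: int
    base: float


@dataclass
class ROIRegion:
    """One connected component of the refined ROI mask."""

    region_id: int
    mask: np.ndarray  # bool, cropped to bbox
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1) inclusive, frame coords
    kind: str  # "single" | "touching" | "overlapped"
    estimated_count: int


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse a 1-4 channel frame to single-channel uint8.

    Multichannel input is averaged over the first three channels (a fourth
    alpha-like channel is ignored) and rounded; single-channel input passes
    through unchanged.
    """
    if frame.ndim == 2:
        return frame
    if frame.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D frame, got shape {frame.shape}")
    n_ch = frame.shape[-1]
    if n_ch > 4:
        raise ValueError(f"expected at most 4 channels, got {n_ch}")
    if n_ch == 1:
        return frame[..., 0]
    used = frame[..., : min(n_ch, 3)].astype(np.float64)
    return np.rint(used.mean(axis=-1)).astype(frame.dtype)


def block_entropy(block: np.ndarray, levels: int = 256, base: float = 2.0) -> float:
    """Grey-level entropy of one block: E = -sum_i P_i log(P_i).

    P_i is the occurrence probability of level i within the block; levels
    that do not occur contribute nothing. With ``base=2`` the result is in
    bits, bounded by log2(levels).
    """
    block = np.asarray(block)
    if block.size == 0:
        raise ValueError("empty block")
    counts = np.bincount(block.ravel().astype(np.int64), minlength=levels)
    probs = counts[counts > 0] / block.size
    return float(-(probs * (np.log(probs) / np.log(base))).sum())


def entropy_map(
    image: np.ndarray,
    block_size: int = 32,
    stride: int = 16,
    levels: int = 256,
    base: float = 2.0,
) -> EntropyMap:
    """Sliding-window entropy over the frame, edge windows clamped.

    Every stride-lattice origin gets one entropy value; windows that would
    extend past the frame are clamped (not padded) so edge blocks use only
    real pixels.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    h, w = image.shape
    if block_size > min(h, w):
        raise ValueError("block_size exceeds frame dimensions")
    rows = np.arange(0, h, stride)
    cols = np.arange(0, w, stride)
    values = np.empty((rows.size, cols.size))
    for ri, r in enumerate(rows):
        for ci, c in enumerate(cols):
            block = image[r : min(r + block_size, h), c : min(c + block_size, w)]
            values[ri, ci] = block_entropy(block, levels=levels, base=base)
    return EntropyMap(values, rows, cols, block_size, stride, levels, base)


def threshold_and_refine(
    emap: EntropyMap,
    frame_shape: tuple[int, int],
    tau: float = DEFAULT_TAU,
    min_area: int = DEFAULT_MIN_AREA,
) -> np.ndarray:
    """Paint blocks with entropy >= tau, fill holes, drop small components.

    Returns the boolean ROI mask. Hole filling precedes the area prior so
    that debris attached to no cell is measured at its true size.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    h, w = frame_shape
    mask = np.zeros((h, w), bool)
    hot = np.argwhere(emap.values >= tau)
    n = emap.block_size
    for ri, ci in hot:
        r, c = emap.row_origins[ri], emap.col_origins[ci]
        mask[r : min(r + n, h), c : min(c + n, w)] = True
    mask = ndimage.binary_fill_holes(mask)
    lab, n_comp = ndimage.label(mask, structure=_STRUCT8)
    if n_comp:
        areas = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n_comp + 1))
        keep = np.concatenate(([False], areas >= min_area))
        mask = keep[lab]
    return mask


def cell_level_mask(
    image: np.ndarray,
    roi_mask: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    max_hole: int = 300,
) -> np.ndarray:
    """Refine the block-granular entropy mask to cell outlines.

    Cells are darker than the brightfield background, so an Otsu cut on the
    intensities inside the ROI mask separates cell bodies from the
    background padding introduced by whole-block painting. Only holes up to
    ``max_hole`` px are filled (pale cell centers), so background pockets
    enclosed by cell clusters are preserved; sub-prior debris is dropped.
    """
    from skimage.filters import threshold_otsu

    vals = image[roi_mask]
    if vals.size == 0:
        return np.zeros_like(roi_mask, bool)
    t = threshold_otsu(vals)
    binary = roi_mask & (image < t)
    binary = ndimage.binary_closing(binary, _STRUCT8)
    holes = ndimage.binary_fill_holes(binary) & ~binary
    hlab, hn = ndimage.label(holes)  # 4-connected background pockets
    if hn:
        hareas = ndimage.sum_labels(np.ones_like(hlab), hlab, np.arange(1, hn + 1))
        fill = np.concatenate(([False], hareas <= max_hole))
        binary |= fill[hlab]
    lab, n_comp = ndimage.label(binary, structure=_STRUCT8)
    if n_comp:
        areas = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n_comp + 1))
        keep = np.concatenate(([False], areas >= min_area))
        binary = keep[lab]
    return binary


def extract_rois(
    mask: np.ndarray,
    image: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    h_depth: float = 2.0,
    min_seed_dist: float | None = None,
    solidity_threshold: float = 0.75,
    beta: float = 130.0,
) -> list[ROIRegion]:
    """Split the refined mask into tagged cell-level regions.

    The entropy mask is first sharpened to cell outlines
    (:func:`cell_level_mask`); each connected component becomes a region.
    Cell count is estimated from distance-transform seed maxima. A region
    is ``single`` with exactly one seed; with two or more seeds it is
    ``touching`` when every random-walker split candidate is plausibly
    cell-shaped (solidity >= ``solidity_threshold``), otherwise
    ``overlapped`` (and downstream stages discard it).
    """
    refined = cell_level_mask(image, mask, min_area=min_area)
    lab, n_comp = ndimage.label(refined, structure=_STRUCT8)
    regions: list[ROIRegion] = []
    for rid in range(1, n_comp + 1):
        comp = lab == rid
        rows = np.any(comp, axis=1)
        cols = np.any(comp, axis=0)
        r0, r1 = np.where(rows)[0][[0, -1]]
        c0, c1 = np.where(cols)[0][[0, -1]]
        sub = comp[r0 : r1 + 1, c0 : c1 + 1]
        sub_img = image[r0 : r1 + 1, c0 : c1 + 1]
        dmap = separation.distance_transform(np.pad(sub, 1))[1:-1, 1:-1]
        seeds = separation.generate_seeds(
            dmap, h_depth=h_depth, min_seed_dist=min_seed_dist, min_area=min_area
        )
        k = len(seeds.points)
        if k <= 1:
            kind = "single"
        else:
            _, label_map = separation.random_walk_segment(sub_img, sub, seeds, beta=beta)
            cells = separation.split_cells(label_map, sub, min_area=min_area)
            k = len(cells)
            if k <= 1:
                kind = "single"
            elif all(_solidity(c.mask) >= solidity_threshold for c in cells):
                kind = "touching"
            else:
                kind = "overlapped"
        regions.append(
            ROIRegion(
                region_id=rid,
                mask=sub,
                bbox=(int(r0), int(c0), int(r1), int(c1)),
                kind=kind,
                estimated_count=k,
            )
        )
    return regions


def _solidity(mask: np.ndarray) -> float:
    from skimage.morphology import convex_hull_image

    hull = convex_hull_image(mask)
    hull_area = hull.sum()
    return float(mask.sum() / hull_area) if hull_area else 0.0
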