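"""Touching-cell separation: distance-transform seeding + seeded random walker.

The walker is solved directly on the 4-connected pixel lattice of the ROI
foreground: edge weights w_ij = exp(-beta (g_i - g_j)^2) on [0, 1]-scaled
intensities, and each unlabeled pixel receives the probability that a
random walk started there reaches each seed first (combinatorial Dirichlet
problem on the graph Laplacian).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from skimage.morphology import h_maxima

_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class SeedSet:
    """Seed pixels with labels 1..K."""

    points: list[tuple[int, int]]  # (row, col), label i+1 at index i

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CellMask:
    """One separated cell within a parent ROI."""

    label: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # inclusive, ROI-local coords
    parent_roi: int | None = None


def distance_transform(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to the nearest background pixel."""
    mask = np.asarray(mask, bool)
    if mask.all():
        raise ValueError("mask has no background pixels")
    return ndimage.distance_transform_edt(mask)


def generate_seeds(
    dmap: np.ndarray,
    h_depth: float = 2.0,
    min_seed_dist: float | None = None,
    min_area: int = 600,
) -> SeedSet:
    """Seeds = h-maxima of the distance map, merged when closer than
    ``min_seed_dist`` (default half the radius of the area-prior disc)."""
    if min_seed_dist is None:
        min_seed_dist = 0.5 * math.sqrt(min_area / math.pi)
    if dmap.max() <= 0:
        return SeedSet(points=[])
    peaks = h_maxima(dmap, h_depth)
    lab, n = ndimage.label(peaks, structure=_STRUCT8)
    if n == 0:  # flat plateau shallower than h: fall back to global max
        r, c = np.unravel_index(np.argmax(dmap), dmap.shape)
        return SeedSet(points=[(int(r), int(c))])
    centroids = ndimage.center_of_mass(peaks, lab, index=np.arange(1, n + 1))
    pts = [np.array(c) for c in centroids]
    # agglomerative merge of near-coincident maxima
    merged = True
    while merged and len(pts) > 1:
        merged = False
        best = (None, None, np.inf)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = float(np.hypot(*(pts[i] - pts[j])))
                if d < best[2]:
                    best = (i, j, d)
        if best[2] < min_seed_dist:
            i, j, _ = best
            pts[i] = (pts[i] + pts[j]) / 2.0
            del pts[j]
            merged = True
    out = []
    fg = dmap > 0
    for p in pts:
        r, c = int(round(p[0])), int(round(p[1]))
        if not fg[r, c]:  # merged centroid drifted off foreground: snap back
            rr, cc = np.nonzero(fg)
            k = np.argmin((rr - r) ** 2 + (cc - c) ** 2)
            r, c = int(rr[k]), int(cc[k])
        out.append((r, c))
    return SeedSet(points=out)


def random_walk_segment(
    image: np.ndarray,
    mask: np.ndarray,
    seeds: SeedSet,
    beta: float = 130.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random-walker probabilities and argmax label map on the ROI.

    Returns ``(probs, label_map)`` with ``probs`` of shape (K, H, W); the
    probability vector sums to 1 on every foreground pixel and label_map is
    0 on background, 1..K on foreground. Foreground components containing
    no seed are assigned to the nearest seed with a warning.
    """
    mask = np.asarray(mask, bool)
    k = len(seeds)
    if k == 0:
        raise ValueError("at least one seed required")
    h, w = mask.shape
    probs = np.zeros((k, h, w))
    if k == 1:
        probs[0][mask] = 1.0
        label_map = np.where(mask, 1, 0)
        return probs, label_map

    seed_rc = np.array(seeds.points)
    if not mask[seed_rc[:, 0], seed_rc[:, 1]].all():
        raise ValueError("all seeds must lie on foreground")

    # components without a seed -> nearest seed by Euclidean distance
    comp_lab, n_comp = ndimage.label(mask, structure=_STRUCT8)
    seeded_comps = set(comp_lab[seed_rc[:, 0], seed_rc[:, 1]])
    orphan = np.zeros((h, w), bool)
    if n_comp > len(seeded_comps & set(range(1, n_comp + 1))) or any(
        c not in seeded_comps for c in range(1, n_comp + 1)
    ):
        for c in range(1, n_comp + 1):
            if c not in seeded_comps:
                orphan |= comp_lab == c
    if orphan.any():
        warnings.warn(
            "foreground component without seed; assigned to nearest seed",
            stacklevel=2,
        )
        rr, cc = np.nonzero(orphan)
        d2 = (rr[:, None] - seed_rc[None, :, 0]) ** 2 + (
            cc[:, None] - seed_rc[None, :, 1]
        ) ** 2
        nearest = np.argmin(d2, axis=1)
        for lbl in range(k):
            sel = nearest == lbl
            probs[lbl, rr[sel], cc[sel]] = 1.0

    solve_mask = mask & ~orphan
    idx = -np.ones((h, w), np.int64)
    fr, fc = np.nonzero(solve_mask)
    n_nodes = fr.size
    idx[fr, fc] = np.arange(n_nodes)

    g = image.astype(np.float64)
    lo, hi = g[solve_mask].min(), g[solve_mask].max()
    g = (g - lo) / (hi - lo) if hi > lo else np.zeros_like(g)

    # 4-connected lattice edges within the foreground
    edges_i, edges_j, weights = [], [], []
    for dr, dc in ((0, 1), (1, 0)):
        a = solve_mask[: h - dr if dr else h, : w - dc if dc else w]
        b = solve_mask[dr:, dc:]
        both = a & b
        ar, ac = np.nonzero(both)
        i = idx[ar, ac]
        j = idx[ar + dr, ac + dc]
        wgt = np.exp(-beta * (g[ar, ac] - g[ar + dr, ac + dc]) ** 2)
        edges_i.append(i)
        edges_j.append(j)
        weights.append(np.maximum(wgt, 1e-6))
    ei = np.concatenate(edges_i)
    ej = np.concatenate(edges_j)
    ew = np.concatenate(weights)

    adj = sparse.coo_matrix(
        (np.concatenate([ew, ew]), (np.concatenate([ei, ej]), np.concatenate([ej, ei]))),
        shape=(n_nodes, n_nodes),
    ).tocsr()
    degree = np.asarray(adj.sum(axis=1)).ravel()
    laplacian = sparse.diags(degree) - adj

    seed_idx = idx[seed_rc[:, 0], seed_rc[:, 1]]
    is_seed = np.zeros(n_nodes, bool)
    is_seed[seed_idx] = True
    un = np.nonzero(~is_seed)[0]
    lap_uu = laplacian[un][:, un].tocsc()
    lap_us = laplacian[un][:, seed_idx].tocsr()

    node_probs = np.zeros((n_nodes, k))
    node_probs[seed_idx] = np.eye(k)
    if un.size:
        rhs = -lap_us.toarray()  # K columns, dense is fine at ROI scale
        sol = spsolve(lap_uu, rhs)
        if sol.ndim == 1:
            sol = sol[:, None]
        node_probs[un] = np.clip(np.asarray(sol), 0.0, 1.0)
        node_probs[un] /= node_probs[un].sum(axis=1, keepdims=True)

    for lbl in range(k):
        probs[lbl, fr, fc] = node_probs[:, lbl]

    label_map = np.zeros((h, w), np.int64)
    any_fg = mask
    stacked = probs[:, any_fg]
    label_map[any_fg] = np.argmax(stacked, axis=0) + 1
    return probs, label_map


def split_cells(
    label_map: np.ndarray,
    mask: np.ndarray,
    min_area: int = 600,
    parent_roi: int | None = None,
) -> list[CellMask]:
    """One mask per walker label; fragments below min_area/4 are merged into
    the neighboring label sharing the longest boundary. Masks partition the
    ROI foreground exactly."""
    mask = np.asarray(mask, bool)
    lm = np.where(mask, label_map, 0).astype(np.int64)
    labels = [int(l) for l in np.unique(lm) if l > 0]
    # degenerate-fragment rule
    changed = True
    while changed and len(labels) > 1:
        changed = False
        areas = {l: int((lm == l).sum()) for l in labels}
        small = [l for l in labels if areas[l] < min_area / 4]
        if not small:
            break
        l = min(small, key=lambda x: areas[x])
        frag = lm == l
        ring = ndimage.binary_dilation(frag, _STRUCT8) & ~frag & mask
        neighbor_labels = lm[ring]
        neighbor_labels = neighbor_labels[(neighbor_labels > 0) & (neighbor_labels != l)]
        if neighbor_labels.size:
            target = int(np.bincount(neighbor_labels).argmax())
            lm[frag] = target
            labels.remove(l)
            changed = True
        else:
            break
    cells = []
    for out_label, l in enumerate(sorted(labels), start=1):
        cm = lm == l
        rows = np.any(cm, axis=1)
        cols = np.any(cm, axis=0)
        r0, r1 = np.where(rows)[0][[0, -1]]
        c0, c1 = np.where(cols)[0][[0, -1]]
        cells.append(
            CellMask(
                label=out_label,
                mask=cm,
                bbox=(int(r0), int(c0), int(r1), int(c1)),
                parent_roi=parent_roi,
            )
        )
    return cells
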