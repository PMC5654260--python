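"""Contour-based shape-factor quantification for segmented cells.

Regional factors (area, perimeter, convex area/perimeter, Feret
diameters), moments-based ellipse fitting, and the derived dimensionless
factors (CSF, ESF, Elongation, Convexity, Compactness).

Measurement conventions, fixed so tolerances are meaningful:

* lengths are measured through boundary-pixel centers: the perimeter is
  the polygon length of the traced contour after a circular moving-average
  smoothing whose window scales with contour length (~1/30 of the boundary
  points). A raw sqrt(2)-weighted chain overestimates smooth contours by
  ~5% and is badly unstable under re-rasterization (rotation, 2x
  nearest-neighbor upscaling); the smoothed estimator keeps the
  digitized-circle bias under ~2% at cell scales and is scale/rotation
  stable to ~1%. Kulpa's corrected chain weights (0.948 axial, 1.343
  diagonal) remain as the fallback for very short contours;
* areas are measured in pixel extent, so the convex area uses the hull of
  pixel *corners* and always dominates the pixel-count area;
* Feret calipers rotate at 1 degree resolution over the corner hull.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

# Kulpa's corrected chain-code step weights (axial, diagonal)
CHAIN_WEIGHTS = (0.948, 1.343)

# Moore neighborhood in clockwise order starting East
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass
class EllipseFit:
    ra: float  # long semi-axis
    rb: float  # short semi-axis
    theta: float  # radians in (-pi/2, pi/2], from the column (x) axis

    def __post_init__(self):
        if not self.ra >= self.rb > 0:
            raise ValueError("requires Ra >= Rb > 0")


@dataclass
class RegionalFactors:
    area_r: float
    perm_r: float
    area_c: float
    perm_c: float
    max_fd: float
    min_fd: float


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed boundary (Moore-neighbor tracing, 8-connected).

    Returns an (n, 2) array of (row, col) boundary pixels; the first pixel
    is not repeated at the end.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (rows[0], cols[0])  # top-most then left-most foreground pixel

    if mask.sum() == 1:
        return np.array([[start[0] - 1, start[1] - 1]])

    contour = [start]
    # backtrack starts West of the start pixel
    prev = (start[0], start[1] - 1)
    current = start
    while True:
        base = _MOORE.index((prev[0] - current[0], prev[1] - current[1]))
        nxt = None
        for step in range(1, 9):
            d = _MOORE[(base + step) % 8]
            cand = (current[0] + d[0], current[1] + d[1])
            if padded[cand]:
                nxt = cand
                break
            prev = cand
        if nxt is None:
            break
        if nxt == start and len(contour) > 1:
            break
        contour.append(nxt)
        prev, current = current, nxt
    return np.array(contour) - 1


def chain_perimeter(contour: np.ndarray) -> float:
    """Closed-contour length from chain steps with corrected weights."""
    if len(contour) < 2:
        return CHAIN_WEIGHTS[0] * 4  # lone pixel: unit square convention
    steps = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    diagonal = np.all(np.abs(steps) == 1, axis=1)
    return float(
        CHAIN_WEIGHTS[0] * (~diagonal).sum() + CHAIN_WEIGHTS[1] * diagonal.sum()
    )


def contour_perimeter(contour: np.ndarray, window_divisor: int = 30) -> float:
    """Perimeter of the contour smoothed by a circular moving average.

    The window is ~1/``window_divisor`` of the contour length (odd, >= 3),
    so the relative smoothing — and hence the small negative length bias —
    is independent of image scale.
    """
    n = len(contour)
    window = max(3, 2 * int(n / window_divisor / 2) + 1)
    if n < window + 2:
        return chain_perimeter(contour)
    c = contour.astype(float)
    half = window // 2
    sm = sum(np.roll(c, k, axis=0) for k in range(-half, half + 1)) / window
    closed = np.vstack([sm, sm[:1]])
    return float(np.hypot(*np.diff(closed, axis=0).T).sum())


def _corner_points(mask: np.ndarray) -> np.ndarray:
    """Pixel-corner point cloud of the boundary (4 corners per pixel)."""
    contour = np.argwhere(mask)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (contour[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def _polygon_perimeter(points: np.ndarray) -> float:
    closed = np.vstack([points, points[:1]])
    return float(np.hypot(*np.diff(closed, axis=0).T).sum())


def regional_factors(mask: np.ndarray, feret_step_deg: float = 1.0) -> RegionalFactors:
    """Area, perimeter, convex hull quantities, and Feret diameters."""
    mask = np.asarray(mask, bool)
    area_r = int(mask.sum())
    if area_r < 5:
        raise ValueError("mask too small for shape analysis (< 5 px)")
    contour = trace_boundary(mask)
    perm_r = contour_perimeter(contour)

    corner_pts = _corner_points(mask)
    hull_ext = ConvexHull(corner_pts)
    area_c = float(hull_ext.volume)  # 2-D: volume is the polygon area

    center_hull = ConvexHull(contour) if len(contour) >= 3 else None
    if center_hull is not None:
        perm_c = _polygon_perimeter(contour[center_hull.vertices])
    else:
        perm_c = perm_r

    hull_pts = corner_pts[hull_ext.vertices]
    angles = np.deg2rad(np.arange(0.0, 180.0, feret_step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = hull_pts @ dirs.T  # (n_pts, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return RegionalFactors(
        area_r=float(area_r),
        perm_r=perm_r,
        area_c=area_c,
        perm_c=perm_c,
        max_fd=float(widths.max()),
        min_fd=float(widths.min()),
    )


def fit_ellipse(mask: np.ndarray) -> EllipseFit:
    """Ellipse with the same second central moments as the mask."""
    rr, cc = np.nonzero(np.asarray(mask, bool))
    if rr.size < 5:
        raise ValueError("mask too small for ellipse fitting")
    x = cc.astype(float)
    y = rr.astype(float)
    mu20 = x.var()
    mu02 = y.var()
    mu11 = ((x - x.mean()) * (y - y.mean())).mean()
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise ValueError("degenerate (collinear) mask")
    ra = 2.0 * np.sqrt(evals[1])
    rb = 2.0 * np.sqrt(evals[0])
    major = evecs[:, 1]  # (x, y) components
    theta = float(np.arctan2(major[1], major[0]))
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return EllipseFit(ra=float(ra), rb=float(rb), theta=theta)


@dataclass
class DerivedFactors:
    esf: float
    csf: float
    elongation: float
    conv: float
    compt: float


def derived_factors(regional: RegionalFactors, ellipse: EllipseFit) -> DerivedFactors:
    """Dimensionless factors, all normalized to 1 at the circular limit
    (except Elongation, which is 0 for a circle)."""
    if regional.perm_r <= 0 or ellipse.ra <= 0 or regional.max_fd <= 0:
        raise ValueError("zero denominator in derived factors")
    return DerivedFactors(
        esf=ellipse.rb / ellipse.ra,
        csf=4.0 * np.pi * regional.area_r / regional.perm_r**2,
        elongation=1.0 - ellipse.rb / ellipse.ra,
        conv=regional.perm_c / regional.perm_r,
        compt=np.sqrt(4.0 * regional.area_r / np.pi) / regional.max_fd,
    )


FACTOR_COLUMNS = [
    "area_r", "perm_r", "area_c", "perm_c", "max_fd", "min_fd",
    "ra", "rb", "theta", "esf", "csf", "elongation", "conv", "compt",
]


def shape_record(mask: np.ndarray) -> dict[str, float]:
    """All 14 shape quantities for one mask."""
    reg = regional_factors(mask)
    ell = fit_ellipse(mask)
    der = derived_factors(reg, ell)
    return {
        "area_r": reg.area_r, "perm_r": reg.perm_r,
        "area_c": reg.area_c, "perm_c": reg.perm_c,
        "max_fd": reg.max_fd, "min_fd": reg.min_fd,
        "ra": ell.ra, "rb": ell.rb, "theta": ell.theta,
        "esf": der.esf, "csf": der.csf, "elongation": der.elongation,
        "conv": der.conv, "compt": der.compt,
    }


def shape_report(masks, classes=None, cell_ids=None) -> pd.DataFrame:
    """Per-cell table of all shape factors, optionally grouped by class."""
    rows = []
    for i, mask in enumerate(masks):
        rec = shape_record(mask)
        rec["cell_id"] = cell_ids[i] if cell_ids is not None else i
        rec["class"] = classes[i] if classes is not None else "unclassified"
        rows.append(rec)
    return pd.DataFrame(rows, columns=["cell_id", "class"] + FACTOR_COLUMNS)


def class_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean/sd of every factor column."""
    return report.groupby("class")[FACTOR_COLUMNS].agg(["mean", "std"])
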