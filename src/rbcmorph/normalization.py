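"""Size-invariant patch normalization by corner-median intensity mapping.

A 100x100 pure-background mask is cropped from a frame once; every
variable-size single-cell patch is pasted at its center after the mask has
been shifted by the background intensity difference dM = median(patch
corners) - median(mask corners). Cell pixels are therefore carried over
untouched (no rescaling, no histogram surgery) and the net input is a
bilinear 78x78 resize of the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .roi import block_entropy

MASK_SIZE = 100
NET_SIZE = 78
_OVERSIZE_TARGET = 96


@dataclass
class NormalizedPatch:
    """100x100 normalized patch plus paste bookkeeping."""

    pixels: np.ndarray
    paste_offset: tuple[int, int]  # (row, col) of pasted patch origin
    paste_shape: tuple[int, int]
    delta_m: float


def median(values) -> float:
    """Median by the sort-and-index rule: middle element when the count is
    odd, mean of the two middle elements when even."""
    seq = sorted(float(v) for v in np.asarray(values, float).ravel())
    n = len(seq)
    if n == 0:
        raise ValueError("median of empty sequence")
    if n % 2 == 1:
        return seq[n // 2]
    return 0.5 * (seq[n // 2 - 1] + seq[n // 2])


def corner_samples(image: np.ndarray, extent: int = 3) -> np.ndarray:
    """Mean intensity of an extent x extent window at each of the 4 corners
    (windowed rather than single-pixel to resist shot noise)."""
    img = np.asarray(image, float)
    e = min(extent, img.shape[0], img.shape[1])
    return np.array(
        [
            img[:e, :e].mean(),
            img[:e, -e:].mean(),
            img[-e:, :e].mean(),
            img[-e:, -e:].mean(),
        ]
    )


def estimate_delta(patch_corners, mask_corners) -> float:
    """Signed background difference dM = median(G_k) - median(B)."""
    g = np.asarray(patch_corners, float)
    b = np.asarray(mask_corners, float)
    if g.size != 4 or b.size != 4:
        raise ValueError("corner sequences must have exactly 4 samples")
    return median(g) - median(b)


def adapt_mask(mask: np.ndarray, delta_m: float) -> np.ndarray:
    """Linear intensity mapping: shift every mask pixel by dM, clip to
    [0, 255]."""
    return np.clip(np.rint(mask.astype(float) + delta_m), 0, 255).astype(np.uint8)


def select_background_mask(
    frame: np.ndarray, size: int = MASK_SIZE, stride: int = 25
) -> np.ndarray:
    """Automatic normalization-mask selection: the size x size window with
    minimal grey-level entropy (pure background is maximally uniform)."""
    h, w = frame.shape
    if h < size or w < size:
        raise ValueError("frame smaller than requested mask")
    best = None
    best_e = np.inf
    for r in range(0, h - size + 1, stride):
        for c in range(0, w - size + 1, stride):
            e = block_entropy(frame[r : r + size, c : c + size])
            if e < best_e:
                best_e = e
                best = (r, c)
    r, c = best
    return frame[r : r + size, c : c + size].copy()


def compose(
    patch: np.ndarray,
    adapted_mask: np.ndarray,
    cell_mask: np.ndarray | None = None,
    delta_m: float = 0.0,
) -> NormalizedPatch:
    """Paste the (full rectangular) patch at the center of the adapted mask.

    Cell-pixel intensities are preserved exactly. Patches exceeding the
    mask are isotropically downscaled to fit 96x96 first (with a warning);
    this loses exact intensity preservation but keeps elongated cells whole.
    """
    out = adapted_mask.copy()
    size = out.shape[0]
    ph, pw = patch.shape
    if ph > size or pw > size:
        warnings.warn(
            f"patch {patch.shape} exceeds {size}x{size}; downscaling to fit "
            f"{_OVERSIZE_TARGET}px",
            stacklevel=2,
        )
        scale = _OVERSIZE_TARGET / max(ph, pw)
        new_shape = (max(int(round(ph * scale)), 1), max(int(round(pw * scale)), 1))
        patch = np.rint(
            resize(patch.astype(float), new_shape, order=1, preserve_range=True,
                   anti_aliasing=True)
        ).astype(out.dtype)
        ph, pw = patch.shape
    r0 = (size - ph) // 2
    c0 = (size - pw) // 2
    out[r0 : r0 + ph, c0 : c0 + pw] = patch
    return NormalizedPatch(
        pixels=out, paste_offset=(r0, c0), paste_shape=(ph, pw), delta_m=delta_m
    )


def normalize_patch(
    patch: np.ndarray,
    background_mask: np.ndarray,
    cell_mask: np.ndarray | None = None,
) -> NormalizedPatch:
    """Full normalization: corner sampling, dM estimation, mask adaptation,
    centered composition."""
    delta = estimate_delta(corner_samples(patch), corner_samples(background_mask))
    adapted = adapt_mask(background_mask, delta)
    return compose(patch, adapted, cell_mask=cell_mask, delta_m=delta)


def resize_for_net(normalized: NormalizedPatch | np.ndarray) -> np.ndarray:
    """Bilinear 100x100 -> 78x78 resize; float32 on the 0-255 scale."""
    pixels = normalized.pixels if isinstance(normalized, NormalizedPatch) else normalized
    if pixels.shape != (MASK_SIZE, MASK_SIZE):
        raise ValueError(f"expected {MASK_SIZE}x{MASK_SIZE} input, got {pixels.shape}")
    out = resize(
        pixels.astype(np.float64),
        (NET_SIZE, NET_SIZE),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    return out.astype(np.float32)
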