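"""Silhouette extraction: raw seed images to clean binary masks.

Seed views show a bright seed against a dark background with the suction
nozzle entering from one image edge.  The stages are bimodal thresholding,
nozzle removal (the horizontal row at which the per-row foreground pixel
count jumps marks the nozzle/seed intersection), and morphological cleanup
to a single solid component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogram, EmptyMask, NoIntersectionWarning

__all__ = [
    "SilhouetteMask",
    "binarize",
    "clean_mask",
    "remove_nozzle",
    "silhouette_contour",
    "extract_silhouettes",
]


@dataclass
class SilhouetteMask:
    """A cleaned binary silhouette for one view."""

    mask: np.ndarray  # bool, foreground = seed
    view_index: int = 0
    nozzle_boundary_row: int | None = None
    no_intersection: bool = False  # nozzle removal found no row change


def binarize(image: np.ndarray, threshold: float | str = "auto") -> np.ndarray:
    """Threshold a grayscale image to a boolean foreground mask.

    ``"auto"`` uses Otsu's bimodal-histogram threshold.  Polarity is chosen
    so the smaller-area class is foreground (the seed occupies a minority of
    the frame); an explicit numeric threshold marks pixels above it.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("image is empty")
    if threshold == "auto":
        if np.ptp(img) < 1e-12:
            raise DegenerateHistogram("constant image has no bimodal histogram")
        thr = threshold_otsu(img)
        above = img > thr
        return above if above.sum() <= above.size / 2 else ~above
    return img > float(threshold)


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Fill holes and keep only the largest connected component."""
    m = ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))
    labels, n = ndimage.label(m)
    if n <= 1:
        return m
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _detect_intersection_row(
    mask: np.ndarray, change_fraction: float, min_stable_rows: int = 3
) -> int | None:
    """First row (scanning from the top) where the white-pixel count jumps.

    The nozzle has near-constant width, so the nozzle/seed intersection is
    the first row whose count grows by at least ``change_fraction`` relative
    to the previous row *after* a run of ``min_stable_rows`` near-constant
    rows (the nozzle shaft).  The stability requirement keeps the detector
    from firing on the naturally steep width growth at a bare seed apex.
    """
    counts = mask.sum(axis=1)
    nz = np.flatnonzero(counts)
    if len(nz) < 2:
        return None
    stable = 0
    for r in range(nz[0] + 1, nz[-1] + 1):
        prev = counts[r - 1]
        cur = counts[r]
        if prev == 0:
            stable = 0
            continue
        if cur >= prev * (1.0 + change_fraction):
            if stable >= min_stable_rows:
                return int(r)
            stable = 0
        elif abs(int(cur) - int(prev)) <= 0.5 * change_fraction * prev:
            stable += 1
        else:
            stable = 0
    return None


def remove_nozzle(
    masks: list[np.ndarray] | list[SilhouetteMask],
    change_fraction: float = 0.30,
    cross_view_consensus: bool = False,
) -> list[SilhouetteMask]:
    """Clear the suction nozzle (entering from the top edge) from each view.

    Rows above the detected intersection row are cleared and the largest
    remaining component is kept.  If no row's white-pixel count changes by at
    least ``change_fraction``, the mask is returned unchanged with the
    ``no_intersection`` flag set (and a :class:`NoIntersectionWarning`).

    ``cross_view_consensus`` replaces each per-view row with the median
    detected row over all views, which is robust when single views fail.
    """
    raw = [m.mask if isinstance(m, SilhouetteMask) else np.asarray(m, bool) for m in masks]
    rows = [_detect_intersection_row(m, change_fraction) for m in raw]
    if cross_view_consensus:
        found = [r for r in rows if r is not None]
        consensus = int(np.median(found)) if found else None
        rows = [consensus] * len(raw)
    out = []
    for i, (m, r) in enumerate(zip(raw, rows)):
        if r is None:
            warnings.warn(
                f"view {i}: no nozzle/seed intersection row found",
                NoIntersectionWarning,
                stacklevel=2,
            )
            out.append(
                SilhouetteMask(mask=m.copy(), view_index=i, no_intersection=True)
            )
            continue
        cleared = m.copy()
        cleared[:r] = False
        out.append(
            SilhouetteMask(mask=clean_mask(cleared), view_index=i, nozzle_boundary_row=r)
        )
    return out


def silhouette_contour(mask: np.ndarray) -> np.ndarray:
    """Closed outer boundary polygon of the largest foreground component.

    Returns (N, 2) vertices in (x, y) pixel coordinates, counter-clockwise
    (in image axes), subpixel-traced.  Large components are traced on a
    lightly smoothed field to suppress pixel-staircase bias in perimeter
    estimates; tiny components fall back to the raw marching-squares trace.
    """
    m = clean_mask(mask)
    if not m.any():
        raise EmptyMask("mask has no foreground")
    area = int(m.sum())
    pad = np.pad(m.astype(float), 2)
    if area >= 16:
        field = ndimage.gaussian_filter(pad, 1.0)
        if field.max() <= 0.5:
            field = pad
    else:
        field = pad
    contours = measure.find_contours(field, 0.5)
    if not contours:
        raise EmptyMask("no contour found")
    poly = max(contours, key=len)
    # find_contours yields (row, col); convert to (x, y) and undo padding
    poly = poly[:, ::-1] - 2.0
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    # enforce counter-clockwise orientation (positive shoelace area in image axes)
    x, y = poly[:, 0], poly[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        poly = poly[::-1]
    return poly


def extract_silhouettes(
    images: list[np.ndarray],
    threshold: float | str = "auto",
    change_fraction: float = 0.30,
    nozzle: bool = True,
    cross_view_consensus: bool = False,
) -> list[SilhouetteMask]:
    """Full silhouette pipeline: binarize, clean, remove the nozzle."""
    masks = [clean_mask(binarize(img, threshold)) for img in images]
    if nozzle:
        return remove_nozzle(masks, change_fraction, cross_view_consensus)
    return [SilhouetteMask(mask=m, view_index=i) for i, m in enumerate(masks)]
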