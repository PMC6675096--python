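"""Nuclei, cell-body and spot segmentation for three-channel field images.

The chain is the standard high-content one: nuclei are detected on the
nuclear stain by smoothing, global Otsu thresholding and a distance-transform
watershed to split touching objects; cells are grown from the nuclei seeds by
a marker-controlled watershed over the (inverted, smoothed) cell-body
intensity restricted to its foreground mask; punctate payload signal is then
thresholded *per cell* with Otsu's method so that each cell's spot mask is
independent of every other cell's intensity scale.

Conventions: thresholded foreground components use 4-connectivity; watershed
regions are connected under 8-connectivity. Label images use 0 for
background and contiguous IDs 1..N. A cell's label always equals the label
of the nucleus that seeded it.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import relabel_sequential, watershed

from .errors import InputError

logger = logging.getLogger(__name__)


def _smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if sigma > 0:
        img = gaussian(img, sigma=sigma, preserve_range=True)
    return img


def _otsu_foreground(img: np.ndarray) -> np.ndarray:
    """Global Otsu foreground; all-background for (near-)constant images."""
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    return img > threshold_otsu(img, nbins=256)


def segment_nuclei(
    nuclear_img: np.ndarray,
    smooth_sigma: float = 2.0,
    min_area: int = 40,
    max_area: int = 100_000,
    h_minima_depth: float = 2.0,
) -> np.ndarray:
    """Segment nuclei on the nuclear channel.

    Pipeline: Gaussian smoothing (``smooth_sigma`` px) -> global Otsu
    threshold -> hole filling -> distance-transform watershed with shallow
    maxima suppressed at depth ``h_minima_depth`` (px) to split touching
    nuclei -> area filter [min_area, max_area] px^2 -> contiguous relabel.
    A blank image yields zero objects rather than an error.
    """
    img = np.asarray(nuclear_img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InputError(f"expected a non-empty 2D image, got shape {img.shape}")
    fg = _otsu_foreground(_smooth(img, smooth_sigma))
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(fg)
    peaks = h_maxima(dist, h_minima_depth)
    markers = cc_label(peaks, connectivity=1)
    if markers.max() == 0:  # single shallow object: keep it whole
        markers = cc_label(fg, connectivity=1)
    labels = watershed(-dist, markers=markers, mask=fg, connectivity=2)

    # area filter and contiguous relabel
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[(counts >= min_area) & (counts <= max_area)]
    filtered = np.where(np.isin(labels, keep), labels, 0)
    relabeled, _, _ = relabel_sequential(filtered)
    return relabeled.astype(np.int32)


def segment_cells(
    body_img: np.ndarray,
    nuclei: np.ndarray,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Grow cell regions from nuclei seeds over the cell-body channel.

    Marker-controlled watershed on the inverted smoothed body intensity,
    restricted to the union of the body-channel Otsu foreground and the
    nuclei (so every seed lies inside the mask). Cell label i therefore
    contains nucleus label i entirely, and the cells partition the seeded
    foreground. Empty nuclei produce empty cell labels with a warning.
    """
    body_img = np.asarray(body_img, dtype=float)
    nuclei = np.asarray(nuclei)
    if body_img.shape != nuclei.shape:
        raise InputError(
            f"body image {body_img.shape} and nuclei {nuclei.shape} shapes differ"
        )
    if nuclei.max() == 0:
        logger.warning("no nuclei seeds: returning empty cell labels")
        return np.zeros(body_img.shape, dtype=np.int32)
    sm = _smooth(body_img, smooth_sigma)
    fg = _otsu_foreground(sm) | (nuclei > 0)
    cells = watershed(-sm, markers=nuclei.astype(np.int32), mask=fg, connectivity=2)
    return cells.astype(np.int32)


def otsu_threshold_values(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of a 1D sample of intensities (``nbins``-bin histogram)."""
    return float(threshold_otsu(values.ravel(), nbins=nbins))


def spot_mask_per_cell(
    payload_img: np.ndarray,
    cells: np.ndarray,
    min_cell_pixels: int = 8,
) -> np.ndarray:
    """Threshold the payload channel independently within each cell.

    For each cell an Otsu threshold is computed over that cell's own pixel
    intensities (256-bin histogram spanning the cell's intensity range) and
    the spot mask keeps pixels strictly above it. Degenerate cells —
    constant intensity or fewer than ``min_cell_pixels`` pixels — get an
    empty mask: with no evidence of signal, no spots are fabricated. The
    returned mask is a subset of the union of cell regions by construction.
    """
    payload_img = np.asarray(payload_img, dtype=float)
    cells = np.asarray(cells)
    if payload_img.shape != cells.shape:
        raise InputError(
            f"payload image {payload_img.shape} and cells {cells.shape} shapes differ"
        )
    mask = np.zeros(payload_img.shape, dtype=bool)
    for sl, cell_id in _iter_objects(cells):
        in_cell = cells[sl] == cell_id
        vals = payload_img[sl][in_cell]
        if vals.size < min_cell_pixels or np.ptp(vals) == 0:
            continue
        thr = otsu_threshold_values(vals)
        local = np.zeros_like(in_cell)
        local[in_cell] = vals > thr
        mask[sl] |= local
    return mask


def _iter_objects(labels: np.ndarray):
    """Yield (bounding-box slice, id) per labeled object, in id order."""
    for cell_id, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is not None:
            yield sl, cell_id


def on_border_ids(labels: np.ndarray) -> set[int]:
    """IDs of objects touching the image border."""
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return set(np.unique(edge[edge > 0]).tolist())
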