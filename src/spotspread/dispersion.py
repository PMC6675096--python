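"""Per-cell spot dispersion: the core transport measurement.

For each segmented cell the payload spot mask is reduced to a single
dimensionless number::

    dispersion = mean_i ||x_i - c|| / D

where ``x_i`` are the pixel centers of the cell's spot mask, ``c`` is the
unweighted centroid of those pixels, and ``D`` is the cell diameter — the
maximum Euclidean distance between any two pixel centers of the cell.
A value of 0 means all payload is aggregated at a single focus (which may be
anywhere in the cell, not necessarily the cell centroid or nucleus); values
approach 1 as the signal spreads toward opposite extremes of the cell.
Because the focus is estimated from the mask itself, the statistic is
sensitive to aggregation toward unmarked subcellular compartments, where
centroid- or membrane-referenced measures are not.

A membrane-band comparator is also provided: the cell is divided into
``n_bands`` concentric equal-width bands of distance-from-boundary and the
spot-pixel-weighted mean band index is reported, 1 = deepest interior,
``n_bands`` = membrane-adjacent (the construction used by generic
high-content pipelines such as CellProfiler's radial bands).

Cells with an empty spot mask carry *undefined* (NaN) dispersion — never 0 —
and are excluded from aggregation downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import DataIntegrityError, InputError
from .io_plate import MeasurementTable
from .segmentation import _iter_objects, on_border_ids

__all__ = [
    "spot_centroid",
    "cell_diameter",
    "dispersion_cell",
    "band_dispersion_cell",
    "measure_dispersion",
]


def spot_centroid(spot_pixels: np.ndarray) -> tuple[float, float]:
    """Unweighted centroid (row, col) of a set of pixel centers.

    Raises :class:`InputError` on an empty set; callers record the cell's
    dispersion as undefined instead of calling with no pixels.
    """
    pts = np.atleast_2d(np.asarray(spot_pixels, dtype=float))
    if pts.size == 0:
        raise InputError("centroid of an empty pixel set is undefined")
    mean = pts.mean(axis=0)
    return (float(mean[0]), float(mean[1]))


def cell_diameter(cell_pixels: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance between pixel centers, exact.

    The point set is reduced to its convex hull (the maximum is attained
    between hull vertices) and the maximum is taken over all hull-vertex
    pairs; for degenerate (e.g. collinear) sets where hull construction
    fails, the full pairwise maximum is used. Returns NaN for fewer than
    two pixels.
    """
    pts = np.atleast_2d(np.asarray(cell_pixels, dtype=float))
    if len(pts) < 2:
        return float("nan")
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear/degenerate: brute force below is exact anyway
    return float(pdist(pts).max())


def dispersion_cell(cell_pixels: np.ndarray, spot_pixels: np.ndarray) -> float:
    """Dispersion of one cell: mean spot-to-centroid distance over diameter.

    ``spot_pixels`` must be a subset of ``cell_pixels`` (a spot pixel outside
    its cell indicates corrupted segmentation and raises
    :class:`DataIntegrityError`). Returns NaN when the spot mask is empty or
    the cell diameter is undefined or zero; a single-pixel mask gives exactly
    0. Defined values always lie in [0, 1], since no point of the cell is
    farther from the (interior) centroid than the diameter.
    """
    cell_pts = np.atleast_2d(np.asarray(cell_pixels, dtype=float))
    spot_pts = np.atleast_2d(np.asarray(spot_pixels, dtype=float))
    if spot_pts.size == 0:
        return float("nan")
    cell_set = {tuple(p) for p in cell_pts.tolist()}
    outside = [tuple(p) for p in spot_pts.tolist() if tuple(p) not in cell_set]
    if outside:
        raise DataIntegrityError(
            f"{len(outside)} spot pixel(s) outside the cell, e.g. {outside[0]}"
        )
    diam = cell_diameter(cell_pts)
    if not np.isfinite(diam) or diam <= 0:
        return float("nan")
    centroid = np.asarray(spot_centroid(spot_pts))
    dists = np.linalg.norm(spot_pts - centroid, axis=1)
    return float(dists.mean() / diam)


def band_dispersion_cell(
    cell_pixels: np.ndarray,
    spot_pixels: np.ndarray,
    n_bands: int = 4,
) -> float:
    """Membrane-band comparator: spot-weighted mean band index in [1, n_bands].

    The cell's Euclidean distance transform (distance of each cell pixel to
    the nearest non-cell pixel) is split into ``n_bands`` equal-width bands;
    band ``n_bands`` hugs the membrane, band 1 is the deepest interior. The
    value is the mean band index over spot pixels, so it is bounded in
    [1, n_bands] by construction. NaN when the spot mask is empty.
    """
    if n_bands < 1:
        raise InputError("n_bands must be >= 1")
    cell_pts = np.atleast_2d(np.asarray(cell_pixels, dtype=int))
    spot_pts = np.atleast_2d(np.asarray(spot_pixels, dtype=int))
    if spot_pts.size == 0:
        return float("nan")

    # rebuild the cell mask in a padded bounding box for the EDT
    rmin, cmin = cell_pts.min(axis=0)
    rmax, cmax = cell_pts.max(axis=0)
    mask = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=bool)
    mask[cell_pts[:, 0] - rmin + 1, cell_pts[:, 1] - cmin + 1] = True
    dist = ndi.distance_transform_edt(mask)
    dmax = dist[mask].max()

    depth = dist[spot_pts[:, 0] - rmin + 1, spot_pts[:, 1] - cmin + 1]
    if np.any(depth <= 0):
        raise DataIntegrityError("spot pixel outside the cell")
    # normalized depth in (0, 1]; band n_bands nearest the membrane
    frac = depth / dmax
    band = n_bands - np.minimum(np.floor(frac * n_bands), n_bands - 1)
    return float(band.mean())


def measure_dispersion(
    cells: np.ndarray,
    spots: np.ndarray,
    min_spot_px: int = 1,
    n_bands: int = 4,
) -> MeasurementTable:
    """Per-cell dispersion measurements for a segmented field.

    Produces one record per cell ID (in ID order) with spot-pixel count,
    spot centroid, cell diameter, dispersion, membrane-band dispersion and
    an ``on_border`` flag. Cells whose mask has fewer than ``min_spot_px``
    pixels carry undefined (NaN) dispersion, never 0.
    """
    cells = np.asarray(cells)
    spots = np.asarray(spots, dtype=bool)
    if cells.shape != spots.shape:
        raise InputError(f"cells {cells.shape} and spots {spots.shape} shapes differ")
    if np.any(spots & (cells == 0)):
        raise DataIntegrityError("spot mask has pixels outside every cell")
    border = on_border_ids(cells)

    records = []
    for sl, cell_id in _iter_objects(cells):
        in_cell = cells[sl] == cell_id
        cell_pts = np.argwhere(in_cell) + [s.start for s in sl]
        spot_pts = np.argwhere(in_cell & spots[sl]) + [s.start for s in sl]
        n_spot = len(spot_pts)
        diam = cell_diameter(cell_pts)
        if n_spot >= min_spot_px and np.isfinite(diam) and diam > 0:
            cr, cc = spot_centroid(spot_pts)
            disp = dispersion_cell(cell_pts, spot_pts)
            band = band_dispersion_cell(cell_pts, spot_pts, n_bands=n_bands)
        else:
            cr = cc = disp = band = float("nan")
        records.append(
            {
                "cell_id": cell_id,
                "n_spot_px": n_spot,
                "spot_centroid_row": cr,
                "spot_centroid_col": cc,
                "cell_diameter_px": diam,
                "dispersion": disp,
                "band_dispersion": band,
                "on_border": cell_id in border,
            }
        )
    columns = [
        "cell_id",
        "n_spot_px",
        "spot_centroid_row",
        "spot_centroid_col",
        "cell_diameter_px",
        "dispersion",
        "band_dispersion",
        "on_border",
    ]
    return MeasurementTable(pd.DataFrame(records, columns=columns), level="cell")
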