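"""Synthetic three-channel plate images with known dispersion ground truth.

The generator emulates the live-cell internalization assay the pipeline was
built for: round adherent cells carrying

* a bright nuclear stain (channel 1),
* a medium-intensity cell-body stain (channel 2), and
* a punctate payload channel (channel 3) whose vesicle-like spots cluster
  around a per-cell *focus* — a point that may sit anywhere in the cell, the
  way internalized payload aggregates toward an unmarked compartment.

Spot centers are drawn from an isotropic Gaussian around the focus,
truncated to the cell interior; the standard deviation ``spread`` (px) is
the single dial controlling aggregation, from fully aggregated (spread 0)
to near-uniform occupancy (spread comparable to the cell radius), and is
the quantity the dispersion statistic is expected to track. Setting
``uniform_spots`` instead draws centers uniformly over the cell interior,
the closed-form reference case: for many spots the dispersion of a uniform
disk tends to (2R/3)/(2R) = 1/3.

All randomness flows from one seed; per-image seeds are spawned
deterministically, so identical parameters and seed give bit-identical
images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io_plate import DEFAULT_PATTERN, format_ref_name, well_name, write_image

_ROWS = "ABCDEFGHIJKLMNOP"


@dataclass(frozen=True)
class SceneParams:
    """Geometry, optics and noise of one synthetic field image.

    Intensities are arbitrary camera units on a uint16 scale; defaults give
    well-separated bimodal histograms so the default segmentation parameters
    succeed, which is what fixtures must do to exercise the pipeline.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 6
    cell_radius: tuple[float, float] = (16.0, 22.0)
    nucleus_frac: float = 0.4  # nucleus radius as fraction of cell radius
    spread: float = 6.0  # spot-center sigma around the focus, px
    n_spots: int = 25
    uniform_spots: bool = False  # uniform over cell instead of Gaussian
    focus_frac: float = 0.35  # focus drawn within this fraction of the radius
    spot_amplitude: float = 600.0
    spot_sigma: float = 1.2  # rendered blob width, px
    background: float = 100.0
    cell_floor: float = 40.0  # payload autofluorescence inside cells
    body_level: float = 300.0
    nucleus_level: float = 900.0
    noise_sigma: float = 8.0
    poisson_noise: bool = False
    border_margin: float = 4.0
    spot_inset: float = 2.0  # keep spot centers this far inside the membrane
    #: inner exclusion radius for spot centers, as a fraction of the cell
    #: radius; models cytoplasmic payload excluded from the nucleus, which
    #: is what pushes dispersion of widely distributed vesicles above the
    #: uniform-disk value
    exclude_frac: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.shape
        rmax = self.cell_radius[1]
        if 2 * (rmax + self.border_margin) > min(h, w):
            raise InputError(
                f"cell radius {rmax} does not fit in a {h}x{w} image"
            )
        if not 0 <= self.nucleus_frac < 1:
            raise InputError("nucleus_frac must be in [0, 1)")
        if self.spread < 0 or self.n_spots < 1:
            raise InputError("spread must be >= 0 and n_spots >= 1")
        if not 0 <= self.exclude_frac < 1:
            raise InputError("exclude_frac must be in [0, 1)")


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one generated cell."""

    cell_index: int
    center: tuple[float, float]  # (row, col)
    radius: float
    nucleus_radius: float
    focus: tuple[float, float]
    spread: float
    n_spots: int
    spot_centers: np.ndarray = field(repr=False)


@dataclass
class SyntheticScene:
    """One rendered field: three channel images plus ground truth."""

    nuclear_img: np.ndarray
    body_img: np.ndarray
    payload_img: np.ndarray
    cells: list[CellTruth]
    labels: np.ndarray  # ground-truth cell label image (disk stamps)
    params: SceneParams
    seed: int


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_centers(params: SceneParams, rng: np.random.Generator):
    """Rejection-sample non-touching cell centers and radii."""
    h, w = params.shape
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < params.n_cells:
        attempts += 1
        if attempts > 20_000:
            raise InputError(
                f"cannot place {params.n_cells} cells of radius "
                f"{params.cell_radius} in a {h}x{w} image"
            )
        radius = rng.uniform(*params.cell_radius)
        margin = radius + params.border_margin
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all(
            np.hypot(r - pr, c - pc) > radius + prad + 4.0
            for pr, pc, prad in placed
        ):
            placed.append((r, c, radius))
    return placed


def _sample_spot_centers(
    center: np.ndarray,
    radius: float,
    focus: np.ndarray,
    params: SceneParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spot centers: truncated isotropic Gaussian around the focus (or
    uniform over the allowed region).

    The allowed region is the disk of radius ``radius - spot_inset`` minus
    the central exclusion disk of radius ``exclude_frac * radius`` (the
    nucleus, when modeled)."""
    rmax = radius - params.spot_inset
    rmin = params.exclude_frac * radius
    if rmin >= rmax:
        raise InputError("exclusion radius leaves no room for spots")
    out = np.empty((params.n_spots, 2))
    n = 0
    while n < params.n_spots:
        if params.uniform_spots:
            # exact uniform over the annulus via radius inverse-CDF
            theta = rng.uniform(0, 2 * np.pi, size=params.n_spots)
            rad = np.sqrt(rng.uniform(rmin**2, rmax**2, size=params.n_spots))
            cand = center + np.column_stack([rad * np.sin(theta), rad * np.cos(theta)])
        elif params.spread == 0:
            cand = np.tile(focus, (params.n_spots, 1))
        else:
            cand = focus + rng.normal(0, params.spread, size=(params.n_spots, 2))
        dist = np.hypot(*(cand - center).T)
        ok = cand[(dist <= rmax) & (dist >= rmin)]
        take = min(len(ok), params.n_spots - n)
        out[n : n + take] = ok[:take]
        n += take
    return out


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def generate_scene(params: SceneParams = SceneParams(), seed: int = 0) -> SyntheticScene:
    """Render one three-channel field with per-cell ground truth.

    Reproducible: identical ``params`` and ``seed`` give bit-identical
    images.
    """
    rng = np.random.default_rng(seed)
    h, w = params.shape
    nuclear = np.full((h, w), params.background, dtype=float)
    body = np.full((h, w), params.background, dtype=float)
    payload = np.full((h, w), params.background, dtype=float)
    labels = np.zeros((h, w), dtype=np.int32)

    cells: list[CellTruth] = []
    for idx, (r, c, radius) in enumerate(_place_centers(params, rng), start=1):
        center = np.array([r, c])
        nuc_radius = params.nucleus_frac * radius
        cell_mask = _disk_mask((h, w), center, radius)
        labels[cell_mask] = idx
        body[cell_mask] += params.body_level
        payload[cell_mask] += params.cell_floor
        nuclear[_disk_mask((h, w), center, nuc_radius)] += params.nucleus_level

        # focus anywhere within focus_frac of the radius (outside any
        # central exclusion zone, so spread=0 stays feasible)
        lo = params.exclude_frac * radius
        hi = max(params.focus_frac * (radius - params.spot_inset), min(lo + 1.0, radius - params.spot_inset))
        theta = rng.uniform(0, 2 * np.pi)
        off = np.sqrt(rng.uniform(lo**2, hi**2))
        focus = center + off * np.array([np.sin(theta), np.cos(theta)])

        centers = _sample_spot_centers(center, radius, focus, params, rng)
        _render_spots(payload, centers, params)
        cells.append(
            CellTruth(
                cell_index=idx,
                center=(float(r), float(c)),
                radius=float(radius),
                nucleus_radius=float(nuc_radius),
                focus=(float(focus[0]), float(focus[1])),
                spread=params.spread,
                n_spots=params.n_spots,
                spot_centers=centers,
            )
        )

    imgs = []
    for img in (nuclear, body, payload):
        if params.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        img = img + rng.normal(0, params.noise_sigma, size=img.shape)
        imgs.append(np.clip(np.round(img), 0, 65535).astype(np.uint16))
    nuclear_img, body_img, payload_img = imgs
    return SyntheticScene(
        nuclear_img=nuclear_img,
        body_img=body_img,
        payload_img=payload_img,
        cells=cells,
        labels=labels,
        params=params,
        seed=seed,
    )


def _render_spots(img: np.ndarray, centers: np.ndarray, params: SceneParams) -> None:
    """Add Gaussian intensity blobs at the given sub-pixel centers."""
    h, w = img.shape
    half = int(np.ceil(4 * params.spot_sigma))
    for r, c in centers:
        r0, c0 = int(round(r)), int(round(c))
        rs = slice(max(r0 - half, 0), min(r0 + half + 1, h))
        cs = slice(max(c0 - half, 0), min(c0 + half + 1, w))
        rr, cc = np.mgrid[rs, cs]
        img[rs, cs] += params.spot_amplitude * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2 * params.spot_sigma**2)
        )


# ---------------------------------------------------------------------------
# Monte-Carlo oracle for the expected dispersion of the generative model
# ---------------------------------------------------------------------------


def _disk_pixels(radius: float) -> np.ndarray:
    n = int(np.ceil(radius))
    rr, cc = np.mgrid[-n : n + 1, -n : n + 1]
    inside = rr**2 + cc**2 <= radius**2
    return np.column_stack([rr[inside], cc[inside]]).astype(float)


def sample_cell_dispersion(
    radius: float,
    spread: float,
    n_spots: int,
    rng: np.random.Generator,
    uniform: bool = False,
    spot_inset: float = 2.0,
    exclude_frac: float = 0.0,
) -> float:
    """One draw of the dispersion statistic under the generative spot model.

    Works on exact geometry (spot centers as points, cell diameter 2R),
    bypassing rendering, thresholding and segmentation entirely, so it
    serves as an independent oracle for the imaging pipeline. With a central
    exclusion zone the focus sits mid-annulus (a point at the disk center
    would be excluded).
    """
    params = SceneParams(
        spread=spread,
        n_spots=n_spots,
        uniform_spots=uniform,
        spot_inset=spot_inset,
        exclude_frac=exclude_frac,
        cell_radius=(radius, radius),
        shape=(int(4 * radius + 16), int(4 * radius + 16)),
    )
    center = np.zeros(2)
    focus = center
    if exclude_frac > 0:
        theta = rng.uniform(0, 2 * np.pi)
        mid = 0.5 * (exclude_frac * radius + radius - spot_inset)
        focus = mid * np.array([np.sin(theta), np.cos(theta)])
    pts = _sample_spot_centers(center, radius, focus, params, rng)
    dists = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    return float(dists.mean() / (2 * radius))


def expected_dispersion_mc(
    radius: float = 18.0,
    spread: float = 6.0,
    n_spots: int = 25,
    n_reps: int = 200,
    seed: int = 0,
    uniform: bool = False,
    spot_inset: float = 2.0,
    exclude_frac: float = 0.0,
) -> tuple[float, float]:
    """Monte-Carlo (mean, sd) of the dispersion under the generative model.

    ``n_reps`` independent cells are simulated at exact geometry; the sd is
    the between-cell standard deviation (use sd/sqrt(n_reps) for the
    standard error of the mean).
    """
    if n_reps < 100:
        raise InputError("n_reps must be >= 100 for a stable estimate")
    rng = np.random.default_rng(seed)
    draws = np.array(
        [
            sample_cell_dispersion(
                radius,
                spread,
                n_spots,
                rng,
                uniform=uniform,
                spot_inset=spot_inset,
                exclude_frac=exclude_frac,
            )
            for _ in range(n_reps)
        ]
    )
    return float(draws.mean()), float(draws.std(ddof=1))


def spread_for_dispersion(
    target: float,
    radius: float = 18.0,
    n_spots: int = 25,
    n_reps: int = 300,
    seed: int = 0,
    exclude_frac: float = 0.0,
    spot_inset: float = 2.0,
) -> float:
    """Invert the oracle: spread sigma whose expected dispersion is ``target``.

    Bisection on the (monotone in spread) Monte-Carlo mean; used to design
    conditions with prescribed expected dispersion levels. Targets above the
    wide-spread limit of the plain model (~0.28 for default geometry) need a
    nuclear exclusion zone (``exclude_frac``), which is also how such values
    arise in cells: widely dispersed vesicles occupy the cytoplasm but not
    the nucleus.
    """
    lo, hi = 1e-3, 3.0 * radius
    mean_hi, _ = expected_dispersion_mc(
        radius, hi, n_spots, n_reps, seed, exclude_frac=exclude_frac, spot_inset=spot_inset
    )
    if not 0 < target < mean_hi:
        raise InputError(f"target {target} outside achievable range (0, {mean_hi:.3f})")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        mean_mid, _ = expected_dispersion_mc(
            radius, mid, n_spots, n_reps, seed, exclude_frac=exclude_frac, spot_inset=spot_inset
        )
        if mean_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def condition_for_dispersion(
    target: float,
    radius: float = 18.0,
    n_spots: int = 25,
    n_reps: int = 300,
    seed: int = 0,
) -> dict[str, float]:
    """Spot-model kwargs (spread, exclude_frac, spot_inset) hitting ``target``.

    Low targets are realized as a tight Gaussian around a focus (aggregated
    phenotype); targets beyond the wide-spread limit of the plain model use
    a nuclear exclusion zone (dispersed cytoplasmic phenotype), mirroring
    how the two extremes arise in cells.
    """
    exclude_frac, spot_inset = 0.0, 2.0
    if target > 0.26:
        exclude_frac, spot_inset = 0.5, 1.0
    spread = spread_for_dispersion(
        target,
        radius=radius,
        n_spots=n_spots,
        n_reps=n_reps,
        seed=seed,
        exclude_frac=exclude_frac,
        spot_inset=spot_inset,
    )
    return {"spread": spread, "exclude_frac": exclude_frac, "spot_inset": spot_inset}


# ---------------------------------------------------------------------------
# plate generation
# ---------------------------------------------------------------------------


def generate_plate(
    root: str | Path,
    spread_schedule: Mapping[str, Sequence[float]],
    n_wells_per_condition: int = 2,
    n_fields: int = 2,
    scene_params: SceneParams = SceneParams(),
    scene_params_by_condition: Mapping[str, SceneParams] | None = None,
    seed: int = 0,
    pattern: str = DEFAULT_PATTERN,
) -> pd.DataFrame:
    """Write a synthetic plate of TIFFs plus ground-truth tables.

    ``spread_schedule`` maps each condition label to its per-timepoint spot
    spread (px); all conditions must share the same number of timepoints
    (the plate is acquired at common times). Wells are assigned row-major
    (condition 1 -> A01.., condition 2 -> next wells, ...), channels are
    1 = nuclei, 2 = cell body, 3 = payload, and files are named with the
    default plate pattern so the folder parses with no configuration.

    Writes ``truth.csv`` (per generated cell: well, field, timepoint,
    condition, spread, focus, radius) and ``conditions.csv`` (well ->
    condition) beside the images, and returns the truth table.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    n_time = {len(v) for v in spread_schedule.values()}
    if len(n_time) != 1:
        raise InputError("all conditions must have the same number of timepoints")
    (n_timepoints,) = n_time

    # assign wells row-major across the plate
    conditions = list(spread_schedule)
    wells: list[tuple[str, int, str]] = []
    i = 0
    for cond in conditions:
        for _ in range(n_wells_per_condition):
            row, col = _ROWS[i // 24], i % 24 + 1
            wells.append((row, col, cond))
            i += 1

    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(len(wells) * n_fields * n_timepoints))

    truth_rows = []
    cond_rows = [
        {"well": well_name(r, c), "condition": cond} for r, c, cond in wells
    ]
    for row, col, cond in wells:
        for fieldno in range(1, n_fields + 1):
            for t in range(n_timepoints):
                spread = float(spread_schedule[cond][t])
                base = (scene_params_by_condition or {}).get(cond, scene_params)
                params = replace(base, spread=spread)
                scene = generate_scene(params, seed=int(next(child_seeds)) % (2**31))
                for channel, img in (
                    (1, scene.nuclear_img),
                    (2, scene.body_img),
                    (3, scene.payload_img),
                ):
                    name = format_ref_name(pattern, row, col, fieldno, t, channel)
                    write_image(root / name, img)
                for cell in scene.cells:
                    truth_rows.append(
                        {
                            "well": well_name(row, col),
                            "condition": cond,
                            "field": fieldno,
                            "timepoint": t,
                            "cell_index": cell.cell_index,
                            "center_row": cell.center[0],
                            "center_col": cell.center[1],
                            "radius": cell.radius,
                            "focus_row": cell.focus[0],
                            "focus_col": cell.focus[1],
                            "spread": cell.spread,
                            "n_spots": cell.n_spots,
                        }
                    )
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(root / "truth.csv", index=False)
    pd.DataFrame(cond_rows).to_csv(root / "conditions.csv", index=False)
    return truth
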