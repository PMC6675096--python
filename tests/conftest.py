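"""Shared fixtures: synthetic scenes, segmented pipelines, small plates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spotspread import (
    SceneParams,
    generate_plate,
    generate_scene,
    measure_dispersion,
    segment_cells,
    segment_nuclei,
    spot_mask_per_cell,
)


def run_pipeline(scene):
    """Run the segmentation+measurement chain on a synthetic scene."""
    nuclei = segment_nuclei(scene.nuclear_img)
    cells = segment_cells(scene.body_img, nuclei)
    spots = spot_mask_per_cell(scene.payload_img, cells)
    table = measure_dispersion(cells, spots)
    return nuclei, cells, spots, table


def match_truth(scene, cells, table) -> pd.DataFrame:
    """Join ground-truth cells to measured records via the label under each
    true center; cells lost to segmentation are dropped."""
    t = table.data.set_index("cell_id")
    rows = []
    for cell in scene.cells:
        lab = cells[int(round(cell.center[0])), int(round(cell.center[1]))]
        if lab > 0 and lab in t.index:
            rows.append(
                {
                    "true_radius": cell.radius,
                    "true_spread": cell.spread,
                    "dispersion": t.loc[lab, "dispersion"],
                    "band_dispersion": t.loc[lab, "band_dispersion"],
                    "n_spot_px": t.loc[lab, "n_spot_px"],
                }
            )
    return pd.DataFrame(rows)


def disk_pixels(radius: float, center=(0, 0)) -> np.ndarray:
    """Integer pixel coordinates of a rasterized disk."""
    n = int(np.ceil(radius))
    rr, cc = np.mgrid[-n : n + 1, -n : n + 1]
    inside = rr**2 + cc**2 <= radius**2
    return np.column_stack([rr[inside] + center[0], cc[inside] + center[1]])


@pytest.fixture(scope="session")
def default_scene():
    return generate_scene(SceneParams(), seed=1)


@pytest.fixture(scope="session")
def segmented_scene(default_scene):
    return (default_scene, *run_pipeline(default_scene))


@pytest.fixture(scope="session")
def small_plate(tmp_path_factory):
    """2 conditions x 1 well x 2 fields x 1 timepoint, 5 cells per field."""
    root = tmp_path_factory.mktemp("plate")
    truth = generate_plate(
        root,
        spread_schedule={"aggregated": [3.0], "dispersed": [10.0]},
        n_wells_per_condition=1,
        n_fields=2,
        scene_params=SceneParams(n_cells=5),
        seed=7,
    )
    return root, truth
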