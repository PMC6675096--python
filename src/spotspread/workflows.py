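"""Canonical workflow definitions built on the engine.

The standard dispersion workflow wires the three field channels through
segmentation into the per-cell measurement table::

    nuclei_img ──▶ segment_nuclei ─┐
    body_img ─────▶ segment_cells ─┼─▶ spot_mask ──▶ measure
    payload_img ───────────────────┘

Each node declares its tunable parameters so the engine's partial execution
and caching can drive parameter tuning on intermediate outputs.
"""

from __future__ import annotations

from .dispersion import measure_dispersion
from .engine import Module, ModuleSpec, ParamSpec, WorkflowGraph, WorkflowInput, build_workflow
from .segmentation import segment_cells, segment_nuclei, spot_mask_per_cell

#: Workflow input names, in channel-role order.
INPUTS = ("nuclei_img", "body_img", "payload_img")

#: (node name, slot) of the final cell-level measurement table.
MEASURE_OUTPUT = ("measure", 0)


def dispersion_workflow() -> WorkflowGraph:
    """Build the standard nuclei→cells→spots→dispersion workflow."""
    modules = [
        Module(
            ModuleSpec(
                name="segment_nuclei",
                input_kinds=("image",),
                output_kinds=("labels",),
                params=(
                    ParamSpec("smooth_sigma", "float", 2.0, low=0.0, high=20.0),
                    ParamSpec("min_area", "int", 40, low=1, high=10**6),
                    ParamSpec("max_area", "int", 100_000, low=1, high=10**7),
                    ParamSpec("h_minima_depth", "float", 2.0, low=0.0, high=50.0),
                ),
            ),
            lambda img, **p: (segment_nuclei(img, **p),),
        ),
        Module(
            ModuleSpec(
                name="segment_cells",
                input_kinds=("image", "labels"),
                output_kinds=("labels",),
                params=(ParamSpec("smooth_sigma", "float", 2.0, low=0.0, high=20.0),),
            ),
            lambda img, nuclei, **p: (segment_cells(img, nuclei, **p),),
        ),
        Module(
            ModuleSpec(
                name="spot_mask",
                input_kinds=("image", "labels"),
                output_kinds=("labels",),
                params=(ParamSpec("min_cell_pixels", "int", 8, low=1, high=10**6),),
            ),
            lambda img, cells, **p: (spot_mask_per_cell(img, cells, **p),),
        ),
        Module(
            ModuleSpec(
                name="measure",
                input_kinds=("labels", "labels"),
                output_kinds=("table",),
                params=(
                    ParamSpec("min_spot_px", "int", 1, low=1, high=10**6),
                    ParamSpec("n_bands", "int", 4, low=1, high=32),
                ),
            ),
            lambda cells, spots, **p: (
                measure_dispersion(cells, spots.astype(bool), **p),
            ),
        ),
    ]
    inputs = [WorkflowInput(name, "image") for name in INPUTS]
    edges = [
        (("nuclei_img", 0), ("segment_nuclei", 0)),
        (("body_img", 0), ("segment_cells", 0)),
        (("segment_nuclei", 0), ("segment_cells", 1)),
        (("payload_img", 0), ("spot_mask", 0)),
        (("segment_cells", 0), ("spot_mask", 1)),
        (("segment_cells", 0), ("measure", 0)),
        (("spot_mask", 0), ("measure", 1)),
    ]
    return build_workflow(modules, inputs, edges)
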