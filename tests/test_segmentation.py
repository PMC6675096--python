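"""Nuclei/cell segmentation and per-cell spot thresholding."""

import logging

import numpy as np
import pytest

from spotspread import (
    InputError,
    SceneParams,
    generate_scene,
    segment_cells,
    segment_nuclei,
    spot_mask_per_cell,
)
from conftest import run_pipeline


def disks_image(shape, centers, radius, level=1000.0, background=50.0):
    img = np.full(shape, background)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for r, c in centers:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = level
    return img


class TestNuclei:
    def test_two_separated_disks(self):
        img = disks_image((100, 100), [(30, 30), (30, 70)], radius=10)
        labels = segment_nuclei(img)
        assert labels.max() == 2
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_constant_image_zero_objects(self):
        assert segment_nuclei(np.full((64, 64), 7.0)).max() == 0

    def test_generator_ground_truth_centers(self):
        scene = generate_scene(SceneParams(n_cells=5), seed=3)
        labels = segment_nuclei(scene.nuclear_img)
        assert labels.max() == 5
        hits = [
            labels[int(round(c.center[0])), int(round(c.center[1]))]
            for c in scene.cells
        ]
        assert all(h > 0 for h in hits)
        assert len(set(hits)) == 5  # one object per true nucleus

    def test_area_filter_removes_specks(self):
        img = disks_image((100, 100), [(50, 50)], radius=10)
        img[5, 5] = 1000.0  # single-pixel speck
        assert segment_nuclei(img, min_area=40).max() == 1

    def test_labels_contiguous(self):
        scene = generate_scene(SceneParams(n_cells=4), seed=5)
        labels = segment_nuclei(scene.nuclear_img)
        ids = np.unique(labels[labels > 0])
        np.testing.assert_array_equal(ids, np.arange(1, labels.max() + 1))


class TestCells:
    def test_two_blobs_partition_foreground(self):
        body = disks_image((100, 100), [(30, 30), (30, 70)], radius=15, level=500)
        nuclei = np.zeros((100, 100), np.int32)
        nuclei[28:33, 28:33] = 1
        nuclei[28:33, 68:73] = 2
        cells = segment_cells(body, nuclei)
        assert cells.max() == 2
        # interiors (eroded past the smoothing halo) fully labeled, one id each
        rr, cc = np.mgrid[:100, :100]
        for i, (r, c) in enumerate([(30, 30), (30, 70)], start=1):
            interior = (rr - r) ** 2 + (cc - c) ** 2 <= 10**2
            assert set(np.unique(cells[interior])) == {i}
        # background well away from the blobs stays unlabeled
        far = (rr - 30) ** 2 + (cc - 30) ** 2 > 22**2
        far &= (rr - 30) ** 2 + (cc - 70) ** 2 > 22**2
        assert cells[far].max() == 0

    def test_zero_seeds_zero_cells(self, caplog):
        body = disks_image((50, 50), [(25, 25)], radius=10)
        with caplog.at_level(logging.WARNING):
            cells = segment_cells(body, np.zeros((50, 50), np.int32))
        assert cells.max() == 0
        assert any("no nuclei" in r.message for r in caplog.records)

    def test_touching_blobs_split_between_seeds(self):
        body = disks_image((80, 120), [(40, 45), (40, 75)], radius=20, level=500)
        nuclei = np.zeros((80, 120), np.int32)
        nuclei[38:43, 43:48] = 1
        nuclei[38:43, 73:78] = 2
        cells = segment_cells(body, nuclei)
        assert cells.max() == 2
        # two disjoint regions, each claiming its seed's side
        assert cells[40, 45] == 1 and cells[40, 75] == 2
        assert (cells == 1).sum() > 200 and (cells == 2).sum() > 200
        # the touching region is split, not merged: both labels present
        # along the seam column range
        seam = cells[:, 55:65]
        assert {1, 2} <= set(np.unique(seam[seam > 0]))

    def test_nucleus_inherits_cell_id(self, segmented_scene):
        scene, nuclei, cells, spots, table = segmented_scene
        inside = nuclei > 0
        assert np.array_equal(cells[inside], nuclei[inside])

    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            segment_cells(np.zeros((10, 10)), np.zeros((5, 5), np.int32))

    def test_ground_truth_count_recovered(self, segmented_scene):
        scene, nuclei, cells, spots, table = segmented_scene
        assert cells.max() == len(scene.cells)
        # each true spot focus falls in its own cell
        labs = [
            cells[int(round(c.focus[0])), int(round(c.focus[1]))] for c in scene.cells
        ]
        assert len(set(labs)) == len(scene.cells) and all(l > 0 for l in labs)


class TestSpotMask:
    @staticmethod
    def one_cell_bimodal():
        cells = np.zeros((10, 10), np.int32)
        cells[:, :] = 1
        payload = np.full((10, 10), 10.0)
        bright = np.zeros((10, 10), bool)
        bright.flat[:50] = True
        payload[bright] = 200.0
        return payload, cells, bright

    def test_bimodal_exact(self):
        payload, cells, bright = self.one_cell_bimodal()
        mask = spot_mask_per_cell(payload, cells)
        np.testing.assert_array_equal(mask, bright)

    def test_constant_cell_empty_mask(self):
        cells = np.ones((10, 10), np.int32)
        assert not spot_mask_per_cell(np.full((10, 10), 42.0), cells).any()

    def test_tiny_cell_empty_mask(self):
        cells = np.zeros((10, 10), np.int32)
        cells[0, :4] = 1
        payload = np.random.default_rng(0).uniform(0, 100, (10, 10))
        assert not spot_mask_per_cell(payload, cells, min_cell_pixels=8).any()

    def test_per_cell_independence(self):
        rng = np.random.default_rng(1)
        cells = np.zeros((10, 20), np.int32)
        cells[:, :10] = 1
        cells[:, 10:] = 2
        payload = rng.uniform(10, 200, (10, 20))
        base = spot_mask_per_cell(payload, cells)
        scaled = payload.copy()
        scaled[cells == 2] *= 10  # rescale only cell B
        again = spot_mask_per_cell(scaled, cells)
        np.testing.assert_array_equal(base[cells == 1], again[cells == 1])

    def test_affine_rescale_invariance(self):
        rng = np.random.default_rng(2)
        cells = np.ones((20, 20), np.int32)
        payload = rng.uniform(0, 1000, (20, 20))
        a = spot_mask_per_cell(payload, cells)
        b = spot_mask_per_cell(3.0 * payload + 7.0, cells)
        np.testing.assert_array_equal(a, b)

    def test_mask_subset_of_cells(self, segmented_scene):
        scene, nuclei, cells, spots, table = segmented_scene
        assert not np.any(spots & (cells == 0))

    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            spot_mask_per_cell(np.zeros((4, 4)), np.zeros((5, 5), np.int32))


def between_class_variances(values: np.ndarray, nbins: int = 256):
    """Independent oracle: between-class variance of every candidate split
    of the nbins-histogram; returns (bin centers, variance per split)."""
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    variances = np.full(nbins, -np.inf)
    for k in range(1, nbins):  # class 0 = bins [0, k)
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        variances[k - 1] = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
    return centers, variances


@pytest.mark.parametrize("seed", range(5))
def test_otsu_maximizes_between_class_variance(seed):
    """The per-cell threshold attains the exhaustive-search maximum of the
    between-class variance over the same 256-bin histogram (ties at the flat
    optimum are equivalent)."""
    from spotspread.segmentation import otsu_threshold_values

    rng = np.random.default_rng(seed)
    values = np.concatenate(
        [rng.normal(80, 12, 300), rng.normal(300, 40, 80 + 30 * seed)]
    )
    ours = otsu_threshold_values(values)
    centers, variances = between_class_variances(values)
    k = int(np.argmin(np.abs(centers - ours)))
    assert variances[k] >= variances.max() * (1 - 1e-9)


def test_cell_partition_no_double_ids(segmented_scene):
    """Cell labels are a partition: computed labels are single-valued by
    construction, and every label id appears as exactly one 8-connected
    region."""
    from skimage.measure import label as cc_label

    scene, nuclei, cells, spots, table = segmented_scene
    for i in range(1, cells.max() + 1):
        assert cc_label(cells == i, connectivity=2).max() == 1


def test_full_pipeline_from_generator(default_scene):
    nuclei, cells, spots, table = run_pipeline(default_scene)
    assert len(table.data) == len(default_scene.cells)
    assert table.data["dispersion"].notna().all()
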