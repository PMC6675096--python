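"""Batch execution, aggregation and the repeated-measures ANOVA."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from spotspread import (
    ConfigurationError,
    InputError,
    MeasurementTable,
    aggregate,
    parse_plate_folder,
    plot_timeseries,
    rm_anova,
    run_batch,
)
from spotspread.workflows import dispersion_workflow

ROLES = {"nuclei": 1, "body": 2, "payload": 3}


@pytest.fixture(scope="module")
def batch_table(small_plate):
    root, truth = small_plate
    refs = parse_plate_folder(root)
    return run_batch(refs, dispersion_workflow(), ROLES)


class TestRunBatch:
    def test_cell_counts_match_truth(self, small_plate, batch_table):
        root, truth = small_plate
        # 2 wells x 2 fields x 5 cells
        assert len(batch_table.data) == len(truth) == 20
        assert set(batch_table.data.columns) >= {
            "well_row",
            "well_col",
            "field",
            "timepoint",
            "cell_id",
            "dispersion",
        }

    def test_deterministic_rerun(self, small_plate, batch_table):
        root, _ = small_plate
        again = run_batch(parse_plate_folder(root), dispersion_workflow(), ROLES)
        pd.testing.assert_frame_equal(batch_table.data, again.data)

    def test_missing_role_rejected(self, small_plate):
        root, _ = small_plate
        refs = parse_plate_folder(root)
        with pytest.raises(ConfigurationError):
            run_batch(refs, dispersion_workflow(), {"nuclei": 1, "body": 2})
        with pytest.raises(ConfigurationError):
            run_batch(refs, dispersion_workflow(), {"nuclei": 1, "body": 2, "payload": 9})

    def test_corrupt_image_skipped_not_fatal(self, small_plate, tmp_path, caplog):
        import shutil

        root, _ = small_plate
        broken = tmp_path / "broken"
        shutil.copytree(root, broken)
        victim = sorted(broken.glob("*_c3.tif"))[0]
        victim.write_bytes(b"not a tiff")
        refs = parse_plate_folder(broken)
        with caplog.at_level(logging.WARNING):
            table = run_batch(refs, dispersion_workflow(), ROLES)
        assert len(table.data) == 15  # 3 of 4 fields survive
        assert any("failed" in r.message for r in caplog.records)


class TestAggregate:
    @staticmethod
    def cell_table(rows):
        df = pd.DataFrame(
            rows,
            columns=["well_row", "well_col", "field", "timepoint", "cell_id", "dispersion"],
        )
        return MeasurementTable(df, level="cell")

    def test_mean_and_count(self):
        t = self.cell_table(
            [("A", 1, 1, 0, 1, 0.2), ("A", 1, 1, 0, 2, 0.4)]
        )
        ts = aggregate(t, {"A01": "x"})
        assert len(ts) == 1
        row = ts.iloc[0]
        assert row["mean_dispersion"] == pytest.approx(0.3)
        assert row["n_cells"] == 2 and row["condition"] == "x"

    def test_undefined_only_well_dropped_with_warning(self, caplog):
        t = self.cell_table(
            [("A", 1, 1, 0, 1, 0.2), ("B", 1, 1, 0, 1, np.nan)]
        )
        with caplog.at_level(logging.WARNING):
            ts = aggregate(t, {"A01": "x", "B01": "x"})
        assert list(ts["well"]) == ["A01"]
        assert any("B01" in r.message for r in caplog.records)

    def test_orders_agree_with_equal_field_counts(self, batch_table):
        cmap = {"A01": "aggregated", "A02": "dispersed"}
        pooled = aggregate(batch_table, cmap, order="cells_pooled_per_well")
        per_img = aggregate(batch_table, cmap, order="per_image_then_well")
        if (batch_table.data.groupby(["well_row", "well_col", "field"]).size().nunique() == 1):
            pd.testing.assert_frame_equal(pooled, per_img)

    def test_cells_conserved(self, batch_table):
        ts = aggregate(batch_table, {"A01": "a", "A02": "d"})
        defined = batch_table.data.dropna(subset=["dispersion"])
        assert ts["n_cells"].sum() == len(defined)

    def test_unmapped_well_listed(self):
        t = self.cell_table([("C", 7, 1, 0, 1, 0.2)])
        with pytest.raises(ConfigurationError, match="C07"):
            aggregate(t, {"A01": "x"})


def ts_from_matrix(matrix, conditions):
    """Build a time-series table from a wells x timepoints array."""
    rows = []
    for i, (well_vals, cond) in enumerate(zip(matrix, conditions)):
        for t, v in enumerate(well_vals):
            rows.append(
                {
                    "condition": cond,
                    "well": f"W{i}",
                    "timepoint": t,
                    "mean_dispersion": v,
                    "n_cells": 10,
                }
            )
    return pd.DataFrame(rows)


def anova_by_hand(matrix, conditions):
    """Independent sum-of-squares oracle for the between-subject F."""
    y = np.asarray(matrix, float)
    conds = sorted(set(conditions))
    t = y.shape[1]
    grand = y.mean()
    ss_cond = ss_subj = 0.0
    for c in conds:
        sub = y[[i for i, cc in enumerate(conditions) if cc == c]]
        ss_cond += len(sub) * t * (sub.mean() - grand) ** 2
        for row in sub:
            ss_subj += t * (row.mean() - sub.mean()) ** 2
    df1 = len(conds) - 1
    df2 = len(y) - len(conds)
    return (ss_cond / df1) / (ss_subj / df2), df1, df2


class TestRmAnova:
    def test_identical_series_no_effect(self):
        m = [[0.2, 0.25, 0.3]] * 4
        res = rm_anova(ts_from_matrix(m, ["a", "a", "b", "b"]))
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_hand_sum_of_squares(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.1, 0.4, size=(6, 2))  # 2 cond x 3 wells x 2 timepoints
        conds = ["a"] * 3 + ["b"] * 3
        res = rm_anova(ts_from_matrix(m, conds))
        f, df1, df2 = anova_by_hand(m, conds)
        assert res.F == pytest.approx(f, abs=1e-10)
        assert (res.df1, res.df2) == (df1, df2)

    def test_matches_pingouin_mixed_anova(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        m = rng.uniform(0.1, 0.4, size=(8, 4))
        conds = ["a"] * 4 + ["b"] * 4
        ts = ts_from_matrix(m, conds)
        res = rm_anova(ts)
        pg = pingouin.mixed_anova(
            data=ts,
            dv="mean_dispersion",
            within="timepoint",
            subject="well",
            between="condition",
        )
        row = pg[pg["Source"] == "condition"].iloc[0]
        assert res.F == pytest.approx(float(row["F"]), rel=1e-9)
        assert res.p == pytest.approx(float(row["p_unc"]), rel=1e-9)
        inter = pg[pg["Source"] == "Interaction"].iloc[0]
        t_int = res.table.set_index("effect").loc["condition:timepoint"]
        assert t_int["F"] == pytest.approx(float(inter["F"]), rel=1e-9)

    def test_invariant_to_relabeling_and_time_permutation(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0.1, 0.4, size=(6, 4))
        conds = ["a"] * 3 + ["b"] * 3
        base = rm_anova(ts_from_matrix(m, conds))
        # permute wells within conditions and shuffle timepoint labels
        perm_wells = m[[1, 2, 0, 5, 3, 4]]
        perm_time = perm_wells[:, [3, 0, 2, 1]]
        again = rm_anova(ts_from_matrix(perm_time, conds))
        assert again.F == pytest.approx(base.F, rel=1e-12)
        assert again.p == pytest.approx(base.p, rel=1e-12)

    def test_unbalanced_instructs_window_restriction(self):
        ts = ts_from_matrix(np.full((4, 3), 0.2), ["a", "a", "b", "b"])
        ts = ts.drop(index=ts[(ts["well"] == "W0") & (ts["timepoint"] == 2)].index)
        with pytest.raises(InputError, match="window"):
            rm_anova(ts)

    def test_window_and_pair_filtering(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0.1, 0.4, size=(6, 5))
        conds = ["a", "a", "b", "b", "c", "c"]
        ts = ts_from_matrix(m, conds)
        res = rm_anova(ts, condition_pair=("a", "b"), timepoint_window=(2, 4))
        sub = [i for i, c in enumerate(conds) if c in ("a", "b")]
        f, df1, df2 = anova_by_hand(m[sub][:, 2:5], ["a", "a", "b", "b"])
        assert res.F == pytest.approx(f, abs=1e-10)

    def test_too_few_wells_rejected(self):
        ts = ts_from_matrix(np.full((3, 2), 0.2), ["a", "a", "b"])
        with pytest.raises(InputError, match="wells"):
            rm_anova(ts)

    def test_gg_epsilon_bounds(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0.1, 0.4, size=(8, 5))
        res = rm_anova(ts_from_matrix(m, ["a"] * 4 + ["b"] * 4), gg_correction=True)
        assert 1 / 4 <= res.gg_epsilon <= 1.0
        assert "p_gg" in res.table.columns


class TestPlot:
    def test_figure_written(self, tmp_path):
        m = np.linspace(0.1, 0.4, 24).reshape(4, 6)
        ts = ts_from_matrix(m, ["a", "a", "b", "b"])
        out = plot_timeseries(ts, tmp_path / "fig.png")
        assert out.exists() and out.stat().st_size > 0

    def test_single_condition_ok(self, tmp_path):
        ts = ts_from_matrix(np.full((2, 3), 0.2), ["a", "a"])
        assert plot_timeseries(ts, tmp_path / "one.png").exists()

    def test_empty_table_errors(self, tmp_path):
        with pytest.raises(InputError):
            plot_timeseries(pd.DataFrame(), tmp_path / "no.png")
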