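"""Batch execution, well-level aggregation and the repeated-measures ANOVA.

A parsed plate is processed field by field through a workflow; cell records
are pooled to per-(well, timepoint) mean dispersion, assembled into
per-condition time series, and two conditions are compared with a mixed
repeated-measures ANOVA: wells are the independent experimental units
(subjects), timepoints the repeated factor, and the reported statistic is
the between-subject condition effect

    F = MS_condition / MS_wells-within-condition

with p from the F(df_condition, df_wells) distribution. Timepoints are
treated as categorical; a Greenhouse–Geisser epsilon for the within-subject
effects is available as an option but no sphericity correction is applied
to the between-subject F (it does not involve the within-subject error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import WorkflowGraph, WorkflowRunner
from .errors import ConfigurationError, InputError
from .io_plate import (
    MeasurementTable,
    PlateImageRef,
    iter_well_groups,
    normalize_well,
    read_image,
)
from .synthetic import sample_cell_dispersion
from .workflows import MEASURE_OUTPUT

logger = logging.getLogger(__name__)

AggregationOrder = Literal["cells_pooled_per_well", "per_image_then_well"]


# ---------------------------------------------------------------------------
# batch execution
# ---------------------------------------------------------------------------


def run_batch(
    refs: Sequence[PlateImageRef],
    workflow: WorkflowGraph,
    channel_roles: Mapping[str, int],
    param_overrides: Mapping[str, Mapping[str, float]] | None = None,
    exclude_border: bool = False,
) -> MeasurementTable:
    """Run a workflow over every (well, field, timepoint) of a parsed plate.

    ``channel_roles`` maps the roles ``nuclei``, ``body`` and ``payload`` to
    channel numbers present in ``refs``. Individual field failures are
    logged and skipped rather than aborting the batch; the returned
    cell-level table carries full provenance columns.
    """
    for role in ("nuclei", "body", "payload"):
        if role not in channel_roles:
            raise ConfigurationError(f"channel role {role!r} not mapped")
    present = {r.channel for r in refs}
    missing = {c for c in channel_roles.values() if c not in present}
    if missing:
        raise ConfigurationError(
            f"role channels {sorted(missing)} absent from plate (has {sorted(present)})"
        )

    runner = WorkflowRunner(workflow)
    frames: list[pd.DataFrame] = []
    n_failed = 0
    for (row, col, fieldno, t), group in iter_well_groups(refs).items():
        by_channel = {r.channel: r for r in group}
        try:
            inputs = {
                "nuclei_img": read_image(by_channel[channel_roles["nuclei"]]),
                "body_img": read_image(by_channel[channel_roles["body"]]),
                "payload_img": read_image(by_channel[channel_roles["payload"]]),
            }
            table = runner.run_partial(MEASURE_OUTPUT, inputs, param_overrides)
        except KeyError as exc:
            n_failed += 1
            logger.warning("field %s%02d f%d t%d missing channel %s", row, col, fieldno, t, exc)
            continue
        except Exception as exc:  # noqa: BLE001 — batch robustness is the contract
            n_failed += 1
            logger.warning("field %s%02d f%d t%d failed: %s", row, col, fieldno, t, exc)
            continue
        df = table.data.copy()
        if exclude_border:
            df = df[~df["on_border"]]
        df.insert(0, "well_row", row)
        df.insert(1, "well_col", col)
        df.insert(2, "field", fieldno)
        df.insert(3, "timepoint", t)
        frames.append(df)

    logger.info("batch complete: %d fields ok, %d failed", len(frames), n_failed)
    if not frames:
        data = pd.DataFrame(
            columns=["well_row", "well_col", "field", "timepoint", "cell_id"]
        )
    else:
        data = pd.concat(frames, ignore_index=True)
    out = MeasurementTable(data, level="cell")
    out.require_provenance()
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate(
    cell_table: MeasurementTable,
    condition_map: Mapping[str, str] | pd.DataFrame,
    order: AggregationOrder = "cells_pooled_per_well",
) -> pd.DataFrame:
    """Aggregate cell dispersion to (condition, well, timepoint) means.

    Undefined dispersions are excluded (a cell with no detected payload
    carries no transport information); ``n_cells`` counts the cells that
    entered each mean. Two aggregation orders are supported: pooling all of
    a well's cells per timepoint (default) or averaging per field image
    first and then across fields — identical whenever all fields of a well
    contain equal cell counts.
    """
    if isinstance(condition_map, pd.DataFrame):
        condition_map = dict(
            zip(condition_map["well"].astype(str), condition_map["condition"])
        )
    condition_map = {normalize_well(w): c for w, c in condition_map.items()}
    if order not in ("cells_pooled_per_well", "per_image_then_well"):
        raise ConfigurationError(f"unknown aggregation order {order!r}")

    df = cell_table.data.copy()
    if df.empty:
        raise InputError("cell table is empty")
    df["well"] = [
        f"{r}{c:02d}" for r, c in zip(df["well_row"], df["well_col"])
    ]
    unmapped = sorted(set(df["well"]) - set(condition_map))
    if unmapped:
        raise ConfigurationError(f"wells missing from condition map: {unmapped}")

    defined = df.dropna(subset=["dispersion"])
    lost = set(map(tuple, df[["well", "timepoint"]].drop_duplicates().values)) - set(
        map(tuple, defined[["well", "timepoint"]].drop_duplicates().values)
    )
    for well, t in sorted(lost):
        logger.warning("well %s timepoint %s: no defined dispersions, row dropped", well, t)

    if order == "cells_pooled_per_well":
        g = defined.groupby(["well", "timepoint"])["dispersion"].agg(["mean", "size"])
    else:
        per_image = defined.groupby(["well", "timepoint", "field"])["dispersion"].mean()
        g = per_image.groupby(["well", "timepoint"]).mean().to_frame("mean")
        g["size"] = defined.groupby(["well", "timepoint"])["dispersion"].size()
    g = g.reset_index().rename(columns={"mean": "mean_dispersion", "size": "n_cells"})
    g.insert(0, "condition", g["well"].map(condition_map))
    return g[["condition", "well", "timepoint", "mean_dispersion", "n_cells"]]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    """Between-subject condition effect of the mixed design."""

    F: float
    df1: int
    df2: int
    p: float
    table: pd.DataFrame  # full effect table (condition, timepoint, interaction)
    gg_epsilon: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"F({self.df1},{self.df2}) = {self.F:.4g}, p = {self.p:.4g}"


def rm_anova(
    ts: pd.DataFrame,
    condition_pair: tuple[str, str] | None = None,
    timepoint_window: tuple[float, float] | None = None,
    gg_correction: bool = False,
) -> AnovaResult:
    """Mixed repeated-measures ANOVA on a time-series table.

    ``ts`` has columns condition, well, timepoint, mean_dispersion (the
    output of :func:`aggregate`). Optionally restrict to two conditions and
    a closed timepoint window. Requires >= 2 wells per condition, >= 2
    timepoints, and every well measured at every retained timepoint
    (balanced within-subject design); unbalanced input raises with the
    instruction to restrict the window.

    The headline statistic is the between-subject condition effect; the
    returned table also carries the within-subject timepoint and
    condition x timepoint effects (with Greenhouse–Geisser adjusted p-values
    when ``gg_correction`` is set).
    """
    df = ts.copy()
    if condition_pair is not None:
        df = df[df["condition"].isin(condition_pair)]
        if df["condition"].nunique() != 2:
            raise InputError(f"conditions {condition_pair} not both present")
    if timepoint_window is not None:
        lo, hi = timepoint_window
        df = df[(df["timepoint"] >= lo) & (df["timepoint"] <= hi)]
    if df.empty:
        raise InputError("no rows left after filtering")

    wide = df.pivot_table(
        index=["condition", "well"], columns="timepoint", values="mean_dispersion"
    )
    if wide.isna().any().any():
        raise InputError(
            "unbalanced design: some wells lack some timepoints; "
            "restrict the timepoint window to commonly measured times"
        )
    conds = wide.index.get_level_values("condition")
    n_per = conds.value_counts()
    if (n_per < 2).any():
        raise InputError(f"need >= 2 wells per condition, got {dict(n_per)}")
    a, t = n_per.size, wide.shape[1]
    if t < 2:
        raise InputError("need >= 2 timepoints in the window")

    y = wide.to_numpy()
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    time_mean = y.mean(axis=0)
    cond_labels = np.asarray(conds)
    cond_names = n_per.index.to_numpy()
    cond_mean = {c: y[cond_labels == c].mean() for c in cond_names}
    cond_time_mean = {c: y[cond_labels == c].mean(axis=0) for c in cond_names}
    n_of = {c: int(n_per[c]) for c in cond_names}

    # between-subject partition
    ss_cond = t * sum(n_of[c] * (cond_mean[c] - grand) ** 2 for c in cond_names)
    ss_subj = t * sum(
        (subj_mean[i] - cond_mean[cond_labels[i]]) ** 2 for i in range(len(y))
    )
    df_cond = a - 1
    df_subj = len(y) - a
    ms_cond = ss_cond / df_cond
    ms_subj = ss_subj / df_subj
    tiny = 1e-12 * max(((y - grand) ** 2).sum(), np.finfo(float).tiny)
    if ms_subj > tiny:
        f_cond = ms_cond / ms_subj
        p_cond = float(stats.f.sf(f_cond, df_cond, df_subj))
    elif ss_cond > tiny:  # perfect separation with zero well noise
        f_cond, p_cond = np.inf, 0.0
    else:  # degenerate: no between-well variation at all
        f_cond, p_cond = 0.0, 1.0

    # within-subject partition
    ss_time = len(y) * ((time_mean - grand) ** 2).sum()
    ss_inter = sum(
        n_of[c] * ((cond_time_mean[c] - cond_mean[c] - time_mean + grand) ** 2).sum()
        for c in cond_names
    )
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj - ss_time - ss_inter
    df_time = t - 1
    df_inter = df_cond * df_time
    df_err = df_subj * df_time
    ms_err = ss_err / df_err if df_err > 0 else np.nan

    def _f(ss, dfn):
        if ms_err and ms_err > 0:
            f = (ss / dfn) / ms_err
            return f, float(stats.f.sf(f, dfn, df_err))
        return 0.0, 1.0

    f_time, p_time = _f(ss_time, df_time)
    f_int, p_int = _f(ss_inter, df_inter)

    eps = None
    rows = [
        ("condition", ss_cond, df_cond, f_cond, p_cond),
        ("wells(condition)", ss_subj, df_subj, np.nan, np.nan),
        ("timepoint", ss_time, df_time, f_time, p_time),
        ("condition:timepoint", ss_inter, df_inter, f_int, p_int),
        ("error(within)", ss_err, df_err, np.nan, np.nan),
    ]
    table = pd.DataFrame(rows, columns=["effect", "SS", "df", "F", "p"])
    if gg_correction and t > 2:
        eps = _gg_epsilon(y, cond_labels, cond_names)
        for effect, dfn in (("timepoint", df_time), ("condition:timepoint", df_inter)):
            i = table.index[table["effect"] == effect][0]
            table.loc[i, "p_gg"] = float(
                stats.f.sf(table.loc[i, "F"], dfn * eps, df_err * eps)
            )
    return AnovaResult(
        F=float(f_cond), df1=df_cond, df2=df_subj, p=p_cond, table=table, gg_epsilon=eps
    )


def _gg_epsilon(y: np.ndarray, cond_labels: np.ndarray, cond_names) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-condition covariance."""
    t = y.shape[1]
    pooled = np.zeros((t, t))
    dof = 0
    for c in cond_names:
        sub = y[cond_labels == c]
        pooled += np.cov(sub, rowvar=False) * (len(sub) - 1)
        dof += len(sub) - 1
    s = pooled / dof
    # double-center
    s_dc = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
    num = np.trace(s_dc) ** 2
    den = (t - 1) * np.sum(s_dc**2)
    return float(np.clip(num / den, 1.0 / (t - 1), 1.0))


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


def plot_timeseries(ts: pd.DataFrame, destination: str | Path) -> Path:
    """Per-condition mean ± SEM dispersion vs timepoint, written to file."""
    if ts.empty:
        raise InputError("time-series table is empty; nothing to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, sub in ts.groupby("condition"):
        g = sub.groupby("timepoint")["mean_dispersion"]
        mean, sem = g.mean(), g.sem()
        ax.errorbar(mean.index, mean.values, yerr=sem.values, marker="o", capsize=3, label=str(cond))
    ax.set_xlabel("timepoint")
    ax.set_ylabel("mean dispersion")
    ax.set_ylim(bottom=0)
    ax.legend(title="condition", frameon=False)
    fig.tight_layout()
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(destination, dpi=150)
    plt.close(fig)
    return destination


# ---------------------------------------------------------------------------
# simulation-based calibration of the ANOVA
# ---------------------------------------------------------------------------


def simulate_null_anova(
    n_reps: int = 500,
    n_wells: int = 4,
    n_timepoints: int = 4,
    mu: float = 0.3,
    sigma_well: float = 0.02,
    sigma_noise: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """p-values of the condition effect under a zero-effect null.

    Well-level series are drawn from a random-intercept model
    y_ij = mu + b_i + e_ij with identical mu in both conditions; used to
    check the empirical type-I error of :func:`rm_anova`.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_reps)
    for k in range(n_reps):
        rows = []
        for cond in ("A", "B"):
            for w in range(n_wells):
                b = rng.normal(0, sigma_well)
                for t in range(n_timepoints):
                    rows.append(
                        {
                            "condition": cond,
                            "well": f"{cond}{w}",
                            "timepoint": t,
                            "mean_dispersion": mu + b + rng.normal(0, sigma_noise),
                        }
                    )
        pvals[k] = rm_anova(pd.DataFrame(rows)).p
    return pvals


def simulate_separation_power(
    model_a: Mapping[str, float],
    model_b: Mapping[str, float],
    n_reps: int = 100,
    n_wells: int = 4,
    n_timepoints: int = 4,
    n_cells_per_well: int = 30,
    radius: float = 18.0,
    n_spots: int = 25,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of simulations separating two spot-model conditions at ``alpha``.

    ``model_a``/``model_b`` are keyword arguments of
    :func:`spotspread.synthetic.sample_cell_dispersion` (``spread``, and
    optionally ``exclude_frac`` / ``spot_inset`` for nucleus-excluded
    phenotypes). Each replicate draws per-cell dispersions from the
    generative spot model for every well/timepoint, aggregates to well means
    and runs the repeated-measures ANOVA — the statistical design of the
    plate experiment at exact geometry.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        rows = []
        for cond, model in (("A", model_a), ("B", model_b)):
            for w in range(n_wells):
                for t in range(n_timepoints):
                    cells = [
                        sample_cell_dispersion(radius, n_spots=n_spots, rng=rng, **model)
                        for _ in range(n_cells_per_well)
                    ]
                    rows.append(
                        {
                            "condition": cond,
                            "well": f"{cond}{w}",
                            "timepoint": t,
                            "mean_dispersion": float(np.mean(cells)),
                        }
                    )
        if rm_anova(pd.DataFrame(rows)).p < alpha:
            hits += 1
    return hits / n_reps
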