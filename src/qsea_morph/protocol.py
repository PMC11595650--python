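"""The standardized expansion assay: 30-min sampling over the 5 h after
blastulation, milestone metrics and percent changes, and group expansion
maps with per-timepoint significance.

Each embryo's metric trajectory is resampled at tB + 0, 30, ..., 300 min
(11 points, the tB frame included, linear interpolation between stored
frames).  Group A vs group B comparison at every offset — Shapiro-gated
Welch t or Mann-Whitney, see :mod:`qsea_morph.stats` — produces an
expansion map from which the earliest significant offset is read off.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .stats import compare_groups
from .synth import MILESTONES, EmbryoRecord, MetricTimeSeries

#: the standard assay grid: every 30 min over the 5 h following tB,
#: including the tB frame itself
QSEA_OFFSETS_MIN: np.ndarray = np.arange(0, 301, 30)


class CoverageError(ValueError):
    """A series does not cover the requested sampling window."""


def sample_qsea(
    ts: MetricTimeSeries,
    tB: float,
    offsets_min: np.ndarray | None = None,
    strict: bool = True,
) -> np.ndarray:
    """Metric values at tB + each offset (minutes), linearly interpolated.

    In strict mode the series must span the whole window; in lenient mode
    offsets beyond the series end are returned as NaN.
    """
    offsets = QSEA_OFFSETS_MIN if offsets_min is None else np.asarray(offsets_min)
    t_req = tB + offsets / 60.0
    end = ts.times[-1]
    if strict and (tB < ts.times[0] - 1e-9 or t_req[-1] > end + 1e-9):
        raise CoverageError(
            f"series [{ts.times[0]:.2f}, {end:.2f}] hpi does not cover "
            f"[{tB:.2f}, {t_req[-1]:.2f}] hpi"
        )
    vals = np.interp(t_req, ts.times, ts.values)
    if not strict:
        vals = np.where((t_req > end + 1e-9) | (t_req < ts.times[0] - 1e-9), np.nan, vals)
    return vals


def qsea_table(
    embryos: Iterable[EmbryoRecord],
    metric: str,
    offsets_min: np.ndarray | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Wide assay table: one row per embryo, one column per offset (min)."""
    offsets = QSEA_OFFSETS_MIN if offsets_min is None else np.asarray(offsets_min)
    rows = {}
    for e in embryos:
        if metric not in e.trajectories:
            raise KeyError(f"embryo {e.embryo_id} has no {metric!r} trajectory")
        rows[e.embryo_id] = sample_qsea(e.trajectories[metric], e.timings["tB"], offsets, strict)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[int(o) for o in offsets])
    df.index.name = "embryo_id"
    return df


def qsea_table_from_long(
    trajectories: pd.DataFrame,
    cohort: pd.DataFrame,
    metric: str,
    offsets_min: np.ndarray | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Wide assay table from a long-format trajectory table.

    ``trajectories`` needs columns embryo_id / metric / time_hpi / value;
    ``cohort`` supplies tB per embryo.
    """
    for col in ("embryo_id", "metric", "time_hpi", "value"):
        if col not in trajectories.columns:
            raise ValueError(f"trajectory table is missing column {col!r}")
    sub = trajectories[trajectories["metric"] == metric]
    if sub.empty:
        raise ValueError(f"trajectory table has no rows for metric {metric!r}")
    tb = cohort.set_index("embryo_id")["tB"]
    offsets = QSEA_OFFSETS_MIN if offsets_min is None else np.asarray(offsets_min)
    rows = {}
    for eid, grp in sub.groupby("embryo_id", sort=True):
        grp = grp.sort_values("time_hpi")
        ts = MetricTimeSeries(metric, grp["time_hpi"].to_numpy(), grp["value"].to_numpy())
        rows[eid] = sample_qsea(ts, float(tb.loc[eid]), offsets, strict)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[int(o) for o in offsets])
    df.index.name = "embryo_id"
    return df


def percent_change(v_from: float, v_to: float) -> float:
    """(v_to − v_from) / v_from × 100."""
    if v_from <= 0:
        raise ValueError("percent change needs a positive reference value")
    return (v_to - v_from) / v_from * 100.0


def milestone_metrics(
    ts: MetricTimeSeries, timings: dict[str, float], strict: bool = True
) -> dict[str, float]:
    """Metric values at each milestone plus the three percent changes.

    tSB precedes the series start by generator convention; its value is
    reported as the earliest available frame value (the tB anchor).
    """
    t_order = [timings[k] for k in ("tSB", "tB", "tEB", "t_biopsy")]
    if not all(a <= b for a, b in zip(t_order, t_order[1:])):
        raise ValueError("timings must be ordered tSB <= tB <= tEB <= t_biopsy")
    if strict and (timings["tB"] < ts.times[0] - 1e-9 or timings["t_biopsy"] > ts.times[-1] + 1e-9):
        raise CoverageError("series does not cover [tB, t_biopsy]")
    out: dict[str, float] = {"at_tSB": float(ts.values[0])}
    for ms in MILESTONES:
        out[f"at_{ms}"] = ts.value_at(timings[ms])
    out["pct_tEB_tB"] = percent_change(out["at_tB"], out["at_tEB"])
    out["pct_tbiopsy_tEB"] = percent_change(out["at_tEB"], out["at_t_biopsy"])
    out["pct_tbiopsy_tB"] = percent_change(out["at_tB"], out["at_t_biopsy"])
    return out


def milestone_table(embryos: Iterable[EmbryoRecord], metrics: Iterable[str] | None = None) -> pd.DataFrame:
    """One row per embryo × metric with milestone values and percent changes."""
    rows = []
    for e in embryos:
        names = list(e.trajectories) if metrics is None else list(metrics)
        for metric in names:
            rec = milestone_metrics(e.trajectories[metric], e.timings)
            rec.update(embryo_id=e.embryo_id, metric=metric)
            rows.append(rec)
    cols = [
        "embryo_id", "metric", "at_tSB", "at_tB", "at_tEB", "at_t_biopsy",
        "pct_tEB_tB", "pct_tbiopsy_tEB", "pct_tbiopsy_tB",
    ]
    return pd.DataFrame(rows, columns=cols)


def build_expansion_map(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Per-offset group means, SDs, ns and two-sided p-values.

    Inputs are wide assay tables (embryo × offset) on the same offset
    grid.  P-values come from the normality-gated two-group test and are
    reported unadjusted, with a Holm-adjusted column alongside (11
    correlated tests are performed).  Offsets where either group has
    fewer than 2 values raise.
    """
    if list(group_a.columns) != list(group_b.columns):
        raise ValueError("groups are on different offset grids")
    offsets = [int(c) for c in group_a.columns]
    standard = offsets == [int(o) for o in QSEA_OFFSETS_MIN]
    rows = []
    pvals = []
    for col in group_a.columns:
        x = group_a[col].dropna().to_numpy(dtype=float)
        y = group_b[col].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"fewer than 2 embryos in a group at offset {col}")
        res = compare_groups(x, y, continuous=True)
        pvals.append(res.p_value)
        rows.append(
            {
                "offset_min": int(col),
                f"mean_{labels[0]}": float(x.mean()),
                f"sd_{labels[0]}": float(x.std(ddof=1)),
                f"n_{labels[0]}": len(x),
                f"mean_{labels[1]}": float(y.mean()),
                f"sd_{labels[1]}": float(y.std(ddof=1)),
                f"n_{labels[1]}": len(y),
                "test": res.test_name,
                "p": res.p_value,
            }
        )
    reject_holm, p_holm, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    df = pd.DataFrame(rows)
    df["p_holm"] = p_holm
    df["significant"] = df["p"] < alpha
    df["significant_holm"] = reject_holm
    df.attrs["alpha"] = alpha
    df.attrs["standard_grid"] = bool(standard)
    df.attrs["clustering_correction"] = "none"
    if not standard:
        df.attrs["grid_note"] = "non-standard offset grid"
    return df


def earliest_significant_offset(expansion_map: pd.DataFrame, adjusted: bool = False) -> int | None:
    """First offset (min) with p below alpha, or None.  Uses the unadjusted
    column by default, mirroring how the maps are read."""
    col = "significant_holm" if adjusted else "significant"
    hits = expansion_map.loc[expansion_map[col], "offset_min"]
    return int(hits.iloc[0]) if len(hits) else None
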