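"""From measured objects to analysis-ready C/N trajectories.

Covers the quality filters on measured ROIs, the per-cell
cytoplasmic/nuclear (C/N) ratio, alignment of staggered well acquisition
times onto a common grid by linear interpolation, baseline normalization
against the two pre-stimulation time points, the summed-AUC response
measure, and stratification of cells by their starting C/N ratio.

Time points are 1-based throughout. With the default timing model (3.5 min
frame interval, stimulation during time point 7), time points 9-18 span
7.0-38.5 min post-stimulation, which is the response window used for both
AUC and clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimingModel:
    """Acquisition timing: per-frame interval and per-well stagger (minutes)."""

    frame_interval: float = 3.5
    well_offset: float = 0.5
    stim_timepoint: int = 7            # 1-based; ligand added during this tp
    baseline_timepoints: tuple[int, int] = (5, 6)
    auc_window: tuple[int, int] = (9, 18)

    def __post_init__(self) -> None:
        if max(self.baseline_timepoints) >= self.stim_timepoint:
            raise ValueError("baseline time points must precede stimulation")

    def acquisition_time(self, timepoint, well=1):
        """Actual acquisition minutes for (1-based) timepoint in a given well."""
        return (np.asarray(timepoint) - 1) * self.frame_interval \
            + (np.asarray(well) - 1) * self.well_offset

    def grid_time(self, timepoint):
        """Nominal (well-1) grid minutes for a 1-based timepoint."""
        return (np.asarray(timepoint) - 1) * self.frame_interval


def poststim_minutes(tp, timing: TimingModel | None = None) -> float:
    """Minutes post-stimulation of a 1-based time point: (tp - stim_tp) * interval."""
    if timing is None:
        timing = TimingModel()
    return (np.asarray(tp) - timing.stim_timepoint) * timing.frame_interval


def qc_filter(features: pd.DataFrame, int_lo: float = 260.0, int_hi: float = 4000.0,
              area_min: float = 100.0, radius_min: float = 1.0,
              intensity_cols: list[str] | None = None) -> pd.DataFrame:
    """Exclude ROIs failing the intensity, area and radius gates.

    Kept: int_lo <= every listed mean intensity <= int_hi, area >= area_min,
    mean_radius > radius_min. Defaults are the ~260/~4000 count window, the
    100 px area floor and the mean-radius > 1 sliver filter.
    """
    if intensity_cols is None:
        intensity_cols = [c for c in features.columns if c.startswith("mean_")
                          and c != "mean_radius"]
    keep = (features["area"] >= area_min) & (features["mean_radius"] > radius_min)
    for c in intensity_cols:
        keep &= (features[c] >= int_lo) & (features[c] <= int_hi)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("qc_filter: excluded %d of %d ROIs", n_drop, len(features))
    return features[keep].reset_index(drop=True)


def compute_cn(features: pd.DataFrame, erk_channel: str = "erk",
               akt_channel: str = "akt") -> pd.DataFrame:
    """Per-cell, per-frame C/N ratio: cytoplasmic mean / nuclear mean.

    ``features`` must carry track_id, frame, compartment and
    mean_<channel> columns with paired nucleus/cytoplasm rows. Cells whose
    nuclear mean is 0 at any frame are dropped with a logged reason.
    Returns columns: cell_id (= track_id), timepoint (1-based = frame + 1),
    cn_erk, cn_akt.
    """
    cols = [f"mean_{erk_channel}", f"mean_{akt_channel}"]
    nuc = features[features["compartment"] == "nucleus"].set_index(["track_id", "frame"])
    cyt = features[features["compartment"] == "cytoplasm"].set_index(["track_id", "frame"])
    common = nuc.index.intersection(cyt.index)
    nuc, cyt = nuc.loc[common], cyt.loc[common]
    bad = nuc.index[(nuc[cols] == 0).any(axis=1)].get_level_values(0).unique()
    if len(bad):
        logger.warning("compute_cn: dropping %d cells with zero nuclear mean", len(bad))
    out = pd.DataFrame({
        "cell_id": common.get_level_values(0),
        "timepoint": common.get_level_values(1) + 1,
        "cn_erk": (cyt[f"mean_{erk_channel}"] / nuc[f"mean_{erk_channel}"]).to_numpy(),
        "cn_akt": (cyt[f"mean_{akt_channel}"] / nuc[f"mean_{akt_channel}"]).to_numpy(),
    })
    out = out[~out["cell_id"].isin(bad)]
    return out.sort_values(["cell_id", "timepoint"]).reset_index(drop=True)


def align_and_interpolate(traj: pd.DataFrame, timing: TimingModel | None = None,
                          value_cols: tuple[str, ...] = ("cn_erk", "cn_akt")) -> pd.DataFrame:
    """Interpolate each cell's series onto the well-1 nominal time grid.

    A cell in well w was actually acquired at (tp-1)*interval +
    (w-1)*well_offset minutes; values are linearly interpolated at the
    well-1 grid times. Grid points outside a cell's observed span are
    dropped for that cell (no extrapolation); cells with fewer than two
    observations are dropped.
    """
    if timing is None:
        timing = TimingModel()
    traj = traj.copy()
    if "well" not in traj.columns:
        traj["well"] = 1
    tps = np.sort(traj["timepoint"].unique())
    grid = np.asarray(timing.grid_time(tps), dtype=float)

    meta_cols = [c for c in traj.columns
                 if c not in ("timepoint", "time_min", *value_cols)]
    out = []
    for cell, g in traj.groupby("cell_id", sort=True):
        g = g.sort_values("timepoint")
        if len(g) < 2:
            logger.info("align_and_interpolate: dropping cell %s (<2 points)", cell)
            continue
        t_obs = np.asarray(timing.acquisition_time(g["timepoint"], g["well"]), dtype=float)
        inside = (grid >= t_obs[0]) & (grid <= t_obs[-1])
        block = pd.DataFrame({"timepoint": tps[inside], "time_min": grid[inside]})
        for c in value_cols:
            block[c] = np.interp(grid[inside], t_obs, g[c].to_numpy())
        for c in meta_cols:
            block[c] = g[c].iloc[0]
        out.append(block)
    if not out:
        return traj.iloc[0:0]
    res = pd.concat(out, ignore_index=True)
    front = ["cell_id", "timepoint", "time_min"]
    return res[front + [c for c in res.columns if c not in front]]


def normalize_baseline(traj: pd.DataFrame, baseline: tuple[int, int] = (5, 6),
                       value_cols: tuple[str, ...] = ("cn_erk", "cn_akt")) -> pd.DataFrame:
    """Subtract each cell's mean C/N at the baseline time points.

    Adds cn_norm_* columns and start_ratio_* columns (the subtracted mean).
    Cells missing either baseline point are dropped. The normalized values
    at the two baseline points average to exactly 0 per cell.
    """
    traj = traj.copy()
    base = traj[traj["timepoint"].isin(baseline)]
    counts = base.groupby("cell_id")["timepoint"].nunique()
    ok = counts[counts == len(set(baseline))].index
    dropped = traj["cell_id"].nunique() - len(ok)
    if dropped:
        logger.info("normalize_baseline: dropping %d cells missing baseline points", dropped)
    traj = traj[traj["cell_id"].isin(ok)]
    base = base[base["cell_id"].isin(ok)]
    means = base.groupby("cell_id")[list(value_cols)].mean()
    for c in value_cols:
        kin = c.removeprefix("cn_")
        m = traj["cell_id"].map(means[c])
        traj[f"cn_norm_{kin}"] = traj[c] - m
        traj[f"start_ratio_{kin}"] = m
    return traj.reset_index(drop=True)


def auc(traj: pd.DataFrame, window: tuple[int, int] = (9, 18),
        value_cols: tuple[str, ...] = ("cn_norm_erk", "cn_norm_akt")) -> pd.DataFrame:
    """Summed response per cell: plain sum of normalized C/N over the window.

    The AUC is the sum of the samples at time points ``window[0]..window[1]``
    inclusive (10 points by default), not a trapezoid integral. Cells not
    covering the full window are excluded.
    """
    lo, hi = window
    n_expected = hi - lo + 1
    win = traj[(traj["timepoint"] >= lo) & (traj["timepoint"] <= hi)]
    counts = win.groupby("cell_id")["timepoint"].nunique()
    ok = counts[counts == n_expected].index
    excluded = traj["cell_id"].nunique() - len(ok)
    if excluded:
        logger.info("auc: excluding %d cells with incomplete window", excluded)
    win = win[win["cell_id"].isin(ok)]
    out = win.groupby("cell_id")[list(value_cols)].sum()
    out.columns = [c.replace("cn_norm", "auc") for c in out.columns]
    meta = [c for c in ("well", "condition", "concentration", "replicate",
                        "truth_label", "start_ratio_erk", "start_ratio_akt")
            if c in traj.columns]
    if meta:
        first = traj.groupby("cell_id")[meta].first()
        out = out.join(first)
    return out.reset_index()


DEFAULT_START_BINS = ((0.15, 0.35), (0.35, 0.60), (0.60, 1.00))


def stratify_by_start_ratio(summary: pd.DataFrame,
                            bins=DEFAULT_START_BINS,
                            ratio_col: str = "start_ratio_erk") -> pd.DataFrame:
    """Assign cells to half-open start-ratio pools [lo, hi).

    Default pools: low 0.15-0.35, middle 0.35-0.60, high 0.60-1.00. Cells
    outside every bin get pool = NaN. Overlapping bins are rejected.
    """
    edges = sorted(bins)
    for (l1, h1), (l2, h2) in zip(edges[:-1], edges[1:]):
        if l2 < h1:
            raise ValueError("start-ratio bins must not overlap")
    out = summary.copy()
    pool = np.full(len(out), np.nan, dtype=object)
    for i, (lo, hi) in enumerate(bins):
        sel = (out[ratio_col] >= lo) & (out[ratio_col] < hi)
        pool[sel.to_numpy()] = i
    out["start_pool"] = pool
    return out


def trajectory_matrix(traj: pd.DataFrame, kinase: str = "erk",
                      window: tuple[int, int] = (9, 18)):
    """Cells x window matrix of normalized C/N, for clustering.

    Returns (matrix, cell_ids); only cells covering the full window appear.
    """
    col = f"cn_norm_{kinase}"
    lo, hi = window
    win = traj[(traj["timepoint"] >= lo) & (traj["timepoint"] <= hi)]
    wide = win.pivot_table(index="cell_id", columns="timepoint", values=col)
    wide = wide.dropna(axis=0)
    wide = wide.reindex(columns=range(lo, hi + 1))
    return wide.to_numpy(), wide.index.to_numpy()
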