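"""End-to-end glue: image stack -> tracked C/N trajectory table -> analyses."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import imageprep, segmentation, tracking, trajectories
from .config import PipelineConfig
from .trajectories import TimingModel

logger = logging.getLogger(__name__)


def timing_model(config: PipelineConfig) -> TimingModel:
    t = config.timing
    return TimingModel(frame_interval=t.frame_interval, well_offset=t.well_offset,
                       stim_timepoint=t.stim_timepoint,
                       baseline_timepoints=tuple(t.baseline_timepoints),
                       auc_window=tuple(t.auc_window))


def extract_trajectories(stack: np.ndarray, config: PipelineConfig | None = None,
                         well: int = 1) -> pd.DataFrame:
    """Raw (T, C, H, W) stack -> per-cell C/N table (cell_id, timepoint, cn_*).

    Runs preprocessing, per-frame segmentation/measurement, QC filtering,
    nucleus tracking, complete-track filtering and the C/N ratio. Only
    cells surviving every stage appear in the output.
    """
    if config is None:
        config = PipelineConfig()
    ip, sg, tk, qc = config.imageprep, config.segmentation, config.tracking, config.qc

    nuc, akt, erk, masks = imageprep.preprocess_stack(
        stack, nuclear_subtract=ip.subtract_c,
        akt_ball_radius=ip.rolling_ball_radius, mask_sigma=ip.mask_sigma,
        mask_lo=ip.mask_lo, mask_hi=ip.mask_hi)
    features = segmentation.segment_stack(
        nuc, masks, {"akt": akt, "erk": erk},
        threshold=sg.nuclear_threshold, d_min=sg.diameter_min,
        d_max=sg.diameter_max, expand_px=sg.expand_px)
    features = trajectories.qc_filter(
        features, int_lo=qc.intensity_lo, int_hi=qc.intensity_hi,
        area_min=qc.area_min, radius_min=qc.radius_min)

    n_frames = stack.shape[0]
    nuc_feats = features[features["compartment"] == "nucleus"]
    tracked_nuc = tracking.link_objects(nuc_feats, max_dist=tk.max_link_dist)
    tracked_nuc = tracking.filter_complete_tracks(tracked_nuc, n_frames)
    # carry the nucleus track ids onto the paired cytoplasm rows (same object id)
    key = tracked_nuc.set_index(["frame", "object_id"])["track_id"]
    cyto = features[features["compartment"] == "cytoplasm"].copy()
    idx = pd.MultiIndex.from_frame(cyto[["frame", "object_id"]])
    cyto["track_id"] = key.reindex(idx).to_numpy()
    cyto = cyto.dropna(subset=["track_id"])
    cyto["track_id"] = cyto["track_id"].astype(int)
    # a complete cell needs its cytoplasm in every frame too
    full = cyto.groupby("track_id")["frame"].nunique()
    keep = full[full == n_frames].index
    cyto = cyto[cyto["track_id"].isin(keep)]
    tracked_nuc = tracked_nuc[tracked_nuc["track_id"].isin(keep)]

    both = pd.concat([tracked_nuc, cyto], ignore_index=True)
    cn = trajectories.compute_cn(both)
    cn["well"] = well
    # first-frame nucleus centroid per track, for matching against ground truth
    first = (tracked_nuc.sort_values("frame").groupby("track_id")[["x", "y"]].first())
    cn["x0"] = cn["cell_id"].map(first["x"])
    cn["y0"] = cn["cell_id"].map(first["y"])
    return cn


def analyze_trajectories(cn: pd.DataFrame, config: PipelineConfig | None = None):
    """C/N table -> interpolated, normalized trajectories plus per-cell summary."""
    if config is None:
        config = PipelineConfig()
    timing = timing_model(config)
    traj = trajectories.align_and_interpolate(cn, timing)
    traj = trajectories.normalize_baseline(traj, timing.baseline_timepoints)
    summary = trajectories.auc(traj, timing.auc_window)
    summary = trajectories.stratify_by_start_ratio(summary)
    return traj, summary
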