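"""Synthetic ground-truthed data for the KTR analysis pipeline.

Generates per-cell cytoplasmic/nuclear (C/N) ratio trajectories with a
known response structure, dose series with a planted EC50, and renderable
multi-channel time-lapse image stacks, so that every downstream stage
(segmentation, tracking, trajectory processing, dose-response fitting,
clustering) can be verified against planted truth.

Response archetypes mimic the qualitative single-cell shapes seen in
GPCR-stimulated ERK/Akt reporter data: flat (non-responding), low,
transient (peak ~10 min post-stimulation), sustained (pulse decaying to a
plateau), and biphasic (second peak ~35 min, S1P-like).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ARCHETYPE_IDS = ("flat", "low", "transient", "sustained", "biphasic")


@dataclass(frozen=True)
class Archetype:
    """Noiseless response shape of one cell class.

    Parameters are in minutes post-stimulation; ``amplitude`` is the peak
    baseline-relative C/N change (dimensionless).
    """

    id: str
    amplitude: float
    rise_time: float = 5.0
    decay_time: float = 25.0
    second_peak_delay: float = 25.0  # biphasic only; second peak ~35 min
    plateau_fraction: float = 0.6    # sustained only

    def __post_init__(self) -> None:
        if self.id not in ARCHETYPE_IDS:
            raise ValueError(f"unknown archetype id {self.id!r}; expected one of {ARCHETYPE_IDS}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.id == "flat" and self.amplitude != 0:
            raise ValueError("flat archetype must have amplitude 0")


def default_archetypes() -> dict[str, Archetype]:
    """The five default archetypes with unit-scale amplitudes."""
    return {
        "flat": Archetype("flat", 0.0),
        "low": Archetype("low", 0.12),
        "transient": Archetype("transient", 0.5),
        "sustained": Archetype("sustained", 0.45),
        "biphasic": Archetype("biphasic", 0.4),
    }


def _pulse(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials pulse, normalized to unit peak, 0 for t<=0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    raw = np.exp(-tp / decay) - np.exp(-tp / rise)
    # analytic peak location / height of the unnormalized pulse
    t_star = math.log(decay / rise) * rise * decay / (decay - rise)
    peak = math.exp(-t_star / decay) - math.exp(-t_star / rise)
    out[pos] = raw / peak
    return out


def archetype_waveform(archetype: Archetype, t_post_stim) -> np.ndarray | float:
    """Noiseless baseline-relative C/N change at ``t_post_stim`` minutes.

    Returns 0 for all t <= 0 (stimulus not yet applied); continuous in t.
    Scales linearly with ``archetype.amplitude``.
    """
    scalar = np.isscalar(t_post_stim)
    t = np.atleast_1d(np.asarray(t_post_stim, dtype=float))
    a = archetype
    if a.id == "flat":
        y = np.zeros_like(t)
    elif a.id in ("low", "transient"):
        y = a.amplitude * _pulse(t, a.rise_time, a.decay_time)
    elif a.id == "sustained":
        p = a.plateau_fraction
        plateau = np.where(t > 0, 1.0 - np.exp(-np.maximum(t, 0.0) / a.rise_time), 0.0)
        y = a.amplitude * ((1.0 - p) * _pulse(t, a.rise_time, a.decay_time) + p * plateau)
    elif a.id == "biphasic":
        y = a.amplitude * (
            _pulse(t, a.rise_time, a.decay_time)
            + 0.8 * _pulse(t - a.second_peak_delay, a.rise_time, a.decay_time)
        )
    else:  # pragma: no cover - guarded in Archetype
        raise ValueError(f"unknown archetype id {a.id!r}")
    return float(y[0]) if scalar else y


@dataclass
class SynthConfig:
    """Study conditions for the trajectory generator.

    Defaults follow the imaging protocol the analysis assumes: 3.5 min frame
    interval, ligand addition during (1-based) time point 7, baseline C/N
    ratios spread evenly between 0.20 and 0.75.
    """

    n_cells: int = 100                 # per archetype
    noise_sd: float = 0.02             # additive Gaussian, C/N units
    baseline_low: float = 0.20
    baseline_high: float = 0.75
    amplitude_cv: float = 0.25         # lognormal cell-to-cell heterogeneity
    frame_interval: float = 3.5        # minutes
    n_timepoints: int = 20
    stim_timepoint: int = 7            # 1-based
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_low < self.baseline_high:
            raise ValueError("baseline_low must be < baseline_high")
        if self.n_timepoints < 18:
            raise ValueError("n_timepoints must be >= 18 so the tp 9-18 window exists")


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def generate_trajectories(
    config: SynthConfig,
    mix: list[Archetype] | None = None,
    *,
    condition: str = "synthetic",
    concentration: float = float("nan"),
    well: int = 1,
) -> pd.DataFrame:
    """Generate a tidy per-cell-per-timepoint trajectory table with truth labels.

    C/N(t) = baseline + amplitude_jitter * waveform(t - t_stim) + N(0, noise_sd),
    identically for the ERK and Akt channels (independent noise draws).
    Columns: cell_id, well, condition, concentration, timepoint (1-based),
    time_min, cn_erk, cn_akt, truth_label.
    """
    if mix is None:
        mix = list(default_archetypes().values())
    if config.n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    rng = np.random.default_rng(config.seed)
    tps = np.arange(1, config.n_timepoints + 1)
    time_min = (tps - 1) * config.frame_interval
    t_post = time_min - (config.stim_timepoint - 1) * config.frame_interval

    rows = []
    cell_id = 0
    for arch in mix:
        base = rng.uniform(config.baseline_low, config.baseline_high, size=config.n_cells)
        amps = arch.amplitude * _lognormal_factors(rng, config.n_cells, config.amplitude_cv)
        unit = archetype_waveform(dataclasses.replace(arch, amplitude=1.0) if arch.amplitude else arch,
                                  t_post)
        if arch.amplitude:
            unit = np.asarray(unit)
        else:
            unit = np.zeros_like(t_post)
        for i in range(config.n_cells):
            wav = amps[i] * unit
            cn_erk = base[i] + wav + rng.normal(0.0, config.noise_sd, size=len(tps))
            cn_akt = base[i] + wav + rng.normal(0.0, config.noise_sd, size=len(tps))
            rows.append(pd.DataFrame({
                "cell_id": cell_id,
                "well": well,
                "condition": condition,
                "concentration": concentration,
                "timepoint": tps,
                "time_min": time_min,
                "cn_erk": cn_erk,
                "cn_akt": cn_akt,
                "truth_label": arch.id,
            }))
            cell_id += 1
    return pd.concat(rows, ignore_index=True)


def hill_response(conc: np.ndarray | float, ec50: float, hill: float, top: float) -> np.ndarray | float:
    """Stimulatory Hill curve with lower asymptote 0: top / (1 + (ec50/x)^hill)."""
    return top / (1.0 + (ec50 / np.asarray(conc, dtype=float)) ** hill)


def generate_dose_series(
    ec50: float,
    hill: float,
    top: float,
    concentrations: list[float],
    n_cells: int,
    seed: int,
    *,
    config: SynthConfig | None = None,
    amplitude_cv: float | None = None,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Trajectory table across a concentration series with planted EC50.

    Each concentration gets ``n_cells`` transient-archetype cells per
    replicate, whose mean peak amplitude equals the Hill curve value at that
    concentration; cell-to-cell amplitude jitter is mean-preserving
    lognormal. The downstream AUC is linear in amplitude, so the AUC
    concentration-response curve inherits the planted EC50.
    """
    if len(concentrations) == 0:
        raise ValueError("concentration list must not be empty")
    if np.any(np.asarray(concentrations, dtype=float) <= 0):
        raise ValueError("concentrations must be > 0")
    if config is None:
        config = SynthConfig()
    cv = config.amplitude_cv if amplitude_cv is None else amplitude_cv
    tables = []
    offset = 0
    for rep in range(1, n_replicates + 1):
        for j, conc in enumerate(concentrations):
            mean_amp = float(hill_response(conc, ec50, hill, top))
            arch = Archetype("transient", mean_amp) if mean_amp > 0 else Archetype("flat", 0.0)
            sub = dataclasses.replace(
                config, n_cells=n_cells, amplitude_cv=cv,
                seed=(config.seed + 7919 * rep + 31 * j + seed) % (2**31),
            )
            tab = generate_trajectories(sub, [arch], condition="dose", concentration=conc)
            tab["cell_id"] = tab["cell_id"] + offset
            tab["replicate"] = rep
            offset = int(tab["cell_id"].max()) + 1
            tables.append(tab)
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# Image rendering


@dataclass
class RenderConfig:
    """Geometry and intensity settings for the time-lapse renderer.

    Nuclear diameters must lie in the 8-20 px range the segmentation gate
    expects; intensities are 12-bit counts. The KTR-channel nuclear level is
    chosen so that cytoplasmic intensities stay above the downstream ~260
    count QC floor for the baseline C/N range.
    """

    shape: tuple[int, int] = (420, 420)
    nucleus_diameter_range: tuple[float, float] = (12.0, 16.0)
    ring_width: float = 5.0            # cytoplasm annulus width, px (>= 3)
    nuclear_intensity: float = 900.0   # nuclear-marker channel, nucleus pixels
    nuclear_background: float = 100.0  # must be < 330 segmentation threshold
    ktr_nuclear_intensity: float = 1500.0
    ktr_background: float = 0.0
    jitter_px: float = 1.0             # max per-frame centroid displacement
    poisson_noise: bool = False
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.nucleus_diameter_range
        if lo < 8 or hi > 20:
            warnings.warn(
                "nucleus diameters outside [8, 20] px will be filtered by the "
                "downstream segmentation size gate", stacklevel=2)


@dataclass
class RenderResult:
    """Rendered stack plus planted truth."""

    stack: np.ndarray                 # (T, C, H, W) uint16, 12-bit data
    nucleus_masks: np.ndarray         # (T, H, W) int32 label images (truth)
    cytoplasm_masks: np.ndarray       # (T, H, W) int32 label images (truth)
    centroids: np.ndarray             # (T, n_cells, 2) float (row, col)
    truth: pd.DataFrame               # the trajectory table that was rendered
    channel_roles: tuple[str, str, str] = ("nuclear", "akt", "erk")


def _place_cells(rng: np.random.Generator, n_cells: int, shape: tuple[int, int],
                 radius: np.ndarray, ring: float, jitter: float) -> np.ndarray:
    """Initial centers on a jittered grid so cells never overlap."""
    margin = radius.max() + ring + jitter + 2
    pitch = 2 * margin + 2
    nx = int((shape[1] - 2 * margin) // pitch)
    ny = int((shape[0] - 2 * margin) // pitch)
    if nx * ny < n_cells:
        raise ValueError(
            f"field {shape} fits only {nx * ny} non-overlapping cells; "
            f"{n_cells} requested")
    slots = [(margin + (iy + 0.5) * pitch, margin + (ix + 0.5) * pitch)
             for iy in range(ny) for ix in range(nx)]
    idx = rng.choice(len(slots), size=n_cells, replace=False)
    return np.asarray([slots[i] for i in idx], dtype=float)


def render_timelapse(truth: pd.DataFrame, config: RenderConfig | None = None,
                     seed: int = 0) -> RenderResult:
    """Render a trajectory table into a 3-channel 12-bit time-lapse stack.

    Channel 0 is the nuclear marker (nucleus pixels above, background below,
    the 330-count segmentation threshold).  Channels 1 (Akt) and 2 (ERK) set
    nucleus and cytoplasm mean intensities so their ratio equals the planted
    C/N at each frame.  Per-frame centroid jitter is uniform within
    ``jitter_px``.  Output is clipped to the 12-bit range [0, 4095].
    """
    if config is None:
        config = RenderConfig()
    rng = np.random.default_rng(seed)
    cells = truth["cell_id"].unique()
    n_cells = len(cells)
    tps = np.sort(truth["timepoint"].unique())
    n_t = len(tps)
    H, W = config.shape

    dlo, dhi = config.nucleus_diameter_range
    radius = rng.uniform(dlo, dhi, size=n_cells) / 2.0
    centers0 = _place_cells(rng, n_cells, config.shape, radius,
                            config.ring_width, config.jitter_px)

    cn = {k: truth.pivot_table(index="cell_id", columns="timepoint", values=f"cn_{k}")
          .loc[cells, tps].to_numpy() for k in ("akt", "erk")}

    stack = np.zeros((n_t, 3, H, W), dtype=float)
    nuc_masks = np.zeros((n_t, H, W), dtype=np.int32)
    cyto_masks = np.zeros((n_t, H, W), dtype=np.int32)
    centroids = np.zeros((n_t, n_cells, 2), dtype=float)

    yy, xx = np.mgrid[0:H, 0:W]
    for ti in range(n_t):
        if config.jitter_px > 0 and ti > 0:
            ang = rng.uniform(0, 2 * np.pi, size=n_cells)
            r = rng.uniform(0, config.jitter_px, size=n_cells)
            centers = centers0 + np.column_stack([r * np.sin(ang), r * np.cos(ang)])
        else:
            centers = centers0
        frame = np.zeros((3, H, W), dtype=float)
        frame[0] += config.nuclear_background
        frame[1] += config.ktr_background
        frame[2] += config.ktr_background
        for ci in range(n_cells):
            cy, cx = centers[ci]
            centroids[ti, ci] = (cy, cx)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            nuc = d2 <= radius[ci] ** 2
            cell = d2 <= (radius[ci] + config.ring_width) ** 2
            ring = cell & ~nuc
            nuc_masks[ti][nuc] = ci + 1
            cyto_masks[ti][ring] = ci + 1
            frame[0][nuc] = config.nuclear_intensity
            for ch, kin in ((1, "akt"), (2, "erk")):
                frame[ch][nuc] = config.ktr_nuclear_intensity
                frame[ch][ring] = config.ktr_nuclear_intensity * cn[kin][ci, ti]
        if config.poisson_noise:
            frame = rng.poisson(np.maximum(frame, 0)).astype(float)
        if config.read_noise_sd > 0:
            frame += rng.normal(0, config.read_noise_sd, size=frame.shape)
        stack[ti] = frame

    stack = np.clip(np.round(stack), 0, 4095).astype(np.uint16)
    return RenderResult(stack=stack, nucleus_masks=nuc_masks,
                        cytoplasm_masks=cyto_masks, centroids=centroids,
                        truth=truth)


def write_render(result: RenderResult, tiff_path, truth_yaml_path=None) -> None:
    """Write the stack as a multi-page TIFF (TCYX) with a ground-truth sidecar."""
    import tifffile
    tifffile.imwrite(tiff_path, result.stack, photometric="minisblack",
                     metadata={"axes": "TCYX"})
    if truth_yaml_path is not None:
        import yaml
        meta = {
            "channel_roles": list(result.channel_roles),
            "n_cells": int(result.centroids.shape[1]),
            "n_timepoints": int(result.stack.shape[0]),
            "truth_labels": result.truth.groupby("cell_id")["truth_label"]
                                        .first().to_dict(),
        }
        with open(truth_yaml_path, "w") as fh:
            yaml.safe_dump(meta, fh)
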