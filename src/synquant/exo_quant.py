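"""Stimulated-exocytosis quantification.

Two routes to the same biology: pHluorin time traces, normalized so the
basal epoch maps to 0 and the NH4Cl dequench plateau to 1, with

    % exocytosis = 100 * (stim_mean - basal_mean) / (nh4cl_mean - basal_mean)

and TIRF movies, where single fusion events appear as spreading flashes of
fluorescence and are counted automatically as thresholded spatiotemporal
local maxima of the background-subtracted stack.

Window conventions (configurable): the basal window is the whole pre-
stimulation epoch; the "averaged stimulated fluorescence" window is the
final 60 s before NH4Cl addition (the stimulated plateau); the NH4Cl
window is 30 s starting 10 s after NH4Cl addition, skipping the mixing
transient.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateTraceError, InvalidAnnotationError
from .types import EventList, ExoResult, TimeSeriesTrace, TirfMovie

__all__ = [
    "default_windows",
    "normalize_trace",
    "percent_exocytosis",
    "spontaneous_release",
    "compare_bafilomycin",
    "detect_events",
    "cumulative_event_curve",
]

STIM_PLATEAU_S = 60.0     # stimulated window: final 60 s before NH4Cl
NH4CL_SKIP_S = 10.0       # skip the NH4Cl mixing transient
NH4CL_WINDOW_S = 30.0
MIN_WINDOW_SAMPLES = 3


def _robust_sd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def default_windows(trace: TimeSeriesTrace,
                    stim_window: Optional[tuple] = None,
                    basal_window: Optional[tuple] = None,
                    nh4cl_window: Optional[tuple] = None) -> tuple:
    """Resolve (basal, stim, nh4cl) window intervals from annotations."""
    if trace.t_stim is None or trace.t_nh4cl is None:
        raise InvalidAnnotationError("trace needs t_stim and t_nh4cl annotations")
    if basal_window is None:
        basal_window = (float(trace.times[0]), trace.t_stim)
    if stim_window is None:
        stim_window = (trace.t_nh4cl - STIM_PLATEAU_S, trace.t_nh4cl)
    if nh4cl_window is None:
        nh4cl_window = (trace.t_nh4cl + NH4CL_SKIP_S,
                        trace.t_nh4cl + NH4CL_SKIP_S + NH4CL_WINDOW_S)
    return basal_window, stim_window, nh4cl_window


def _window_mean(trace: TimeSeriesTrace, window: tuple, label: str) -> float:
    vals = trace.window(*window)
    if vals.size < MIN_WINDOW_SAMPLES:
        raise InvalidAnnotationError(
            f"{label} window {window} holds {vals.size} samples; need >= {MIN_WINDOW_SAMPLES}")
    return float(vals.mean())


def _check_dynamic_range(trace: TimeSeriesTrace, basal_window: tuple,
                         basal_mean: float, nh4cl_mean: float) -> None:
    # A dead or inverted cell has nothing to normalize: require the NH4Cl
    # plateau to clear the basal level by 5 robust basal SDs (and strictly).
    basal_vals = trace.window(*basal_window)
    guard = 5.0 * _robust_sd(basal_vals)
    if nh4cl_mean <= basal_mean + guard or nh4cl_mean <= basal_mean:
        raise DegenerateTraceError(
            f"NH4Cl mean {nh4cl_mean:.4g} does not exceed basal {basal_mean:.4g} "
            f"by 5 robust SDs ({guard:.4g}); trace is flat or inverted")


def normalize_trace(trace: TimeSeriesTrace,
                    basal_window: Optional[tuple] = None,
                    nh4cl_window: Optional[tuple] = None) -> TimeSeriesTrace:
    """Rescale a trace so the basal-window mean maps to 0 and the NH4Cl-
    window mean to 1: (value(t) - basal) / (nh4cl - basal)."""
    basal_window, _, nh4cl_window = default_windows(
        trace, basal_window=basal_window, nh4cl_window=nh4cl_window)
    basal_mean = _window_mean(trace, basal_window, "basal")
    nh4cl_mean = _window_mean(trace, nh4cl_window, "NH4Cl")
    _check_dynamic_range(trace, basal_window, basal_mean, nh4cl_mean)
    return trace.with_values((trace.values - basal_mean) / (nh4cl_mean - basal_mean))


def percent_exocytosis(trace: TimeSeriesTrace,
                       stim_window: Optional[tuple] = None,
                       basal_window: Optional[tuple] = None,
                       nh4cl_window: Optional[tuple] = None) -> ExoResult:
    """Percent exocytosis from the three window means.

    Negative values (noisy controls) are clipped to 0 and flagged; values
    above 100 are retained and flagged.
    """
    basal_window, stim_window, nh4cl_window = default_windows(
        trace, stim_window, basal_window, nh4cl_window)
    basal_mean = _window_mean(trace, basal_window, "basal")
    stim_mean = _window_mean(trace, stim_window, "stimulated")
    nh4cl_mean = _window_mean(trace, nh4cl_window, "NH4Cl")
    _check_dynamic_range(trace, basal_window, basal_mean, nh4cl_mean)
    pct = 100.0 * (stim_mean - basal_mean) / (nh4cl_mean - basal_mean)
    clipped = pct < 0
    if clipped:
        warnings.warn("negative percent exocytosis clipped to 0", stacklevel=2)
        pct = 0.0
    exceeds = pct > 100.0
    if exceeds:
        warnings.warn("percent exocytosis exceeds 100; retained and flagged",
                      stacklevel=2)
    return ExoResult(pct_exocytosis=float(pct), basal_mean=basal_mean,
                     stim_mean=stim_mean, nh4cl_mean=nh4cl_mean,
                     basal_window=basal_window, stim_window=stim_window,
                     nh4cl_window=nh4cl_window,
                     clipped_negative=bool(clipped), exceeds_100=bool(exceeds))


def spontaneous_release(trace: TimeSeriesTrace,
                        pre_stim_window: Optional[tuple] = None,
                        basal_window: Optional[tuple] = None,
                        nh4cl_window: Optional[tuple] = None) -> float:
    """Percent release attributable to pre-stimulus drift.

    The percent-exocytosis formula is applied with the pre-stimulus drift
    window substituted for the stimulated window.  By default the drift
    window is the final 60 s before stimulation and the basal reference is
    the first 20 s of the trace; a well-behaved sample stays under a few
    percent.
    """
    if trace.t_stim is None or trace.t_nh4cl is None:
        raise InvalidAnnotationError("trace needs t_stim and t_nh4cl annotations")
    t0 = float(trace.times[0])
    if pre_stim_window is None:
        pre_stim_window = (max(t0, trace.t_stim - 60.0), trace.t_stim)
    if basal_window is None:
        if trace.window(t0, pre_stim_window[0]).size >= MIN_WINDOW_SAMPLES:
            basal_window = (t0, pre_stim_window[0])
        else:
            # pre-stim epoch too short to hold both windows: split it
            mid = 0.5 * (t0 + trace.t_stim)
            basal_window = (t0, mid)
            pre_stim_window = (mid, trace.t_stim)
    res = percent_exocytosis(trace, stim_window=pre_stim_window,
                             basal_window=basal_window, nh4cl_window=nh4cl_window)
    return res.pct_exocytosis


def compare_bafilomycin(baf_trace: TimeSeriesTrace,
                        control_trace: TimeSeriesTrace, **window_kwargs) -> dict:
    """Compare percent exocytosis with and without proton-pump inhibition.

    A bafilomycin-treated trace (annotated with ``t_baf``) blocks vesicle
    reacidification; its percent exocytosis exceeding the untreated
    control's indicates endocytic re-uptake during the measurement.
    """
    if baf_trace.t_baf is None:
        raise InvalidAnnotationError("bafilomycin trace must carry a t_baf annotation")
    pct_baf = percent_exocytosis(baf_trace, **window_kwargs).pct_exocytosis
    pct_ctrl = percent_exocytosis(control_trace, **window_kwargs).pct_exocytosis
    return {"pct_bafilomycin": pct_baf, "pct_control": pct_ctrl,
            "difference": pct_baf - pct_ctrl}


# ---------------------------------------------------------------------------
# TIRF event detection
# ---------------------------------------------------------------------------

def detect_events(movie: TirfMovie,
                  threshold_sd: float = 5.0,
                  smooth_sigma_px: float = 1.5,
                  exclusion_radius: tuple = (3, 4),
                  median_window: int = 11,
                  persistence_fraction: float = 0.25) -> EventList:
    """Detect exocytic flashes as spatiotemporal local maxima.

    Pipeline: per-pixel rolling temporal median -> background subtraction
    -> per-frame Gaussian smoothing -> 3-D local maxima above
    ``threshold_sd`` robust (MAD-based) SDs -> persistence check (a
    spreading flash decays over several frames so it is still elevated one
    frame after onset, while a single-frame noise spike is not) -> greedy
    deduplication within ``exclusion_radius`` = (frames, px), keeping the
    brightest.  On a noise-free stack (robust SD 0) the threshold falls
    back to 5% of the peak residual so flashes are still the only
    detections.
    """
    if movie.n_frames < median_window:
        raise ValueError(
            f"movie has {movie.n_frames} frames; rolling median needs >= {median_window}")
    frames = movie.frames
    background = ndimage.median_filter(frames, size=(median_window, 1, 1))
    residual = frames - background
    smoothed = ndimage.gaussian_filter(
        residual, sigma=(0.0, smooth_sigma_px, smooth_sigma_px))
    sd = _robust_sd(smoothed.ravel())
    threshold = threshold_sd * sd
    if threshold <= 0:
        peak = float(smoothed.max())
        if peak <= 0:
            return EventList(_empty_events(), params=_detect_params(locals()))
        threshold = 0.05 * peak

    dt, dx = exclusion_radius
    footprint = (2 * dt + 1, 2 * dx + 1, 2 * dx + 1)
    local_max = (smoothed == ndimage.maximum_filter(smoothed, size=footprint))
    # The smoothed estimate is unreliable within the filter support of the
    # image border (reflection padding inflates noise there); exclude it.
    border = int(np.ceil(3 * smooth_sigma_px))
    valid = np.zeros_like(local_max)
    valid[:, border:-border or None, border:-border or None] = True
    candidates = np.argwhere(local_max & valid & (smoothed > threshold))
    if len(candidates) and persistence_fraction > 0:
        # a spreading flash is still elevated one frame after onset; a
        # single-frame noise spike leaves only independent noise there
        keep = []
        for t0, r0, c0 in candidates:
            if t0 + 1 >= smoothed.shape[0]:
                continue
            follow = smoothed[t0 + 1, r0, c0]
            if follow >= persistence_fraction * smoothed[t0, r0, c0] and \
                    follow >= 0.5 * threshold:
                keep.append((t0, r0, c0))
        candidates = np.array(keep, dtype=int).reshape(-1, 3)
    if len(candidates):
        amps = smoothed[tuple(candidates.T)]
        order = np.argsort(amps)[::-1]
        kept: list = []
        for idx in order:
            t0, r0, c0 = candidates[idx]
            if all(abs(t0 - t1) > dt or np.hypot(r0 - r1, c0 - c1) > dx
                   for (t1, r1, c1, _) in kept):
                kept.append((t0, r0, c0, float(amps[idx])))
        kept.sort()
    else:
        kept = []
    events = pd.DataFrame(
        [(t0 * movie.frame_interval, int(t0), float(r0), float(c0), a)
         for (t0, r0, c0, a) in kept],
        columns=["t", "frame", "row", "col", "amplitude"],
    )
    if events.empty:
        events = _empty_events()
    return EventList(events, params=_detect_params(dict(
        threshold_sd=threshold_sd, smooth_sigma_px=smooth_sigma_px,
        exclusion_radius=exclusion_radius, median_window=median_window,
        threshold=threshold)))


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=["t", "frame", "row", "col", "amplitude"])


def _detect_params(d: dict) -> dict:
    keep = ("threshold_sd", "smooth_sigma_px", "exclusion_radius",
            "median_window", "threshold")
    return {k: d[k] for k in keep if k in d}


def cumulative_event_curve(events: EventList, bin_width: float,
                           t_stim: float, duration: float) -> tuple:
    """Cumulative event count vs time, plus the mean stimulated release rate.

    Returns (bin_edges, cumulative_counts, rate) where the nondecreasing
    step curve ends at len(events) and rate = final count / stimulated
    epoch duration (events/s).
    """
    if duration <= t_stim:
        raise ValueError("duration must exceed t_stim")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(0.0, duration + bin_width / 2, bin_width)
    t = events.events["t"].to_numpy(dtype=float) if len(events) else np.array([])
    counts, _ = np.histogram(t, bins=edges)
    cumulative = np.cumsum(counts)
    rate = float(len(events)) / (duration - t_stim)
    return edges, cumulative, rate
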