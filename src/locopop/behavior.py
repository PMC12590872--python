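"""Movement-bout segmentation and behavioral summaries from wheel velocity.

Motion onsets/offsets are defined by velocity-threshold criteria evaluated
in 2 s windows: an onset is a timepoint preceded by 2 s of velocity below
0.09 cm/s and followed by 2 s in which velocity exceeds 0.35 cm/s at least
once; an offset mirrors this (2 s with an excursion above 0.30 cm/s before,
2 s below 0.09 cm/s after).  Same-type events closer than 2 s keep only the
earlier one.  Motion timepoints run from each onset to the earliest later
frame whose centered 0.7 s mean velocity falls below 0.09 cm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionThresholds",
    "BoutSet",
    "detect_motion_events",
    "motion_mask",
    "session_summary",
    "speed_event_rate_curve",
    "bout_kinematic_similarity",
]


@dataclass(frozen=True)
class MotionThresholds:
    """Velocity thresholds (cm/s) and window lengths (s) for bout detection."""

    onset_pre_max: float = 0.09
    onset_post_min: float = 0.35
    offset_pre_min: float = 0.30
    offset_post_max: float = 0.09
    window_s: float = 2.0
    stop_window_s: float = 0.7
    stop_thresh: float = 0.09
    min_separation_s: float = 2.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.stop_window_s <= 0:
            raise ValueError("window lengths must be positive")
        for name in ("onset_pre_max", "onset_post_min", "offset_pre_min",
                     "offset_post_max", "stop_thresh", "min_separation_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class BoutSet:
    """Detected motion onsets/offsets and the per-frame motion mask."""

    onsets: np.ndarray
    offsets: np.ndarray
    motion_mask: np.ndarray
    n_frames: int
    frame_rate_hz: float

    def times(self, which: str = "onsets") -> np.ndarray:
        """Event times in seconds (frame / frame rate)."""
        return np.asarray(getattr(self, which), float) / self.frame_rate_hz


def _validate_velocity(velocity: np.ndarray) -> np.ndarray:
    v = np.asarray(velocity, dtype=float)
    if v.ndim != 1:
        raise ValueError("velocity must be one-dimensional")
    if np.isnan(v).any():
        raise ValueError("velocity contains NaN")
    if not np.isfinite(v).all():
        raise ValueError("velocity contains non-finite values")
    if (v < 0).any():
        raise ValueError("velocity must be non-negative speed; rectify on load")
    return v


def _transition_candidates(v: np.ndarray, thresh: float, direction: str) -> np.ndarray:
    """First frames of runs crossing `thresh` upward ('rise') or downward ('fall')."""
    above = v >= thresh
    if direction == "rise":
        hits = above[1:] & ~above[:-1]
    else:
        hits = ~above[1:] & above[:-1]
    return np.flatnonzero(hits) + 1


def _enforce_separation(events: np.ndarray, min_sep: int) -> np.ndarray:
    """Among same-type events closer than min_sep frames, keep the earlier."""
    kept: list[int] = []
    for t in events:
        if not kept or t - kept[-1] >= min_sep:
            kept.append(int(t))
    return np.asarray(kept, dtype=int)


def detect_motion_events(
    velocity: np.ndarray,
    frame_rate_hz: float,
    thresholds: MotionThresholds | None = None,
) -> BoutSet:
    """Segment a wheel-velocity trace into motion onsets and offsets.

    Candidates are threshold transitions (first frame of a run at/above
    ``onset_pre_max`` for onsets; first frame of a run below
    ``offset_post_max`` for offsets).  Each candidate is verified against
    the 2 s pre/post window criteria; candidates whose windows extend past
    the trace ends are excluded, and same-type events closer than
    ``min_separation_s`` drop the later one.  Onsets and offsets are
    detected independently: a bout may contribute only one of the two.

    Parameters
    ----------
    velocity
        Wheel speed in cm/s, one value per imaging frame, non-negative.
    frame_rate_hz
        Sampling rate of the trace (imaging frame rate).
    thresholds
        Detection thresholds; defaults follow the printed criteria.

    Returns
    -------
    BoutSet
        Onset/offset frame indices plus the motion mask.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    th = thresholds or MotionThresholds()
    v = _validate_velocity(velocity)
    W = int(round(th.window_s * frame_rate_hz))
    n = len(v)
    if n <= 2 * W:
        warnings.warn("velocity trace shorter than twice the criterion window; "
                      "returning empty BoutSet", stacklevel=2)
        empty = np.empty(0, dtype=int)
        return BoutSet(empty, empty, np.zeros(n, bool), n, frame_rate_hz)

    onset_cand = _transition_candidates(v, th.onset_pre_max, "rise")
    offset_cand = _transition_candidates(v, th.offset_post_max, "fall")

    onsets = [
        int(t) for t in onset_cand
        if t - W >= 0 and t + W <= n
        and np.all(v[t - W:t] < th.onset_pre_max)
        and np.max(v[t:t + W]) > th.onset_post_min
    ]
    offsets = [
        int(t) for t in offset_cand
        if t - W >= 0 and t + W <= n
        and np.max(v[t - W:t]) > th.offset_pre_min
        and np.all(v[t:t + W] < th.offset_post_max)
    ]
    sep = int(round(th.min_separation_s * frame_rate_hz))
    onsets_arr = _enforce_separation(np.asarray(onsets, int), sep)
    offsets_arr = _enforce_separation(np.asarray(offsets, int), sep)
    mask = motion_mask(v, onsets_arr, frame_rate_hz, th)
    return BoutSet(onsets_arr, offsets_arr, mask, n, frame_rate_hz)


def _centered_window_mean(v: np.ndarray, length: int) -> np.ndarray:
    """Centered moving mean with windows shrinking at the trace edges."""
    out = np.convolve(v, np.ones(length) / length, mode="same")
    h = length // 2
    for i in range(h):
        out[i] = v[: i + h + 1].mean()
        out[-(i + 1)] = v[len(v) - (i + h + 1):].mean()
    return out


def stop_window_frames(stop_window_s: float, frame_rate_hz: float) -> int:
    """Odd frame count for the stop-detection window (0.7 s -> 17 at 25 Hz)."""
    return 2 * int(stop_window_s * frame_rate_hz / 2) + 1


def motion_mask(
    velocity: np.ndarray,
    onsets: np.ndarray,
    frame_rate_hz: float,
    thresholds: MotionThresholds | None = None,
) -> np.ndarray:
    """Per-frame motion classification.

    For each onset, frames from the onset up to (exclusive) the earliest
    later frame whose centered ``stop_window_s`` mean velocity falls below
    ``stop_thresh`` are motion; everything else is non-motion.
    """
    th = thresholds or MotionThresholds()
    v = np.asarray(velocity, float)
    mask = np.zeros(len(v), dtype=bool)
    if len(onsets) == 0:
        return mask
    L = stop_window_frames(th.stop_window_s, frame_rate_hz)
    wmean = _centered_window_mean(v, L)
    for onset in np.asarray(onsets, int):
        below = np.flatnonzero(wmean[onset + 1:] < th.stop_thresh)
        stop = onset + 1 + below[0] if len(below) else len(v)
        mask[onset:stop] = True
    return mask


def session_summary(velocity: np.ndarray, motion: np.ndarray) -> tuple[float, float]:
    """Session mean velocity (cm/s) and fraction of frames spent in motion."""
    v = np.asarray(velocity, float)
    m = np.asarray(motion, bool)
    if len(v) != len(m):
        raise ValueError("velocity and motion mask must have equal length")
    return float(v.mean()), float(m.mean())


def speed_event_rate_curve(
    event_frames: list[np.ndarray],
    velocity: np.ndarray,
    speed_bin_edges: np.ndarray,
    frame_rate_hz: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean Ca2+ event rate (events/s) as a function of locomotion speed.

    Per neuron, the event rate in a speed bin is the number of events whose
    frame velocity falls in the bin divided by the time spent in the bin;
    the returned curve averages rates across neurons.  Bins with zero
    occupancy are NaN (flagged with a warning, never silently zero).

    Returns
    -------
    (rates, occupancy_s)
        Mean rate per bin and the session's occupancy of each bin in seconds.
    """
    v = np.asarray(velocity, float)
    edges = np.asarray(speed_bin_edges, float)
    nbins = len(edges) - 1
    which_bin = np.digitize(v, edges) - 1
    occupancy = np.array([(which_bin == b).sum() for b in range(nbins)], float)
    occupancy_s = occupancy / frame_rate_hz
    if (occupancy == 0).any():
        warnings.warn("speed bins with zero occupancy flagged as NaN", stacklevel=2)
    rates = np.zeros((len(event_frames), nbins))
    for i, ev in enumerate(event_frames):
        ev = np.asarray(ev, int)
        counts = np.array([(which_bin[ev] == b).sum() for b in range(nbins)], float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates[i] = np.where(occupancy_s > 0, counts / occupancy_s, np.nan)
    mean_rates = rates.mean(axis=0) if len(event_frames) else np.full(nbins, np.nan)
    return mean_rates, occupancy_s


def _resample_trajectory(xy: np.ndarray, length: int) -> np.ndarray:
    xy = np.asarray(xy, float)
    t_old = np.linspace(0.0, 1.0, len(xy))
    t_new = np.linspace(0.0, 1.0, length)
    return np.column_stack([np.interp(t_new, t_old, xy[:, d]) for d in range(2)])


def bout_kinematic_similarity(paw_xy: list[np.ndarray]) -> float:
    """Average pairwise Pearson correlation of per-bout paw trajectories.

    Trajectories (T x 2 arrays of X-Y paw position) are linearly resampled
    to the median bout length; Pearson correlation is computed per dimension
    for every bout pair and averaged over pairs and dimensions.  Pairs with
    a constant trajectory in some dimension are skipped with a warning.
    """
    if len(paw_xy) < 2:
        raise ValueError("need at least two bouts")
    length = int(np.median([len(b) for b in paw_xy]))
    bouts = [_resample_trajectory(b, length) for b in paw_xy]
    corrs: list[float] = []
    for i in range(len(bouts)):
        for j in range(i + 1, len(bouts)):
            for d in range(2):
                a, b = bouts[i][:, d], bouts[j][:, d]
                if a.std() == 0 or b.std() == 0:
                    warnings.warn("constant trajectory; bout pair skipped",
                                  stacklevel=2)
                    continue
                corrs.append(float(np.corrcoef(a, b)[0, 1]))
    if not corrs:
        raise ValueError("no valid bout pairs")
    return float(np.mean(corrs))
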