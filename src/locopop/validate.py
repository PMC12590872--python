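"""Recovery metrics against synthetic ground truth.

Matching is greedy within a frame tolerance.  Event matching optionally
removes a constant latency first (the median detected-minus-true lag),
since a peak-based event-time convention trails the transient start by a
fixed, kernel-dependent delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RecoveryScore", "match_events", "event_recovery", "bout_recovery"]


@dataclass
class RecoveryScore:
    """Precision/recall of detected against planted events."""

    true_positives: int
    n_detected: int
    n_true: int

    @property
    def precision(self) -> float:
        return self.true_positives / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return self.true_positives / self.n_true if self.n_true else 1.0


def match_events(detected: np.ndarray, true: np.ndarray, tol_frames: int = 1,
                 latency_correct: bool = False) -> RecoveryScore:
    """Greedy one-to-one matching of detected to true frames within a tolerance."""
    det = np.sort(np.asarray(detected, int))
    tru = np.sort(np.asarray(true, int))
    if len(det) == 0 or len(tru) == 0:
        return RecoveryScore(0, len(det), len(tru))
    if latency_correct:
        lags = [det[np.argmin(np.abs(det - e))] - e for e in tru]
        det = det - int(np.median(lags))
    used = np.zeros(len(det), bool)
    tp = 0
    for e in tru:
        cand = np.flatnonzero((np.abs(det - e) <= tol_frames) & ~used)
        if len(cand):
            used[cand[0]] = True
            tp += 1
    return RecoveryScore(tp, len(det), len(tru))


def event_recovery(detected_trains: list[np.ndarray],
                   true_trains: list[np.ndarray],
                   tol_frames: int = 1) -> RecoveryScore:
    """Pooled latency-corrected precision/recall over a population.

    The latency is estimated per neuron (median lag), so the score reflects
    timing jitter, not the detector's fixed peak-time convention.
    """
    tp = nd = nt = 0
    for det, tru in zip(detected_trains, true_trains):
        s = match_events(det, tru, tol_frames, latency_correct=True)
        tp += s.true_positives
        nd += s.n_detected
        nt += s.n_true
    return RecoveryScore(tp, nd, nt)


def bout_recovery(boutset, true_onsets: np.ndarray, true_offsets: np.ndarray,
                  tol_frames: int = 2) -> dict[str, RecoveryScore]:
    """Precision/recall of detected motion onsets and offsets (no latency)."""
    return {
        "onsets": match_events(boutset.onsets, true_onsets, tol_frames),
        "offsets": match_events(boutset.offsets, true_offsets, tol_frames),
    }
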