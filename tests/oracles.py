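"""Slow, independent reference implementations used only by the tests.

These deliberately avoid the package's vectorized code paths: criteria are
checked frame by frame with explicit loops, and expectations are computed
by exhaustive enumeration, so they can serve as oracles for the fast
implementations.
"""

import math

import numpy as np


def verify_motion_events(velocity, onsets, offsets, rate,
                         onset_pre_max=0.09, onset_post_min=0.35,
                         offset_pre_min=0.30, offset_post_max=0.09,
                         window_s=2.0, min_sep_s=2.0):
    """Frame-by-frame check that every emitted event satisfies the printed
    velocity-threshold criteria, stays clear of the trace edges, and that
    same-type events respect the 2 s separation rule."""
    W = int(round(window_s * rate))
    sep = int(round(min_sep_s * rate))
    n = len(velocity)
    for t in onsets:
        assert t - W >= 0 and t + W <= n, f"onset {t} window out of bounds"
        for f in range(t - W, t):
            assert velocity[f] < onset_pre_max, f"onset {t}: pre-frame {f} fast"
        assert any(velocity[f] > onset_post_min for f in range(t, t + W)), \
            f"onset {t}: no post-window excursion"
    for t in offsets:
        assert t - W >= 0 and t + W <= n, f"offset {t} window out of bounds"
        assert any(velocity[f] > offset_pre_min for f in range(t - W, t)), \
            f"offset {t}: no pre-window excursion"
        for f in range(t, t + W):
            assert velocity[f] < offset_post_max, f"offset {t}: post-frame {f} fast"
    for ev in (onsets, offsets):
        for a, b in zip(ev[:-1], ev[1:]):
            assert b - a >= sep, f"events {a},{b} violate separation"


def first_stop_frame(velocity, onset, rate, stop_window_s=0.7, stop_thresh=0.09):
    """Earliest frame after an onset whose centered-window mean velocity
    drops below the stop threshold, by direct evaluation of every window."""
    L = 2 * int(stop_window_s * rate / 2) + 1
    h = L // 2
    n = len(velocity)
    for f in range(onset + 1, n):
        lo, hi = max(0, f - h), min(n, f + h + 1)
        if np.mean(velocity[lo:hi]) < stop_thresh:
            return f
    return n


def exact_shuffle_jaccard_mean(n, na, nb):
    """E[J] for independently permuted binary vectors with na and nb actives:
    the overlap is hypergeometric; sum k/(na+nb-k) over its pmf."""
    total = 0.0
    for k in range(max(0, na + nb - n), min(na, nb) + 1):
        p = (math.comb(na, k) * math.comb(n - na, nb - k)) / math.comb(n, nb)
        union = na + nb - k
        total += p * (k / union if union > 0 else 0.0)
    return total


def exact_shuffle_jaccard_sd(n, na, nb):
    """SD of the shuffled Jaccard index, by the same enumeration."""
    m = exact_shuffle_jaccard_mean(n, na, nb)
    total = 0.0
    for k in range(max(0, na + nb - n), min(na, nb) + 1):
        p = (math.comb(na, k) * math.comb(n - na, nb - k)) / math.comb(n, nb)
        union = na + nb - k
        j = k / union if union > 0 else 0.0
        total += p * (j - m) ** 2
    return math.sqrt(total)


def adjusted_r2_closed_form(r2, n, p):
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def best_single_predictor(X, y):
    """Exhaustive scan: index of the column with the highest squared
    correlation with y (the optimal size-1 support for OLS)."""
    best, best_c = -1, -1.0
    for j in range(X.shape[1]):
        xj = X[:, j]
        if xj.std() == 0:
            continue
        c = np.corrcoef(xj, y)[0, 1] ** 2
        if c > best_c:
            best_c, best = c, j
    return best
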