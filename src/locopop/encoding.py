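"""Peri-event velocity decoding, N-neuron curves, and encoding efficiency.

The decoder concatenates 4 s windows around all motion onsets (or offsets)
of a day into a design matrix (rows = frames, columns = neurons) and fits
ordinary least squares to predict wheel velocity, leave-one-bout-out
cross-validated (k = number of bouts).  Performance is the adjusted R² of
the pooled held-out predictions:  R²_adj = 1 − (1−R²)(n−1)/(n−p−1).
N-neuron information curves refit the decoder on supports of size
N ∈ {2,4,8,...} chosen by LASSO with the penalty tuned (path search plus
bisection) until the support size equals N.  The efficiency score
interpolates the monotone (isotonic) fit of the N-curve at the day's
active-neuron count and divides by that count: information encoded per
neuron activated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import Lasso, lasso_path

__all__ = [
    "PeriEventDesign",
    "FitResult",
    "build_perievent_design",
    "fit_velocity_model",
    "adjusted_r2",
    "lasso_select_n",
    "n_neuron_curve",
    "efficiency_score",
    "DEFAULT_NS",
]

DEFAULT_NS = (2, 4, 8, 16, 32, 64, 128)


@dataclass
class PeriEventDesign:
    """Concatenated peri-event windows: predictors, target, bout grouping."""

    X: np.ndarray            # (n_events * window_frames) x n_neurons
    y: np.ndarray            # velocity, cm/s, frame-aligned to X rows
    bout_index: np.ndarray   # bout id per row
    window_frames: int
    events: np.ndarray       # retained event frames

    @property
    def n_bouts(self) -> int:
        return len(np.unique(self.bout_index))


@dataclass
class FitResult:
    """Cross-validated decoding performance."""

    r2: float
    adj_r2: float
    n: int
    p: int
    k: int
    ridge_fallback: bool = False


def build_perievent_design(
    dff: np.ndarray,
    velocity: np.ndarray,
    events: np.ndarray,
    frame_rate_hz: float,
    window_s: float = 4.0,
) -> PeriEventDesign:
    """Assemble the peri-event design matrix for one day and action type.

    Windows are centered, inclusive of both endpoints (101 frames for 4 s
    at 25 Hz); events whose window crosses a session edge are dropped with
    a warning.  Rows are ordered by event time, frames in window order.
    """
    x = np.atleast_2d(np.asarray(dff, float))
    v = np.asarray(velocity, float)
    half = int(round(window_s / 2 * frame_rate_hz))
    ev = np.asarray(events, int)
    kept = ev[(ev - half >= 0) & (ev + half < x.shape[1])]
    if len(kept) < len(ev):
        warnings.warn(f"dropped {len(ev) - len(kept)} edge events", stacklevel=2)
    if len(kept) == 0:
        raise ValueError("no events with a full in-session window")
    w = 2 * half + 1
    X = np.concatenate([x[:, e - half:e + half + 1].T for e in kept], axis=0)
    y = np.concatenate([v[e - half:e + half + 1] for e in kept])
    bout = np.repeat(np.arange(len(kept)), w)
    return PeriEventDesign(X, y, bout, w, kept)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 − (1−R²)(n−1)/(n−p−1); the small-sample-corrected R²."""
    if n - p - 1 <= 0:
        raise ValueError("adjusted R² undefined for n - p - 1 <= 0")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _cv_predictions(X: np.ndarray, y: np.ndarray, bout_index: np.ndarray,
                    alpha: float = 0.0) -> np.ndarray:
    """Pooled leave-one-bout-out predictions via Gram-matrix downdating.

    The full normal equations are assembled once; each fold subtracts its
    own rows' contribution, which is much cheaper than refitting from
    scratch when folds are small relative to the design.
    """
    A = np.column_stack([np.ones(len(X)), X])
    G = A.T @ A
    c = A.T @ y
    reg = alpha * np.eye(A.shape[1])
    reg[0, 0] = 0.0  # never penalize the intercept
    yhat = np.empty_like(y)
    for b in np.unique(bout_index):
        te = bout_index == b
        Ab = A[te]
        Gb = G - Ab.T @ Ab + reg
        cb = c - Ab.T @ y[te]
        try:
            coef = np.linalg.solve(Gb, cb)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(Gb, cb, rcond=None)
        yhat[te] = Ab @ coef
    return yhat


def fit_velocity_model(
    design: PeriEventDesign,
    columns: np.ndarray | None = None,
    ridge_alpha: float = 1.0,
) -> FitResult:
    """Leave-one-bout-out cross-validated adjusted R² of the linear decoder.

    One fold per bout: OLS is fit on the remaining bouts' frames and
    predicts the held-out bout; R² pools all held-out predictions.  When
    the predictor count reaches the pooled row count (p >= n-1) the OLS
    problem is degenerate and a fixed-penalty ridge fit is substituted,
    flagged in the result (adjusted R² is then reported as NaN since its
    denominator is non-positive).
    """
    X = design.X if columns is None else design.X[:, np.asarray(columns, int)]
    y = design.y
    if design.n_bouts < 2:
        raise ValueError("need at least two bouts for cross-validation")
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("constant velocity target; R² undefined")
    n, p = X.shape
    fallback = p >= n - 1
    alpha = ridge_alpha if fallback else 0.0
    if fallback:
        warnings.warn("p >= n-1: ridge-regularized fallback fit", stacklevel=2)
    yhat = _cv_predictions(X, y, design.bout_index, alpha)
    r2 = 1.0 - ((y - yhat) ** 2).sum() / sst
    adj = adjusted_r2(r2, n, p) if n - p - 1 > 0 else float("nan")
    return FitResult(float(r2), float(adj), n, p, design.n_bouts, fallback)


def _standardized(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    return np.where(sd > 0, (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)


def _selection_problem(design: PeriEventDesign):
    Xs = _standardized(design.X)
    yc = design.y - design.y.mean()
    return Xs, yc


def _coarse_path(Xs: np.ndarray, yc: np.ndarray, alpha_max: float):
    alphas = alpha_max * np.logspace(0, -4, 60)
    _, coefs, _ = lasso_path(Xs, yc, alphas=alphas)
    return alphas, coefs


def lasso_select_n(design: PeriEventDesign, n_select: int,
                   max_bisect: int = 40, _path=None) -> np.ndarray:
    """Choose a neuron support of size N by tuning the LASSO penalty.

    Predictors are standardized for selection only.  A coarse penalty path
    brackets the target support size, then bisection refines it; if no
    penalty yields exactly N nonzero coefficients (the support jumps past
    N), the nearest achievable support is trimmed by coefficient magnitude
    or padded by marginal correlation, with a warning.
    """
    p = design.X.shape[1]
    if n_select > p:
        raise ValueError("cannot select more neurons than available")
    if n_select == p:
        return np.arange(p)
    Xs, yc = _selection_problem(design)
    n_rows = len(yc)
    alpha_max = np.max(np.abs(Xs.T @ yc)) / n_rows
    if alpha_max == 0:
        warnings.warn("target uncorrelated with all predictors; "
                      "selecting by variance", stacklevel=2)
        return np.argsort(design.X.std(axis=0))[::-1][:n_select]

    alphas, coefs = _path if _path is not None else _coarse_path(Xs, yc, alpha_max)
    sizes = (np.abs(coefs) > 1e-12).sum(axis=0)
    exact = np.flatnonzero(sizes == n_select)
    if len(exact):
        return np.flatnonzero(np.abs(coefs[:, exact[0]]) > 1e-12)

    # bracket the jump and bisect
    above = np.flatnonzero(sizes > n_select)
    below = np.flatnonzero(sizes < n_select)
    lo = alphas[above[0]] if len(above) else alphas[-1] / 10
    hi = alphas[below[-1]] if len(below) else alphas[0]
    best_supp, best_gap = None, np.inf
    for _ in range(max_bisect):
        mid = np.sqrt(lo * hi)
        model = Lasso(alpha=mid, max_iter=5000, tol=1e-6).fit(Xs, yc)
        supp = np.flatnonzero(np.abs(model.coef_) > 1e-12)
        gap = abs(len(supp) - n_select)
        if gap < best_gap or (gap == best_gap and len(supp) > n_select):
            best_gap, best_supp, best_coef = gap, supp, model.coef_
        if len(supp) == n_select:
            return supp
        if len(supp) > n_select:
            lo = mid
        else:
            hi = mid
    warnings.warn(f"no penalty gives support {n_select}; nearest is "
                  f"{len(best_supp)}, trimmed/padded", stacklevel=2)
    if len(best_supp) > n_select:
        order = np.argsort(np.abs(best_coef[best_supp]))[::-1]
        return np.sort(best_supp[order[:n_select]])
    score = np.abs(Xs.T @ yc)
    score[best_supp] = -np.inf
    pad = np.argsort(score)[::-1][: n_select - len(best_supp)]
    return np.sort(np.concatenate([best_supp, pad]))


def n_neuron_curve(
    design: PeriEventDesign,
    ns: tuple[int, ...] = DEFAULT_NS,
) -> dict[int, FitResult]:
    """Adjusted R² of the decoder restricted to LASSO-selected N neurons.

    For each N (values above the neuron count are skipped with a warning),
    the support comes from :func:`lasso_select_n` and the decoder is refit
    by unpenalized OLS on the raw predictors with the same
    leave-one-bout-out cross-validation.
    """
    p = design.X.shape[1]
    Xs, yc = _selection_problem(design)
    alpha_max = np.max(np.abs(Xs.T @ yc)) / len(yc)
    path = _coarse_path(Xs, yc, alpha_max) if alpha_max > 0 else None
    out: dict[int, FitResult] = {}
    for n_sel in ns:
        if n_sel > p:
            warnings.warn(f"N={n_sel} exceeds neuron count {p}; skipped",
                          stacklevel=2)
            continue
        support = lasso_select_n(design, n_sel, _path=path)
        out[n_sel] = fit_velocity_model(design, columns=support)
    return out


def efficiency_score(
    curve: dict[int, float] | dict[int, FitResult],
    n_active: int,
) -> float:
    """Decoding R² at the day's active-neuron count, per active neuron.

    A monotone saturating fit (isotonic regression over the N-curve,
    linearly interpolated between N values, plateau-extrapolated beyond)
    is evaluated at ``n_active``; the score divides that R² by
    ``n_active`` — information encoded per neuron activated.
    """
    if n_active < 1:
        raise ValueError("n_active must be at least 1")
    if not curve:
        raise ValueError("empty N-neuron curve")
    ns = np.array(sorted(curve), float)
    vals = np.array([curve[int(n)].adj_r2 if isinstance(curve[int(n)], FitResult)
                     else curve[int(n)] for n in ns], float)
    iso = IsotonicRegression(increasing=True).fit(ns, vals)
    fitted = iso.predict(ns)
    if n_active > ns[-1]:
        warnings.warn("n_active beyond the largest N; plateau extrapolation",
                      stacklevel=2)
    r2_hat = float(np.interp(n_active, ns, fitted))
    return r2_hat / n_active
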