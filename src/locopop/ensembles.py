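"""Per-bout ensemble vectors and longitudinal ensemble statistics.

An ensemble vector marks, for one movement bout, which neurons exceeded
3 SD within a 2 s window centered on the bout's onset (or offset).
Similarity between two ensembles is the Jaccard index normalized to its
mean over 1000 independent shuffles of the two vectors (each shuffle
permutes a vector's entries, preserving its active count), so chance-level
similarity maps to ~1.  Fate overlap quantifies how much of the late
(days 7-8) ensemble was already active early (days 1-2); action bias
scores each late-ensemble neuron +1/-1/0 by its early onset/offset
activity; the action-separability score is the silhouette of onset vs
offset bouts after PCA (8 components) and a 2-D Chebyshev-metric t-SNE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

__all__ = [
    "SimilarityResult",
    "FateResult",
    "activation_vector",
    "activation_matrix",
    "bout_activation_proportions",
    "fate_overlap",
    "action_bias",
    "ensemble_similarity",
    "similarity_by_day",
    "separability_matrix",
    "separability_score",
]


@dataclass
class SimilarityResult:
    """Raw and shuffle-normalized Jaccard similarity for one ensemble pair."""

    raw: float
    shuffle_mean: float
    normalized: float
    n_shuffles: int


@dataclass
class FateResult:
    """Early-to-late ensemble reactivation overlap with its permutation null."""

    observed_pct: float
    shuffle_mean_pct: float
    p_value: float
    n_late: int
    n_shuffles: int


def activation_vector(
    dff: np.ndarray,
    event_frame: int,
    frame_rate_hz: float,
    window_s: float = 2.0,
    active_thresh_sd: float = 3.0,
) -> np.ndarray:
    """Binary per-neuron activation for one bout.

    Entry i is 1 iff neuron i's standardized dF/F exceeds the threshold at
    any frame of the ``window_s`` window centered on the event (+-1 s by
    default — narrower than the +-2 s typing window; the two conventions
    are deliberately distinct parameters).
    """
    x = np.atleast_2d(np.asarray(dff, float))
    half = int(round(window_s / 2 * frame_rate_hz))
    if event_frame - half < 0 or event_frame + half >= x.shape[1]:
        raise ValueError("event window extends past the session edge")
    win = x[:, event_frame - half:event_frame + half + 1]
    return (win.max(axis=1) > active_thresh_sd).astype(np.int8)


def activation_matrix(
    dff: np.ndarray,
    event_frames: np.ndarray,
    frame_rate_hz: float,
    window_s: float = 2.0,
    active_thresh_sd: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack activation vectors for a list of bouts (edge bouts dropped).

    Returns (bouts x neurons binary matrix, retained event frames).
    """
    rows, kept = [], []
    for e in np.asarray(event_frames, int):
        try:
            rows.append(activation_vector(dff, e, frame_rate_hz, window_s,
                                          active_thresh_sd))
        except ValueError:
            continue
        kept.append(e)
    n_neurons = np.atleast_2d(dff).shape[0]
    mat = np.array(rows, np.int8) if rows else np.empty((0, n_neurons), np.int8)
    return mat, np.asarray(kept, int)


def bout_activation_proportions(
    dff: np.ndarray,
    event_frames: np.ndarray,
    frame_rate_hz: float,
    k: int = 8,
    window_s: float = 2.0,
    active_thresh_sd: float = 3.0,
) -> np.ndarray:
    """Proportion of neurons active on each of the first ``k`` bouts.

    Sessions with fewer than ``k`` valid bouts yield a truncated curve
    (with a warning).
    """
    mat, _ = activation_matrix(dff, np.asarray(event_frames, int)[:k],
                               frame_rate_hz, window_s, active_thresh_sd)
    if mat.shape[0] < k:
        warnings.warn(f"only {mat.shape[0]} of {k} requested bouts available",
                      stacklevel=2)
    return mat.mean(axis=1) if mat.size else np.empty(0)


def ensemble_similarity(
    vec_a: np.ndarray,
    vec_b: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> SimilarityResult:
    """Shuffle-normalized Jaccard similarity of two binary ensemble vectors.

    The raw Jaccard index |A∩B|/|A∪B| is divided by its mean over
    ``n_shuffles`` independent uniform permutations of each vector's
    entries (active counts preserved).  Requires at least one active
    neuron in the union; a pair where either vector is empty has an
    undefined normalization (NaN).
    """
    a = np.asarray(vec_a, bool)
    b = np.asarray(vec_b, bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D with equal length")
    union = (a | b).sum()
    if union == 0:
        raise ValueError("both ensemble vectors are empty; pair undefined")
    raw = float((a & b).sum() / union)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    na, nb = int(a.sum()), int(b.sum())
    n = len(a)
    if na == 0 or nb == 0:
        # every shuffle has an empty intersection; normalization undefined
        return SimilarityResult(raw, 0.0, float("nan"), n_shuffles)
    # a uniform permutation of a binary vector is a uniform random subset of
    # its active count: sample each vector's subset as the argpartition of
    # i.i.d. uniforms (exact, and much faster than explicit permutation)
    sub_a = np.argpartition(rng.random((n_shuffles, n), dtype=np.float32),
                            na - 1, axis=1)[:, :na]
    sub_b = np.argpartition(rng.random((n_shuffles, n), dtype=np.float32),
                            nb - 1, axis=1)[:, :nb]
    hit = np.zeros((n_shuffles, n), dtype=bool)
    np.put_along_axis(hit, sub_a, True, axis=1)
    inter = np.take_along_axis(hit, sub_b, axis=1).sum(axis=1)
    shuffled = inter / (na + nb - inter)
    smean = float(shuffled.mean())
    norm = raw / smean if smean > 0 else float("nan")
    return SimilarityResult(raw, smean, norm, n_shuffles)


def similarity_by_day(
    vectors_by_day: dict[int, np.ndarray],
    mode: str = "within_day",
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Mean normalized similarity per day (within) or day pair (across).

    Parameters
    ----------
    vectors_by_day
        day -> bouts x neurons binary activation matrix (one action type).
    mode
        "within_day": all unordered bout pairs of the same day;
        "across_adjacent_days": all pairs spanning days (d, d+1).

    Days (or pairs) with insufficient bouts, or where every pair is
    undefined, are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict = {}

    def _mean_over_pairs(pairs) -> float:
        vals = []
        for va, vb in pairs:
            try:
                vals.append(ensemble_similarity(va, vb, n_shuffles, rng).normalized)
            except ValueError:
                continue
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    days = sorted(vectors_by_day)
    if mode == "within_day":
        for d in days:
            m = vectors_by_day[d]
            if m.shape[0] < 2:
                continue
            out[d] = _mean_over_pairs(
                (m[i], m[j]) for i in range(len(m)) for j in range(i + 1, len(m)))
    elif mode == "across_adjacent_days":
        for d in days:
            if d + 1 not in vectors_by_day:
                continue
            ma, mb = vectors_by_day[d], vectors_by_day[d + 1]
            if ma.shape[0] < 1 or mb.shape[0] < 1:
                continue
            out[(d, d + 1)] = _mean_over_pairs((x, y) for x in ma for y in mb)
    else:
        raise ValueError("mode must be 'within_day' or 'across_adjacent_days'")
    return out


def fate_overlap(
    early_daily: np.ndarray,
    late_daily: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> FateResult:
    """Percentage of the late ensemble already active early, with null.

    ``early_daily`` and ``late_daily`` are 2 x neurons binary matrices (one
    row per day); a neuron belongs to the early (late) set when active on
    both of its two days.  The null permutes neuron identities of each
    daily vector independently; the one-sided p-value is the fraction of
    shuffles at or above the observed overlap.
    """
    e = np.asarray(early_daily, bool)
    la = np.asarray(late_daily, bool)
    if e.shape[0] != 2 or la.shape[0] != 2:
        raise ValueError("expect exactly two early and two late daily vectors")
    early = e[0] & e[1]
    late = la[0] & la[1]
    n_late = int(late.sum())
    if n_late == 0:
        raise ValueError("late ensemble is empty; overlap undefined")
    observed = 100.0 * (late & early).sum() / n_late
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        pe = rng.permutation(e[0]) & rng.permutation(e[1])
        pl = rng.permutation(la[0]) & rng.permutation(la[1])
        nl = pl.sum()
        null[s] = 100.0 * (pl & pe).sum() / nl if nl else 0.0
    p = float((null >= observed).mean())
    return FateResult(float(observed), float(null.mean()), p, n_late, n_shuffles)


def action_bias(
    members: np.ndarray,
    early_onset_active: np.ndarray,
    early_offset_active: np.ndarray,
) -> float:
    """Mean +1/-1/0 onset/offset-preference score over a late ensemble.

    Members active early at onsets only score +1, offsets only -1, both 0;
    members inactive at both are omitted.  Undefined (NaN is not returned;
    a ValueError is raised) when every member is omitted.
    """
    on = np.asarray(early_onset_active, bool)
    off = np.asarray(early_offset_active, bool)
    idx = np.asarray(members, int)
    if len(idx) == 0:
        raise ValueError("late ensemble is empty")
    scores = []
    for i in idx:
        if on[i] and off[i]:
            scores.append(0.0)
        elif on[i]:
            scores.append(1.0)
        elif off[i]:
            scores.append(-1.0)
    if not scores:
        raise ValueError("all ensemble members inactive early; bias undefined")
    return float(np.mean(scores))


def separability_matrix(
    dff: np.ndarray,
    onsets: np.ndarray,
    offsets: np.ndarray,
    frame_rate_hz: float,
    window_s: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bout x (neurons * window-frames) matrix and onset/offset labels.

    Each row horizontally concatenates every neuron's 4 s window centered
    on one onset or offset of the day (edge bouts dropped).
    """
    x = np.atleast_2d(np.asarray(dff, float))
    half = int(round(window_s / 2 * frame_rate_hz))
    rows, labels = [], []
    for label, evs in (("onset", onsets), ("offset", offsets)):
        for e in np.asarray(evs, int):
            if e - half < 0 or e + half >= x.shape[1]:
                continue
            rows.append(x[:, e - half:e + half + 1].ravel())
            labels.append(label)
    if not rows:
        return np.empty((0, 0)), np.empty(0, object)
    return np.asarray(rows), np.asarray(labels, object)


def separability_score(
    matrix: np.ndarray,
    labels: np.ndarray,
    n_pcs: int = 8,
    tsne_seed: int = 0,
) -> float:
    """Silhouette of onset vs offset bouts in a PCA + t-SNE embedding.

    Rows are z-scored per column, reduced to ``n_pcs`` principal
    components, embedded in 2-D by t-SNE with the Chebyshev metric
    (perplexity min(30, (n_rows-1)/3)), and scored by the silhouette of
    the onset/offset labels on the embedding.
    """
    X = np.asarray(matrix, float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2 or min(np.bincount(np.unique(y, return_inverse=True)[1])) < 2:
        raise ValueError("need at least two bouts of each label")
    sd = X.std(axis=0, ddof=0)
    mu = X.mean(axis=0)
    Xz = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    n_comp = min(n_pcs, Xz.shape[0] - 1, Xz.shape[1])
    pcs = PCA(n_components=n_comp, random_state=tsne_seed).fit_transform(Xz)
    perplexity = min(30.0, (len(pcs) - 1) / 3)
    if perplexity < 1:
        raise ValueError("too few bouts for a t-SNE embedding")
    emb = TSNE(n_components=2, metric="chebyshev", perplexity=perplexity,
               init="pca", random_state=tsne_seed).fit_transform(pcs)
    return float(silhouette_score(emb, y))
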