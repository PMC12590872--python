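"""Synthetic multi-animal, multi-day wheel-running imaging datasets.

The generator emulates the statistical structure the downstream analysis
assumes: ~20-min sessions at ~25 Hz; self-paced locomotion bouts whose
count and peak speed increase across 8 training days; ~160 neurons per
animal with planted onset-only / offset-only / both / neither activation
types whose membership is stable across days; GCaMP6-like transients
(fast-rise, slow-decay difference of exponentials, amplitude in
baseline-SD units) on unit-SD white-noise baselines.  With
``refine=True`` the planted "both" fraction decreases linearly from the
day-1 to the day-8 value while bout-to-bout reliability increases —
the day-by-day ensemble-refinement pattern the analysis is built to
detect.  Every session carries full ground truth (bout frames, event
frames, per-day type labels, ensemble memberships).

All randomness flows through ``numpy.random.SeedSequence(master_seed,
animal, day)`` so identical configurations reproduce bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BehaviorParams",
    "PopulationParams",
    "SynthGroundTruth",
    "SessionRecording",
    "StudyDataset",
    "transient_kernel",
    "generate_behavior",
    "generate_population",
    "generate_session",
    "generate_study",
    "generate_paw_trajectories",
]

N_DAYS = 8


@dataclass(frozen=True)
class BehaviorParams:
    """Session/behavior schedule across the 8 training days.

    Bout counts and peak speeds increase across days, emulating animals
    spending more time running, faster, as training progresses.
    """

    session_duration_s: float = 1200.0
    frame_rate_hz: float = 25.0
    bouts_per_day: tuple[int, ...] = (19, 19, 20, 20, 20, 21, 21, 22)
    bout_duration_mean_s: float = 5.0
    bout_duration_sd_s: float = 0.8
    peak_speed_day1_cm_s: float = 2.0
    peak_speed_day8_cm_s: float = 6.0
    peak_speed_cv: float = 0.15
    ramp_s: float = 0.4
    inter_bout_quiescence_s: float = 5.0
    edge_margin_s: float = 2.5
    speed_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.session_duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration and frame rate must be positive")
        if self.inter_bout_quiescence_s <= 4.0:
            raise ValueError("inter_bout_quiescence_s must exceed 4 s so bouts "
                             "satisfy the detector's 2 s pre/post windows")
        if len(self.bouts_per_day) != N_DAYS:
            raise ValueError("bouts_per_day must cover days 1..8")
        if min(self.peak_speed_day1_cm_s, self.peak_speed_day8_cm_s) <= 0:
            raise ValueError("peak speeds must be positive")


@dataclass(frozen=True)
class PopulationParams:
    """Planted neural-population structure.

    Type fractions are given for day 1 and day 8 and, with ``refine``,
    linearly interpolated in between (the "neither" fraction absorbs the
    remainder each day).  ``reliability`` is the probability that a member
    neuron activates on a given bout.  Transient amplitude is expressed in
    SD of the unit baseline noise.
    """

    n_neurons: int = 160
    onset_fraction: float = 0.15
    offset_fraction: float = 0.15
    both_fraction_day1: float = 0.40
    both_fraction_day8: float = 0.10
    reliability_day1: float = 0.87
    reliability_day8: float = 0.93
    transient_amplitude_sd: float = 8.0
    rise_tau_s: float = 0.2
    decay_tau_s: float = 0.7
    baseline_noise_sd: float = 1.0
    jitter_sd_s: float = 0.15
    jitter_max_s: float = 0.5
    background_rate_hz: float = 0.0
    onset_amplitude_speed_exponent: float = 1.0
    offset_amplitude_speed_exponent: float = 0.0
    refine: bool = True

    def __post_init__(self) -> None:
        for r in (self.reliability_day1, self.reliability_day8):
            if not 0.0 <= r <= 1.0:
                raise ValueError("reliability must lie in [0, 1]")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("kernel taus must be positive")
        f1 = self.onset_fraction + self.offset_fraction + self.both_fraction_day1
        f8 = self.onset_fraction + self.offset_fraction + self.both_fraction_day8
        if f1 > 1.0 + 1e-9 or f8 > 1.0 + 1e-9:
            raise ValueError("type fractions exceed 1")

    def both_fraction(self, day: int) -> float:
        if not self.refine:
            return self.both_fraction_day1
        w = (day - 1) / (N_DAYS - 1)
        return (1 - w) * self.both_fraction_day1 + w * self.both_fraction_day8

    def reliability(self, day: int) -> float:
        if not self.refine:
            return self.reliability_day1
        w = (day - 1) / (N_DAYS - 1)
        return (1 - w) * self.reliability_day1 + w * self.reliability_day8


@dataclass
class SynthGroundTruth:
    """Planted structure for one session: the recovery-test oracle."""

    true_onsets: np.ndarray
    true_offsets: np.ndarray
    true_event_frames: list[np.ndarray]
    true_type: np.ndarray
    onset_members: np.ndarray
    offset_members: np.ndarray
    seed: int


@dataclass
class SessionRecording:
    """One animal-day: velocity trace, dF/F matrix and metadata."""

    animal: int
    day: int
    velocity: np.ndarray
    dff: np.ndarray
    frame_rate_hz: float
    ground_truth: SynthGroundTruth | None = None


@dataclass
class StudyDataset:
    """A full animals x 8-days synthetic study."""

    sessions: dict[tuple[int, int], SessionRecording]
    behavior_params: BehaviorParams
    population_params: PopulationParams
    master_seed: int

    @property
    def animals(self) -> list[int]:
        return sorted({a for a, _ in self.sessions})

    def session(self, animal: int, day: int) -> SessionRecording:
        return self.sessions[(animal, day)]


def transient_kernel(amplitude: float, rise_tau_s: float, decay_tau_s: float,
                     frame_rate_hz: float) -> np.ndarray:
    """Difference-of-exponentials Ca2+ transient, peak-normalized to amplitude."""
    t = np.arange(0.0, 5.0 * decay_tau_s, 1.0 / frame_rate_hz)
    k = np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel; require rise_tau < decay_tau")
    return amplitude * k / peak


def generate_behavior(
    params: BehaviorParams,
    day: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Generate one session's velocity trace and its true bout list.

    Bouts are trapezoids (linear ramps over ``ramp_s``, flat plateau) with
    day-dependent peak speed, separated by at least
    ``inter_bout_quiescence_s`` of quiescence; optional Gaussian speed noise
    is added and the trace clipped at zero.  Returned bouts are
    (onset_frame, offset_frame) pairs: the first non-zero frame and the
    first frame back at zero.
    """
    if not 1 <= day <= N_DAYS:
        raise ValueError("day must be in 1..8")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = params.frame_rate_hz
    n = int(round(params.session_duration_s * rate))
    v = np.zeros(n)

    nb = params.bouts_per_day[day - 1]
    bouts: list[tuple[int, int]] = []
    if nb > 0:
        durs = np.clip(
            rng.normal(params.bout_duration_mean_s, params.bout_duration_sd_s, nb),
            3.0, None)
        w = (day - 1) / (N_DAYS - 1)
        speed_mean = ((1 - w) * params.peak_speed_day1_cm_s
                      + w * params.peak_speed_day8_cm_s)
        peaks = np.clip(
            rng.normal(speed_mean, params.peak_speed_cv * speed_mean, nb),
            1.0, None)
        margin = params.edge_margin_s
        gap_min = params.inter_bout_quiescence_s
        slack = (params.session_duration_s - 2 * margin - durs.sum()
                 - (nb - 1) * gap_min)
        if slack < 0:
            raise ValueError("session too short for the requested bout schedule")
        extra = rng.dirichlet(np.ones(nb + 1)) * slack
        t = margin + extra[0]
        ramp = int(round(params.ramp_s * rate))
        for i in range(nb):
            start = int(round(t * rate))
            dur_f = int(round(durs[i] * rate))
            prof = np.full(dur_f, peaks[i])
            up = np.arange(1, ramp + 1) / ramp * peaks[i]
            down = up[::-1]
            prof[:ramp] = up[:dur_f]
            prof[-ramp:] = down[-dur_f:]
            end = min(start + dur_f, n)
            v[start:end] = prof[: end - start]
            bouts.append((start, start + dur_f))
            t += durs[i] + gap_min + extra[i + 1]
    if params.speed_noise_sd > 0:
        v = np.clip(v + rng.normal(0.0, params.speed_noise_sd, n), 0.0, None)
    return v, bouts


def _assign_roles(params: PopulationParams, rng: np.random.Generator):
    """Persistent per-animal neuron roles and per-day type labels.

    Onset-only and offset-only members are fixed across days.  "Both"
    neurons form a pool sized to the day-1 fraction; with refinement, pool
    members deactivate (become "neither") in a random order so that the
    both-count tracks the linear day schedule.
    """
    n = params.n_neurons
    n_on = int(round(params.onset_fraction * n))
    n_off = int(round(params.offset_fraction * n))
    n_both1 = int(round(params.both_fraction_day1 * n))
    order = rng.permutation(n)
    onset_ids = order[:n_on]
    offset_ids = order[n_on:n_on + n_off]
    both_pool = rng.permutation(order[n_on + n_off:n_on + n_off + n_both1])

    types = np.full((N_DAYS, n), "neither", dtype=object)
    for day in range(1, N_DAYS + 1):
        n_both_d = int(round(params.both_fraction(day) * n))
        types[day - 1, onset_ids] = "onset_only"
        types[day - 1, offset_ids] = "offset_only"
        types[day - 1, both_pool[:n_both_d]] = "both"
    return types, onset_ids, offset_ids, both_pool


def generate_population(
    params: PopulationParams,
    bouts: list[tuple[int, int]],
    day: int,
    seed: int | np.random.Generator,
    n_frames: int,
    frame_rate_hz: float = 25.0,
    types: np.ndarray | None = None,
    bout_scales: np.ndarray | None = None,
) -> tuple[np.ndarray, SynthGroundTruth]:
    """Generate one session's dF/F matrix plus ground truth.

    Each member neuron activates on a given bout with probability
    ``reliability(day)``, receiving one transient at the bout onset (and/or
    offset for "both" neurons) jittered by a clipped Gaussian.  Onset
    transients scale with the bout's relative peak speed
    (``bout_scales ** onset_amplitude_speed_exponent``) so start-related
    activity carries a graded speed code, as striatal activity does during
    locomotion; stop-related transients default to speed-independent
    amplitude (exponent 0).  Baselines are unit-SD white noise; background
    transients at ``background_rate_hz`` are planted uniformly when
    enabled.

    ``types`` (per-neuron labels for this day) may be supplied to keep
    identities consistent across days; otherwise labels are drawn here from
    the day's type fractions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_neurons
    if types is None:
        all_types, *_ = _assign_roles(params, rng)
        types = all_types[day - 1]
    types = np.asarray(types, dtype=object)

    rel = params.reliability(day)
    kernel = transient_kernel(params.transient_amplitude_sd, params.rise_tau_s,
                              params.decay_tau_s, frame_rate_hz)
    if bout_scales is None:
        scales_on = scales_off = np.ones(len(bouts))
    else:
        rel_speed = np.asarray(bout_scales, float)
        scales_on = rel_speed ** params.onset_amplitude_speed_exponent
        scales_off = rel_speed ** params.offset_amplitude_speed_exponent
    dff = rng.normal(0.0, params.baseline_noise_sd, size=(n, n_frames))
    event_frames: list[list[int]] = [[] for _ in range(n)]

    def plant(i: int, frame: int, scale: float = 1.0) -> None:
        if not 0 <= frame < n_frames:
            return
        seg = min(len(kernel), n_frames - frame)
        dff[i, frame:frame + seg] += scale * kernel[:seg]
        event_frames[i].append(frame)

    jmax = params.jitter_max_s
    for i in range(n):
        at_onsets = types[i] in ("onset_only", "both")
        at_offsets = types[i] in ("offset_only", "both")
        for b, (onset_f, offset_f) in enumerate(bouts):
            if at_onsets and rng.random() < rel:
                jit = float(np.clip(rng.normal(0.0, params.jitter_sd_s), -jmax, jmax))
                plant(i, onset_f + int(round(jit * frame_rate_hz)), scales_on[b])
            if at_offsets and rng.random() < rel:
                jit = float(np.clip(rng.normal(0.0, params.jitter_sd_s), -jmax, jmax))
                plant(i, offset_f + int(round(jit * frame_rate_hz)), scales_off[b])
        if params.background_rate_hz > 0:
            n_bg = rng.poisson(params.background_rate_hz * n_frames / frame_rate_hz)
            for f in rng.integers(0, n_frames, n_bg):
                plant(i, int(f))

    gt = SynthGroundTruth(
        true_onsets=np.array([b[0] for b in bouts], int),
        true_offsets=np.array([b[1] for b in bouts], int),
        true_event_frames=[np.array(sorted(e), int) for e in event_frames],
        true_type=types,
        onset_members=np.flatnonzero(np.isin(types, ("onset_only", "both"))),
        offset_members=np.flatnonzero(np.isin(types, ("offset_only", "both"))),
        seed=-1,
    )
    return dff, gt


def _session_rng(master_seed: int, animal: int, day: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master_seed, animal, day)))


def generate_session(
    behavior_params: BehaviorParams,
    population_params: PopulationParams,
    animal: int,
    day: int,
    master_seed: int,
) -> SessionRecording:
    """Deterministically generate one animal-day session.

    Neuron roles are drawn from an animal-level stream (shared across the
    animal's days); behavior and population noise come from a per-(animal,
    day) stream, so any session can be regenerated independently.
    """
    roles_rng = np.random.default_rng(np.random.SeedSequence((master_seed, animal)))
    types_all, *_ = _assign_roles(population_params, roles_rng)
    rng = _session_rng(master_seed, animal, day)
    velocity, bouts = generate_behavior(behavior_params, day, rng)
    if bouts:
        peaks = np.array([velocity[a:b].max() for a, b in bouts])
        scales = peaks / peaks.mean()
    else:
        scales = None
    dff, gt = generate_population(
        population_params, bouts, day, rng,
        n_frames=len(velocity), frame_rate_hz=behavior_params.frame_rate_hz,
        types=types_all[day - 1], bout_scales=scales)
    gt.seed = master_seed
    return SessionRecording(animal, day, velocity, dff,
                            behavior_params.frame_rate_hz, gt)


def generate_study(
    behavior_params: BehaviorParams | None = None,
    population_params: PopulationParams | None = None,
    n_animals: int = 1,
    master_seed: int = 0,
) -> StudyDataset:
    """Generate a full study: ``n_animals`` x 8 daily sessions.

    Neuron IDs are consistent across days within an animal; with
    ``refine=True`` the planted "both" fraction strictly decreases and
    reliability strictly increases across days.
    """
    bp = behavior_params or BehaviorParams()
    pp = population_params or PopulationParams()
    sessions = {
        (a, d): generate_session(bp, pp, a, d, master_seed)
        for a in range(n_animals)
        for d in range(1, N_DAYS + 1)
    }
    return StudyDataset(sessions, bp, pp, master_seed)


def generate_paw_trajectories(
    bouts: list[tuple[int, int]],
    frame_rate_hz: float,
    seed: int | np.random.Generator = 0,
    cycles: float = 10.0,
    phase_jitter: float = 0.15,
    noise_sd: float = 0.05,
) -> list[np.ndarray]:
    """Smooth periodic X-Y paw traces per bout, for the kinematics statistic.

    Stereotyped gait is emulated in normalized bout time: every bout runs
    ``cycles`` stride cycles (with small per-bout phase jitter and additive
    noise) over its duration, so bouts remain phase-consistent after the
    resample-to-common-length step of the pairwise-correlation analysis.
    Larger ``phase_jitter``/``noise_sd`` model less stereotyped running.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for onset, offset in bouts:
        nf = offset - onset
        tau = np.linspace(0.0, 1.0, nf)
        phase = phase_jitter * rng.standard_normal()
        x = np.sin(2 * np.pi * cycles * tau + phase)
        y = (0.4 * np.sin(4 * np.pi * cycles * tau + phase)
             - 0.2 * np.cos(2 * np.pi * cycles * tau))
        xy = np.column_stack([x, y])
        xy += noise_sd * rng.standard_normal(xy.shape)
        out.append(xy)
    return out
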