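"""Synthetic cohorts of facial response signals for dyadic-listening studies.

The generator emulates a hyperscanning-style experiment in which listeners
are exposed to a fixed audio timeline (a block of short affective
"localizer" clips followed by a long audio drama) either alone (group
``SS``) or while facing a partner (group ``SP``).  Every signal follows the
additive inter-subject-correlation model

    x_A(t) = alpha * c(t) + beta * id_A(t) + eps_A(t)

where ``c`` is a stimulus-locked component shared by all subjects, ``id_A``
is a smooth idiosyncratic process of subject A and ``eps_A`` is white
noise.  Action-unit modalities ("eyebrow" = AU2, "smile" = AU12) are then
burst-sparsified so that a configurable fraction of samples is exactly
zero, mimicking the bursty, zero-segmented appearance of automatically
extracted AU intensities, while the gaze-angle modality is low-pass
filtered and stays strictly positive-valued.  Within-dyad coupling is
modelled as a turn-taking process: in alternating epochs one partner's
signal is blended with the lagged signal of the other.

All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

MODALITIES = ("eyebrow", "smile", "gaze")
AU_MODALITIES = ("eyebrow", "smile")

#: Default localizer clip names, in presentation order (affective sound set).
DEFAULT_CLIP_LABELS = (
    "childs-laughter",
    "car-crash",
    "african-music",
    "yelling-shooting",
    "making-love",
    "child-crying",
    "heartbeat",
    "yawning",
    "classical-music",
    "woman-screaming",
)

#: Length of one turn-taking epoch used by :func:`couple_dyad` (seconds).
COUPLING_EPOCH_S = 5.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimelineSegment:
    label: str
    kind: Literal["clip", "silence", "drama"]
    start: float  # seconds from recording onset
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class StimulusTimeline:
    """Stimulus timeline: localizer clips with silences, then the drama."""

    n_localizers: int = 10
    clip_duration: float = 12.0
    silence_duration: float = 10.0
    drama_duration: float = 1620.0
    sample_rate: float = 30.0
    segment_labels: Sequence[str] = DEFAULT_CLIP_LABELS
    segments: tuple[TimelineSegment, ...] = field(default=(), compare=False)

    @property
    def total_duration(self) -> float:
        return (
            self.n_localizers * (self.clip_duration + self.silence_duration)
            + self.drama_duration
        )

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sample_rate))

    @property
    def drama_start(self) -> float:
        return self.n_localizers * (self.clip_duration + self.silence_duration)

    def clip_segments(self) -> list[TimelineSegment]:
        return [s for s in self.segments if s.kind == "clip"]

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


def _check_integer_samples(duration: float, rate: float, what: str) -> None:
    n = duration * rate
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"{what} of {duration} s at {rate} Hz gives a non-integer sample "
            f"count ({n}); adjust the duration or the rate"
        )


def build_timeline(
    n_localizers: int = 10,
    clip_duration: float = 12.0,
    silence_duration: float = 10.0,
    drama_duration: float = 1620.0,
    sample_rate: float = 30.0,
    segment_labels: Optional[Sequence[str]] = None,
) -> StimulusTimeline:
    """Construct the stimulus timeline with per-segment onsets/offsets.

    Defaults reproduce the study layout: 10 localizer clips of 12 s, each
    followed by 10 s of silence, then a 1620 s (27 min) drama block, all at
    30 Hz — 1840 s in total.
    """
    if n_localizers < 0:
        raise ValueError("n_localizers must be >= 0")
    if drama_duration <= 0 or sample_rate <= 0:
        raise ValueError("drama_duration and sample_rate must be positive")
    if n_localizers > 0 and (clip_duration <= 0 or silence_duration <= 0):
        raise ValueError("clip and silence durations must be positive")
    for dur, what in (
        (clip_duration, "clip"),
        (silence_duration, "silence"),
        (drama_duration, "drama block"),
    ):
        if n_localizers > 0 or what == "drama block":
            _check_integer_samples(dur, sample_rate, what)

    if segment_labels is None:
        if n_localizers <= len(DEFAULT_CLIP_LABELS):
            segment_labels = DEFAULT_CLIP_LABELS[:n_localizers]
        else:
            segment_labels = tuple(f"clip-{i + 1:02d}" for i in range(n_localizers))
    if len(segment_labels) != n_localizers:
        raise ValueError("segment_labels must name every localizer clip")

    segments: list[TimelineSegment] = []
    t = 0.0
    for i in range(n_localizers):
        segments.append(
            TimelineSegment(segment_labels[i], "clip", t, t + clip_duration)
        )
        t += clip_duration
        segments.append(
            TimelineSegment(f"silence-{i + 1:02d}", "silence", t, t + silence_duration)
        )
        t += silence_duration
    segments.append(TimelineSegment("drama", "drama", t, t + drama_duration))

    return StimulusTimeline(
        n_localizers=n_localizers,
        clip_duration=clip_duration,
        silence_duration=silence_duration,
        drama_duration=drama_duration,
        sample_rate=sample_rate,
        segment_labels=tuple(segment_labels),
        segments=tuple(segments),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Weights and cohort layout of the synthetic signal model.

    ``alpha``/``beta``/``noise_sd`` weight the shared, idiosyncratic and
    white-noise components; ``coupling_weight`` (gamma) and ``coupling_lag``
    parameterize the turn-taking within-dyad influence.  ``coupling_window``
    optionally confines coupling to an interval (seconds from recording
    onset), which is how localized group effects are planted for scan
    experiments.  ``sp_shared_weight`` injects a weak-coupling group effect
    in the exact sense of the weak coupling model: a single extra process,
    common to every paired-group subject regardless of partnership (the
    joint dynamics of the shared social situation), blended into all SP
    signals inside ``coupling_window``.
    """

    alpha: float = 1.0
    beta: float = 1.0
    noise_sd: float = 0.5
    coupling_weight: float = 0.6
    coupling_lag: float = 1.0
    coupling_mode: Literal["mirror", "complement"] = "mirror"
    coupling_window: Optional[tuple[float, float]] = None
    sp_shared_weight: float = 0.0
    n_single: int = 18
    n_dyads: int = 9
    burst_rate: float = 6.0  # expected AU bursts per minute
    burst_floor: float = 0.35  # fraction of AU samples forced to exactly 0
    gaze_smoothness: float = 0.5  # low-pass cutoff for the gaze modality, Hz
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "alpha",
            "beta",
            "noise_sd",
            "coupling_weight",
            "coupling_lag",
            "sp_shared_weight",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.n_single < 0 or self.n_dyads < 0:
            raise ValueError("cohort counts must be >= 0")
        if not 0.0 <= self.burst_floor < 1.0:
            raise ValueError("burst_floor must be in [0, 1)")
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")
        if self.gaze_smoothness <= 0:
            raise ValueError("gaze_smoothness must be > 0")
        if self.coupling_mode not in ("mirror", "complement"):
            raise ValueError("coupling_mode must be 'mirror' or 'complement'")

    @property
    def n_subjects(self) -> int:
        return self.n_single + 2 * self.n_dyads


@dataclass
class ResponseSignal:
    """One subject x modality time series with group/dyad metadata."""

    subject_id: str
    group: Literal["SS", "SP"]
    modality: str
    sample_rate: float
    values: np.ndarray
    dyad_id: Optional[str] = None
    role_in_dyad: Optional[int] = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.group == "SP" and self.dyad_id is None:
            raise ValueError("SP subjects must carry a dyad_id")
        if self.group == "SS" and self.dyad_id is not None:
            raise ValueError("SS subjects have no dyad")

    def slice_seconds(self, start: float, length: float) -> np.ndarray:
        """Values in the half-open window [start, start+length) seconds."""
        i0 = int(round((start - self.t0) * self.sample_rate))
        i1 = i0 + int(round(length * self.sample_rate))
        if i0 < 0 or i1 > self.values.size:
            raise ValueError("window extends beyond the recorded signal")
        return self.values[i0:i1]


@dataclass
class AnnotationTrace:
    kind: Literal["valence", "arousal"]
    sample_rate: float
    values: np.ndarray
    t0: float = 0.0  # seconds relative to drama onset


@dataclass
class Cohort:
    """Generated cohort: all signals plus the ground-truth label table."""

    signals: list[ResponseSignal]
    labels: pd.DataFrame  # columns: subject_id, group, dyad_id
    timeline: StimulusTimeline
    config: GeneratorConfig

    def get(self, subject_id: str, modality: str) -> ResponseSignal:
        for s in self.signals:
            if s.subject_id == subject_id and s.modality == modality:
                return s
        raise KeyError((subject_id, modality))

    def modality_matrix(self, modality: str, order: Sequence[str]) -> np.ndarray:
        """Stack one modality as an (n_subjects, n_samples) array."""
        return np.vstack([self.get(sid, modality).values for sid in order])


# ---------------------------------------------------------------------------
# Component processes
# ---------------------------------------------------------------------------


def _lowpass(x: np.ndarray, cutoff_hz: float, rate: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass; falls back to identity above Nyquist."""
    nyq = rate / 2.0
    if cutoff_hz >= nyq:
        return x.copy()
    b, a = sps.butter(4, cutoff_hz / nyq)
    return sps.filtfilt(b, a, x)


def _smooth_process(n: int, rate: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth Gaussian process (low-passed white noise)."""
    x = _lowpass(rng.standard_normal(n), cutoff_hz, rate)
    sd = x.std()
    return x / sd if sd > 0 else x


def _segment_envelope(timeline: StimulusTimeline, rng: np.random.Generator) -> np.ndarray:
    """Amplitude envelope: distinct amplitude per clip, near-baseline silences."""
    env = np.empty(timeline.n_samples)
    rate = timeline.sample_rate
    for seg in timeline.segments:
        i0 = int(round(seg.start * rate))
        i1 = int(round(seg.end * rate))
        if seg.kind == "clip":
            amp = 0.8 + 0.8 * rng.random()
        elif seg.kind == "silence":
            amp = 0.15
        else:  # drama
            amp = 1.0
        env[i0:i1] = amp
    # soften segment boundaries (~1 s) so the envelope is physiologically smooth
    return _lowpass(env, 0.5, rate) if timeline.n_samples > 30 else env


def generate_common(timeline: StimulusTimeline, seed: int) -> dict[str, np.ndarray]:
    """Stimulus-locked component ``c(t)``, one series per modality.

    Each series is a smooth (~0.5 Hz bandwidth) Gaussian process modulated
    by a per-segment amplitude envelope: localizer clips receive distinct
    random amplitudes, silences sit near baseline and the drama runs at full
    amplitude.  Identical for every subject; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    common: dict[str, np.ndarray] = {}
    for modality in MODALITIES:
        env = _segment_envelope(timeline, rng)
        proc = _smooth_process(timeline.n_samples, timeline.sample_rate, 0.5, rng)
        common[modality] = env * proc
    return common


def _burst_train(
    n: int, rate: float, bursts_per_min: float, rng: np.random.Generator
) -> np.ndarray:
    """Sparse train of smooth positive bursts (facial-action events)."""
    out = np.zeros(n)
    n_events = rng.poisson(bursts_per_min * n / rate / 60.0)
    if n_events == 0:
        return out
    centers = rng.integers(0, n, size=n_events)
    widths = rng.uniform(0.3, 1.2, size=n_events) * rate  # 0.3-1.2 s bursts
    amps = rng.gamma(2.0, 1.0, size=n_events)
    t = np.arange(n)
    for c, w, a in zip(centers, widths, amps):
        lo, hi = max(0, int(c - 4 * w)), min(n, int(c + 4 * w) + 1)
        out[lo:hi] += a * np.exp(-0.5 * ((t[lo:hi] - c) / w) ** 2)
    sd = out.std()
    return out / sd if sd > 0 else out


def _rescale_unit(x: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0,1]; a constant signal maps to all zeros."""
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def generate_subject(
    common: dict[str, np.ndarray],
    config: GeneratorConfig,
    subject_meta: dict,
    seed: int,
) -> dict[str, ResponseSignal]:
    """Generate one subject's three modality signals from the mixture model.

    ``x = alpha*c + beta*id + eps`` followed by modality shaping: AU
    modalities are soft-thresholded at the ``burst_floor`` quantile so that
    that fraction of samples is exactly 0; gaze is low-pass filtered and
    never sparsified.  Each signal is finally rescaled into [0, 1].
    """
    rng = np.random.default_rng(seed)
    rate = subject_meta.get("sample_rate", 30.0)
    out: dict[str, ResponseSignal] = {}
    for modality in MODALITIES:
        c = common[modality]
        n = c.size
        idio = _smooth_process(n, rate, 0.5, rng)
        if modality in AU_MODALITIES and config.burst_rate > 0:
            bursts = _burst_train(n, rate, config.burst_rate, rng)
            idio = (idio + bursts) / np.sqrt(2.0)
        eps = config.noise_sd * rng.standard_normal(n)
        raw = config.alpha * c + config.beta * idio + eps

        if modality in AU_MODALITIES:
            if config.burst_floor > 0:
                q = np.quantile(raw, config.burst_floor)
                raw = np.clip(raw - q, 0.0, None)
        else:  # gaze: smooth, no exact zeros
            raw = _lowpass(raw, config.gaze_smoothness, rate)

        out[modality] = ResponseSignal(
            subject_id=subject_meta["subject_id"],
            group=subject_meta["group"],
            modality=modality,
            sample_rate=rate,
            values=_rescale_unit(raw),
            dyad_id=subject_meta.get("dyad_id"),
            role_in_dyad=subject_meta.get("role_in_dyad"),
        )
    return out


def couple_dyad(
    sig_a: ResponseSignal,
    sig_b: ResponseSignal,
    weight: float,
    lag: float,
    window: Optional[tuple[float, float]] = None,
    epoch: float = COUPLING_EPOCH_S,
    mode: Literal["mirror", "complement"] = "mirror",
) -> tuple[ResponseSignal, ResponseSignal]:
    """Apply turn-taking within-dyad influence to a pair of signals.

    In alternating epochs of ``epoch`` seconds one partner "attends" the
    other: their signal is blended with a response to the partner's signal
    delayed by ``lag`` seconds, x_A' = (1-w)*x_A + w*g(x_B(t-lag)).  The
    attending role alternates between partners (A in even epochs, B in
    odd), so coupling is never simultaneous — emulating dialogue-like turn
    taking rather than imitation.  Two response mappings g are available:
    ``mirror`` (g(u) = u, the attending partner tracks the other, raising
    lagged cross-correlation) and ``complement`` (g(u) = 1-u, a
    compensatory reply — one partner's activity is met by the other's
    withdrawal — which drives the zero-lag correlation of true pairs
    negative, the dialogue-between-different-states regime).  ``window``
    optionally restricts coupling to an interval in recording seconds.
    Outputs are re-clipped to [0, 1]; ``weight=0`` returns the inputs
    unchanged.
    """
    a, b = sig_a.values, sig_b.values
    if a.shape != b.shape:
        raise ValueError("dyad signals must have equal length")
    if weight < 0 or lag < 0:
        raise ValueError("coupling weight and lag must be >= 0")
    rate = sig_a.sample_rate
    lag_n = lag * rate
    if abs(lag_n - round(lag_n)) > 1e-9:
        raise ValueError("coupling lag must be an integer number of samples")
    lag_n = int(round(lag_n))
    if weight == 0:
        return sig_a, sig_b

    def delayed(x: np.ndarray) -> np.ndarray:
        if lag_n == 0:
            return x
        out = np.empty_like(x)
        out[:lag_n] = x[0]  # edge hold before the first sample
        out[lag_n:] = x[:-lag_n]
        return out

    n = a.size
    t = np.arange(n) / rate
    epoch_idx = np.floor(t / epoch).astype(int)
    mask_a = epoch_idx % 2 == 0  # A attends B in even epochs
    mask_b = ~mask_a
    if window is not None:
        in_win = (t >= window[0]) & (t < window[1])
        mask_a &= in_win
        mask_b &= in_win

    def respond(x: np.ndarray) -> np.ndarray:
        d = delayed(x)
        return d if mode == "mirror" else 1.0 - d

    new_a, new_b = a.copy(), b.copy()
    new_a[mask_a] = (1 - weight) * a[mask_a] + weight * respond(b)[mask_a]
    new_b[mask_b] = (1 - weight) * b[mask_b] + weight * respond(a)[mask_b]
    np.clip(new_a, 0.0, 1.0, out=new_a)
    np.clip(new_b, 0.0, 1.0, out=new_b)
    out_a = ResponseSignal(
        sig_a.subject_id, sig_a.group, sig_a.modality, rate, new_a,
        sig_a.dyad_id, sig_a.role_in_dyad, sig_a.t0,
    )
    out_b = ResponseSignal(
        sig_b.subject_id, sig_b.group, sig_b.modality, rate, new_b,
        sig_b.dyad_id, sig_b.role_in_dyad, sig_b.t0,
    )
    return out_a, out_b


def subject_roster(config: GeneratorConfig) -> pd.DataFrame:
    """Label table: SS block first, then SP subjects with true pairs adjacent."""
    rows = []
    for i in range(config.n_single):
        rows.append({"subject_id": f"ss{i + 1:02d}", "group": "SS", "dyad_id": None})
    for d in range(config.n_dyads):
        for role in (1, 2):
            rows.append(
                {
                    "subject_id": f"sp{d + 1:02d}-{role}",
                    "group": "SP",
                    "dyad_id": f"d{d + 1:02d}",
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "group", "dyad_id"])


def generate_cohort(
    config: GeneratorConfig, timeline: Optional[StimulusTimeline] = None
) -> Cohort:
    """Generate the full cohort: SS singles plus coupled SP dyads.

    Seeds cascade from ``config.seed`` through a spawned seed sequence
    (one child for the common component, one per subject), so the cohort is
    bit-reproducible and individual subjects can be regenerated in
    isolation.
    """
    if timeline is None:
        timeline = build_timeline()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + config.n_subjects)
    common = generate_common(timeline, children[0])
    group_rng = np.random.default_rng(children[1])

    roster = subject_roster(config)
    signals: list[ResponseSignal] = []
    by_subject: dict[str, dict[str, ResponseSignal]] = {}
    for i, row in roster.iterrows():
        meta = {
            "subject_id": row.subject_id,
            "group": row.group,
            "dyad_id": row.dyad_id,
            "role_in_dyad": None if row.dyad_id is None else int(row.subject_id[-1]),
            "sample_rate": timeline.sample_rate,
        }
        by_subject[row.subject_id] = generate_subject(
            common, config, meta, children[2 + i]
        )

    if config.coupling_weight > 0:
        for d in range(config.n_dyads):
            id_a, id_b = f"sp{d + 1:02d}-1", f"sp{d + 1:02d}-2"
            for modality in MODALITIES:
                a, b = couple_dyad(
                    by_subject[id_a][modality],
                    by_subject[id_b][modality],
                    config.coupling_weight,
                    config.coupling_lag,
                    window=config.coupling_window,
                    mode=config.coupling_mode,
                )
                by_subject[id_a][modality] = a
                by_subject[id_b][modality] = b

    if config.sp_shared_weight > 0 and config.n_dyads > 0:
        # weak-coupling group effect: one extra process common to every SP
        # subject (regardless of partnership), blended in within the window
        w = config.sp_shared_weight
        t = np.arange(timeline.n_samples) / timeline.sample_rate
        if config.coupling_window is not None:
            in_win = (t >= config.coupling_window[0]) & (t < config.coupling_window[1])
        else:
            in_win = np.ones(timeline.n_samples, dtype=bool)
        shared = {
            m: _rescale_unit(
                _smooth_process(timeline.n_samples, timeline.sample_rate, 0.5, group_rng)
            )
            for m in MODALITIES
        }
        for sid in roster.loc[roster.group == "SP", "subject_id"]:
            for modality in MODALITIES:
                sig = by_subject[sid][modality]
                v = sig.values.copy()
                v[in_win] = (1 - w) * v[in_win] + w * shared[modality][in_win]
                np.clip(v, 0.0, 1.0, out=v)
                by_subject[sid][modality] = ResponseSignal(
                    sig.subject_id, sig.group, sig.modality, sig.sample_rate,
                    v, sig.dyad_id, sig.role_in_dyad, sig.t0,
                )

    for sid in roster.subject_id:
        for modality in MODALITIES:
            signals.append(by_subject[sid][modality])
    return Cohort(signals=signals, labels=roster, timeline=timeline, config=config)


def generate_annotations(
    timeline: StimulusTimeline, seed: int, sample_rate: float = 5.0
) -> tuple[AnnotationTrace, AnnotationTrace]:
    """Smooth valence and arousal overlay traces over the drama, in [-1, 1]."""
    rng = np.random.default_rng(seed)
    n = int(round(timeline.drama_duration * sample_rate))
    traces = []
    for kind in ("valence", "arousal"):
        x = _smooth_process(n, sample_rate, 0.05, rng)
        x = np.clip(x / 3.0, -1.0, 1.0)
        traces.append(AnnotationTrace(kind=kind, sample_rate=sample_rate, values=x))
    return traces[0], traces[1]
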