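"""Synthetic EEG with planted periodic sources and known ground truth.

Generates multichannel recordings with the statistical structure the
analysis pipeline assumes: periodic responses at harmonics of a base and
a deviant stimulation rate, produced by sources with fixed sensor
topographies, per-harmonic amplitudes and a fixed group delay, embedded
in spatially-mixed 1/f background plus white sensor noise.  Blink-like
transients and bad sensors can be injected with exact bookkeeping so
rejection/repair stages are testable by exact counts.

Units are microvolts throughout; the time origin is at trial onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StimulusSchedule",
    "SensorMontage",
    "PlantedSource",
    "GroundTruth",
    "ArtifactSpec",
    "ArtifactEvent",
    "RawRecording",
    "make_schedule",
    "make_session",
    "spherical_montage",
    "simulate_recording",
    "inject_artifacts",
]


# ---------------------------------------------------------------------------
# Stimulus schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSchedule:
    """Periodic oddball presentation schedule for one condition.

    Every item appears at ``base_hz``; every ``items_per_deviant``-th item
    is a deviant, giving a deviant rate of ``base_hz / items_per_deviant``.
    """

    base_hz: float
    deviant_hz: float
    items_per_deviant: int
    trial_duration_s: float
    n_trials: int
    item_labels: tuple[str, ...]

    @property
    def items_per_trial(self) -> int:
        return len(self.item_labels)

    def deviant_spacing(self) -> int:
        """Spacing in items between consecutive deviant labels."""
        idx = [i for i, lab in enumerate(self.item_labels) if lab == "deviant"]
        if len(idx) < 2:
            raise ValueError("schedule contains fewer than two deviants")
        gaps = np.diff(idx)
        if not np.all(gaps == gaps[0]):
            raise AssertionError("deviant labels are not strictly periodic")
        return int(gaps[0])


def make_schedule(
    base_hz: float,
    items_per_deviant: int,
    trial_duration_s: float,
    n_trials: int,
) -> StimulusSchedule:
    """Build an oddball schedule with one deviant per ``items_per_deviant`` items.

    Raises
    ------
    ValueError
        If ``items_per_deviant < 2`` or the trial does not contain a whole
        number of deviant cycles (``trial_duration_s * base_hz /
        items_per_deviant`` must be an integer).
    """
    if base_hz <= 0:
        raise ValueError("base_hz must be positive")
    if items_per_deviant < 2:
        raise ValueError(
            "items_per_deviant must be >= 2 (every item would be a deviant)"
        )
    n_items = base_hz * trial_duration_s
    n_cycles = n_items / items_per_deviant
    if abs(n_items - round(n_items)) > 1e-9 or abs(n_cycles - round(n_cycles)) > 1e-9:
        raise ValueError(
            "trial_duration_s * base_hz / items_per_deviant must be an integer: "
            f"got {n_cycles} deviant cycles per trial"
        )
    n_items = int(round(n_items))
    labels = tuple(
        "deviant" if i % items_per_deviant == 0 else "base" for i in range(n_items)
    )
    return StimulusSchedule(
        base_hz=float(base_hz),
        deviant_hz=float(base_hz) / items_per_deviant,
        items_per_deviant=int(items_per_deviant),
        trial_duration_s=float(trial_duration_s),
        n_trials=int(n_trials),
        item_labels=labels,
    )


def make_session(
    n_conditions: int = 5,
    trials_per_block: int = 4,
    n_blocks: int = 4,
    seed: int | None = None,
) -> list[tuple[int, int]]:
    """Randomized session order: ``trials_per_block`` trials of every
    condition per block, repeated over ``n_blocks`` blocks.

    Returns a list of ``(block_index, condition_index)`` pairs in
    presentation order.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[int, int]] = []
    for b in range(n_blocks):
        trials = np.repeat(np.arange(n_conditions), trials_per_block)
        rng.shuffle(trials)
        out.extend((b, int(c)) for c in trials)
    return out


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorMontage:
    """Sensor positions plus symmetric neighbor structure (>= 6 per sensor)."""

    positions: np.ndarray  # (n_sensors, 3)
    adjacency: tuple[tuple[int, ...], ...]  # per-sensor neighbor indices, nearest first

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    def neighbors(self, sensor: int, k: int = 6) -> tuple[int, ...]:
        nb = self.adjacency[sensor]
        if len(nb) < k:
            raise ValueError(f"sensor {sensor} has only {len(nb)} neighbors")
        return nb[:k]


def spherical_montage(n_sensors: int = 128, min_neighbors: int = 6) -> SensorMontage:
    """Evenly spaced sensors on the upper ~2/3 of a unit sphere with
    k-nearest-neighbor adjacency, symmetrized so every sensor keeps at
    least ``min_neighbors`` neighbors.
    """
    if n_sensors < min_neighbors + 1:
        raise ValueError("need more sensors than neighbors")
    # Fibonacci lattice restricted to z > -0.33 (scalp-like cap).
    i = np.arange(n_sensors)
    z = 1.0 - (i + 0.5) / n_sensors * 1.33
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    tree = cKDTree(pos)
    _, idx = tree.query(pos, k=min_neighbors + 1)
    neighbor_sets: list[dict[int, float]] = [dict() for _ in range(n_sensors)]
    for s in range(n_sensors):
        for j in idx[s, 1:]:
            d = float(np.linalg.norm(pos[s] - pos[j]))
            neighbor_sets[s][int(j)] = d
            neighbor_sets[int(j)][s] = d  # symmetrize
    adjacency = tuple(
        tuple(sorted(nb, key=nb.get)) for nb in neighbor_sets
    )
    return SensorMontage(positions=pos, adjacency=adjacency)


# ---------------------------------------------------------------------------
# Ground truth and recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSource:
    """One periodic source: unit-norm topography, harmonic amplitudes at
    ``freqs_hz``, group delay ``tau_ms`` and phase intercept ``phi0``.

    The planted phase at harmonic f is ``phi0 - 2*pi*f*tau_ms/1000``,
    wrapped to (-pi, pi].
    """

    topography: np.ndarray  # (n_sensors,), unit norm
    freqs_hz: tuple[float, ...]
    amps_uv: tuple[float, ...]
    tau_ms: float
    phi0: float = 0.0

    def __post_init__(self) -> None:
        topo = np.asarray(self.topography, dtype=float)
        if not np.all(np.isfinite(topo)):
            raise ValueError("topography must be finite")
        nrm = np.linalg.norm(topo)
        if nrm == 0:
            raise ValueError("topography must be nonzero")
        object.__setattr__(self, "topography", topo / nrm)
        if len(self.freqs_hz) != len(self.amps_uv):
            raise ValueError("freqs_hz and amps_uv must have equal length")

    def phase_at(self, f_hz: float) -> float:
        """Planted phase at ``f_hz`` in (-pi, pi]."""
        phi = self.phi0 - 2.0 * math.pi * f_hz * self.tau_ms / 1000.0
        return float(np.angle(np.exp(1j * phi)))

    def waveform(self, t: np.ndarray, tau_shift_ms: float = 0.0,
                 amp_scale: float = 1.0) -> np.ndarray:
        """Source time course at sample times ``t`` (seconds from trial onset)."""
        tau = (self.tau_ms + tau_shift_ms) / 1000.0
        out = np.zeros_like(t)
        for f, a in zip(self.freqs_hz, self.amps_uv):
            out += a * amp_scale * np.cos(2.0 * math.pi * f * (t - tau) + self.phi0)
        return out


@dataclass(frozen=True)
class ArtifactSpec:
    rate_per_min: float = 0.0
    amplitude_uv: float = 100.0


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to simulate — and later verify — a recording."""

    sources: tuple[PlantedSource, ...]
    noise_1f_scale: float = 0.0     # RMS uV of the spatially mixed background
    noise_white_scale: float = 0.0  # RMS uV of i.i.d. sensor noise
    n_background_sources: int = 10
    amp_jitter_frac: float = 0.0    # per-subject SD as fraction of amplitude
    latency_jitter_ms: float = 0.0  # per-subject SD of group delay
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0


@dataclass
class RawRecording:
    """Continuous sensor x time recording for one subject (trials concatenated)."""

    data: np.ndarray  # (n_sensors, n_samples) uV
    fs: float
    montage: SensorMontage
    schedule: StimulusSchedule
    condition_id: str = "cond"
    subject_id: str = "s00"

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.montage.n_sensors:
            raise ValueError(
                f"data has {self.data.shape[0]} rows, montage has "
                f"{self.montage.n_sensors} sensors"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RawRecording":
        return replace(self, data=self.data.copy())


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS noise with 1/f power spectrum (spectrally shaped white noise)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])  # power ~ 1/f
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / max(x.std(), 1e-30)


def _smooth_random_topography(rng: np.random.Generator,
                              montage: SensorMontage,
                              n_passes: int = 3) -> np.ndarray:
    """Random spatially smooth unit-norm sensor pattern (neighbor averaging)."""
    v = rng.standard_normal(montage.n_sensors)
    for _ in range(n_passes):
        v = np.array([
            0.5 * v[s] + 0.5 * np.mean(v[list(montage.adjacency[s])])
            for s in range(montage.n_sensors)
        ])
    return v / np.linalg.norm(v)


def simulate_recording(
    truth: GroundTruth,
    schedule: StimulusSchedule,
    montage: SensorMontage,
    fs: float,
    n_subjects: int,
    condition_id: str = "cond",
) -> list[RawRecording]:
    """Simulate one continuous recording per subject.

    Each recording is the sum over planted sources of
    ``topography (x) sum_k a_k cos(2 pi f_k (t - tau)) + phi0`` restarted at
    every trial onset, plus spatially mixed 1/f background and white sensor
    noise.  Per-subject amplitude/latency jitter is applied when configured.
    Deterministic given ``truth.seed``.
    """
    nyq = fs / 2.0
    for src in truth.sources:
        bad = [f for f in src.freqs_hz if f >= nyq]
        if bad:
            raise ValueError(
                f"harmonic(s) {bad} at or above the Nyquist frequency {nyq} Hz"
            )
    rng = np.random.default_rng(truth.seed)
    trial_samples = int(round(schedule.trial_duration_s * fs))
    if abs(trial_samples - schedule.trial_duration_s * fs) > 1e-9:
        raise ValueError("trial duration must be an integer number of samples")
    t = np.arange(trial_samples) / fs
    n_total = trial_samples * schedule.n_trials

    recordings: list[RawRecording] = []
    for subj in range(n_subjects):
        tau_shifts = rng.normal(0.0, truth.latency_jitter_ms, len(truth.sources)) \
            if truth.latency_jitter_ms > 0 else np.zeros(len(truth.sources))
        amp_scales = rng.normal(1.0, truth.amp_jitter_frac, len(truth.sources)) \
            if truth.amp_jitter_frac > 0 else np.ones(len(truth.sources))

        trial = np.zeros((montage.n_sensors, trial_samples))
        for k, src in enumerate(truth.sources):
            wave = src.waveform(t, tau_shift_ms=float(tau_shifts[k]),
                                amp_scale=float(amp_scales[k]))
            trial += np.outer(src.topography, wave)
        data = np.tile(trial, schedule.n_trials)

        if truth.noise_1f_scale > 0:
            bg = np.zeros((montage.n_sensors, n_total))
            for _ in range(truth.n_background_sources):
                topo = _smooth_random_topography(rng, montage)
                bg += np.outer(topo, _pink_noise(rng, n_total))
            bg *= truth.noise_1f_scale / max(bg.std(), 1e-30)
            data = data + bg
        if truth.noise_white_scale > 0:
            data = data + truth.noise_white_scale * rng.standard_normal(data.shape)

        recordings.append(
            RawRecording(
                data=data,
                fs=float(fs),
                montage=montage,
                schedule=schedule,
                condition_id=condition_id,
                subject_id=f"s{subj:02d}",
            )
        )
    return recordings


@dataclass(frozen=True)
class ArtifactEvent:
    sensor: int
    start_sample: int
    n_samples: int
    amplitude_uv: float

    def epoch_index(self, fs: float, epoch_s: float = 1.0) -> int:
        return int(self.start_sample // round(fs * epoch_s))


def inject_artifacts(
    rec: RawRecording,
    rate_per_min: float,
    amplitude_uv: float,
    seed: int,
    epoch_s: float = 1.0,
) -> tuple[RawRecording, list[ArtifactEvent]]:
    """Add blink-like half-sine transients on random single sensors.

    Each transient lies entirely within one ``epoch_s`` window so downstream
    rejection flags exactly one (epoch, sensor) pair per event.  Returns the
    modified recording and the exact events injected.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    if rate_per_min > 0 and amplitude_uv <= 60.0:
        raise ValueError("amplitude_uv must exceed 60 uV to be rejectable")
    if rate_per_min == 0:
        return rec.copy(), []

    rng = np.random.default_rng(seed)
    out = rec.copy()
    epoch_samples = int(round(rec.fs * epoch_s))
    n_epochs = rec.n_samples // epoch_samples
    n_events = int(round(rate_per_min * rec.n_samples / rec.fs / 60.0))
    width = max(int(round(0.1 * rec.fs)), 4)  # 100 ms blink

    # distinct (epoch, sensor) slots so events never stack
    slots = rng.choice(n_epochs * out.data.shape[0], size=n_events, replace=False)
    events: list[ArtifactEvent] = []
    for slot in np.sort(slots):
        epoch, sensor = int(slot) // out.data.shape[0], int(slot) % out.data.shape[0]
        offset = int(rng.integers(0, epoch_samples - width))
        start = epoch * epoch_samples + offset
        pulse = amplitude_uv * np.sin(np.pi * np.arange(width) / (width - 1))
        pulse[np.abs(pulse) < amplitude_uv * 0.05] = 0.0
        pulse[np.argmax(pulse)] = amplitude_uv  # guarantee threshold crossing
        out.data[sensor, start:start + width] += pulse
        events.append(ArtifactEvent(sensor=sensor, start_sample=start,
                                    n_samples=width, amplitude_uv=amplitude_uv))
    return out, events
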