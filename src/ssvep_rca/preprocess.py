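"""Preprocessing chain: zero-phase bandpass, polyphase resampling,
bad-sensor repair by neighbor averaging, average re-reference, and
1-second epoching with per-(epoch, sensor) rejection.

The stage order is fixed: bandpass -> resample -> repair -> re-reference
-> epoch/reject.  All amplitude thresholds compare absolute values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from ssvep_rca.synth import RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "EpochedRecording",
    "bandpass",
    "resample",
    "repair_bad_sensors",
    "rereference_average",
    "epoch_and_reject",
    "run",
]


@dataclass(frozen=True)
class PreprocessConfig:
    band_lo: float = 0.3
    band_hi: float = 50.0
    filter_order: int = 4
    resample_hz: float = 420.0
    sensor_bad_fraction: float = 0.15
    sensor_amp_thresh_uv: float = 30.0
    n_repair_neighbors: int = 6
    epoch_s: float = 1.0
    epoch_noise_fraction: float = 0.10
    epoch_noise_thresh_uv: float = 30.0
    epoch_artifact_thresh_uv: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi < self.resample_hz / 2:
            raise ValueError("require 0 < band_lo < band_hi < resample_hz/2")
        for name in ("sensor_amp_thresh_uv", "epoch_noise_thresh_uv",
                     "epoch_artifact_thresh_uv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sensor_bad_fraction", "epoch_noise_fraction"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class EpochedRecording:
    """Epoch x sensor x time data with a per-(epoch, sensor) validity mask."""

    data: np.ndarray        # (n_epochs, n_sensors, n_times) uV
    fs: float
    valid_mask: np.ndarray  # (n_epochs, n_sensors) bool
    subject_id: str = "s00"
    condition_id: str = "cond"
    provenance: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]


def bandpass(rec: RawRecording, cfg: PreprocessConfig) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth bandpass."""
    if rec.fs <= 2 * cfg.band_hi:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for band edge {cfg.band_hi} Hz"
        )
    sos = signal.butter(cfg.filter_order, [cfg.band_lo, cfg.band_hi],
                        btype="bandpass", fs=rec.fs, output="sos")
    out = rec.copy()
    out.data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return out


def resample(rec: RawRecording, target_hz: float) -> RawRecording:
    """Polyphase rational resampling (exact sample counts, no drift)."""
    if target_hz == rec.fs:
        return rec.copy()
    frac = Fraction(target_hz / rec.fs).limit_denominator(1000)
    out = rec.copy()
    out.data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                    axis=1)
    out.fs = float(target_hz)
    return out


def repair_bad_sensors(
    rec: RawRecording, cfg: PreprocessConfig
) -> tuple[RawRecording, list[int]]:
    """Replace sensors with *more than* ``sensor_bad_fraction`` of samples
    exceeding ``sensor_amp_thresh_uv`` (absolute value) by the sample-wise
    mean of their ``n_repair_neighbors`` nearest neighbors' original traces.
    """
    frac_bad = np.mean(np.abs(rec.data) > cfg.sensor_amp_thresh_uv, axis=1)
    flagged = [int(s) for s in np.nonzero(frac_bad > cfg.sensor_bad_fraction)[0]]
    if len(flagged) > 0.25 * rec.montage.n_sensors:
        logger.warning(
            "quality gate: %d/%d sensors flagged for repair",
            len(flagged), rec.montage.n_sensors,
        )
    out = rec.copy()
    for s in flagged:
        nb = list(rec.montage.neighbors(s, cfg.n_repair_neighbors))
        out.data[s] = rec.data[nb].mean(axis=0)
    return out, flagged


def rereference_average(rec: RawRecording) -> RawRecording:
    """Subtract the across-sensor mean at every time sample (idempotent)."""
    out = rec.copy()
    out.data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return out


def epoch_and_reject(rec: RawRecording, cfg: PreprocessConfig) -> EpochedRecording:
    """Segment into ``epoch_s`` epochs and reject per (epoch, sensor).

    An (epoch, sensor) pair is invalid when more than
    ``epoch_noise_fraction`` of its samples exceed ``epoch_noise_thresh_uv``
    or any sample exceeds ``epoch_artifact_thresh_uv`` (absolute values).
    """
    epoch_samples = int(round(cfg.epoch_s * rec.fs))
    if abs(epoch_samples - cfg.epoch_s * rec.fs) > 1e-9:
        raise ValueError("epoch length times fs must be an integer")
    n_epochs = rec.n_samples // epoch_samples
    if n_epochs * epoch_samples != rec.n_samples:
        raise ValueError(
            f"{rec.n_samples} samples do not divide into whole "
            f"{epoch_samples}-sample epochs"
        )
    epochs = rec.data[:, : n_epochs * epoch_samples].reshape(
        rec.montage.n_sensors, n_epochs, epoch_samples
    ).transpose(1, 0, 2)

    absd = np.abs(epochs)
    noisy = np.mean(absd > cfg.epoch_noise_thresh_uv, axis=2) > cfg.epoch_noise_fraction
    artifact = np.any(absd > cfg.epoch_artifact_thresh_uv, axis=2)
    valid = ~(noisy | artifact)

    dead = np.nonzero(~valid.any(axis=0))[0]
    if dead.size:
        logger.warning("sensors with no valid epochs dropped downstream: %s",
                       dead.tolist())
    return EpochedRecording(
        data=epochs.copy(),
        fs=rec.fs,
        valid_mask=valid,
        subject_id=rec.subject_id,
        condition_id=rec.condition_id,
        provenance={
            "n_rejected_pairs": int((~valid).sum()),
            "n_noise_rule": int(noisy.sum()),
            "n_artifact_rule": int(artifact.sum()),
        },
    )


def run(rec: RawRecording, cfg: PreprocessConfig | None = None) -> EpochedRecording:
    """Full chain in the fixed order; provenance records repaired sensors."""
    cfg = cfg or PreprocessConfig()
    x = bandpass(rec, cfg)
    x = resample(x, cfg.resample_hz)
    x, repaired = repair_bad_sensors(x, cfg)
    x = rereference_average(x)
    epoched = epoch_and_reject(x, cfg)
    epoched.provenance["repaired_sensors"] = repaired
    epoched.provenance["n_repaired_sensors"] = len(repaired)
    return epoched
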