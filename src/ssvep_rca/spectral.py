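"""Analysis-harmonic enumeration and per-epoch complex spectral coefficients.

Amplitude/phase convention: a unit-amplitude cosine at a bin frequency with
zero phase yields the coefficient ``1 + 0i`` — coefficient magnitude is the
microvolt amplitude of the underlying sinusoid, and phase is measured
counterclockwise from the positive real axis.  With 1-s epochs the bin
spacing is exactly 1 Hz, so every analysis harmonic sits on a bin.

The narrowband estimation stage is implemented by its steady-state
equivalent, the on-bin DFT of whole epochs (epochs hold exact integer
cycles of every analysis frequency).  A true exponentially weighted
recursive (RLS) quadrature estimator is available behind the same
interface via ``method="rls"`` for fidelity studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ssvep_rca.preprocess import EpochedRecording

__all__ = [
    "HarmonicSet",
    "SpectralCoefficients",
    "enumerate_harmonics",
    "spectral_coefficients",
]

CONVENTION = "unit-amplitude cosine at bin frequency, zero phase -> 1 + 0i"


@dataclass(frozen=True)
class HarmonicSet:
    """Ordered analysis frequencies for one role (base or deviant)."""

    role: str  # "base" | "deviant"
    frequencies: tuple[float, ...]
    excluded: tuple[float, ...] = ()
    rule: str = ""

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.frequencies[1:], self.frequencies)):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.frequencies)


@dataclass
class SpectralCoefficients:
    """Complex coefficient per epoch x sensor x frequency (uV).

    Invalid (epoch, sensor) entries are NaN; ``valid_mask`` is inherited
    from the epoched recording.
    """

    coeffs: np.ndarray      # (n_epochs, n_sensors, n_freqs) complex
    freqs: HarmonicSet
    valid_mask: np.ndarray  # (n_epochs, n_sensors) bool
    subject_id: str = "s00"
    condition_id: str = "cond"
    convention: str = CONVENTION


def enumerate_harmonics(
    deviant_hz: float,
    base_hz: float,
    n_harmonics: int,
    exclude_base: bool = False,
) -> HarmonicSet:
    """First ``n_harmonics`` multiples of ``deviant_hz``; with
    ``exclude_base`` the first ``n_harmonics`` multiples that are *not*
    multiples of ``base_hz``, reporting the skipped base multiples.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    ratio = base_hz / deviant_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"base_hz={base_hz} must be an integer multiple of deviant_hz={deviant_hz}"
        )
    role = "base" if deviant_hz == base_hz else "deviant"
    if not exclude_base:
        freqs = tuple(deviant_hz * k for k in range(1, n_harmonics + 1))
        return HarmonicSet(role=role, frequencies=freqs,
                           rule=f"first {n_harmonics} harmonics of {deviant_hz} Hz")
    kept: list[float] = []
    skipped: list[float] = []
    k = 1
    while len(kept) < n_harmonics:
        f = deviant_hz * k
        if abs(f / base_hz - round(f / base_hz)) < 1e-9:
            skipped.append(f)
        else:
            kept.append(f)
        k += 1
    if skipped:
        # complete the interleaving period: base multiples immediately after
        # the last kept harmonic would be skipped before the next kept one
        while True:
            f = deviant_hz * k
            if abs(f / base_hz - round(f / base_hz)) < 1e-9:
                skipped.append(f)
                k += 1
            else:
                break
    return HarmonicSet(
        role=role,
        frequencies=tuple(kept),
        excluded=tuple(skipped),
        rule=(f"first {n_harmonics} harmonics of {deviant_hz} Hz "
              f"excluding multiples of {base_hz} Hz"),
    )


def _dft_coefficients(data: np.ndarray, fs: float,
                      freqs: tuple[float, ...]) -> np.ndarray:
    """On-bin DFT scaled so a unit cosine gives magnitude 1.

    Equivalent to the matched-filter inner product ``2/N sum x e^{-i2pift}``.
    """
    n = data.shape[-1]
    t = np.arange(n) / fs
    basis = np.exp(-2j * np.pi * np.outer(np.asarray(freqs), t))  # (F, N)
    return (2.0 / n) * data @ basis.T


def _rls_coefficients(data: np.ndarray, fs: float, freqs: tuple[float, ...],
                      forgetting: float = 0.99) -> np.ndarray:
    """Exponentially weighted recursive quadrature estimate at each frequency.

    Tracks in-phase/quadrature amplitudes sample by sample; the final state
    is reported.  Converges to the on-bin DFT as ``forgetting -> 1``.
    """
    n = data.shape[-1]
    t = np.arange(n) / fs
    lead = data.shape[:-1]
    out = np.empty(lead + (len(freqs),), dtype=complex)
    flat = data.reshape(-1, n)
    for fi, f in enumerate(freqs):
        c = np.cos(2 * np.pi * f * t)
        s = -np.sin(2 * np.pi * f * t)
        # effective sample count under exponential weighting
        w = forgetting ** np.arange(n - 1, -1, -1)
        denom = 0.5 * w.sum()
        re = (flat * (w * c)).sum(axis=1) / denom
        im = (flat * (w * s)).sum(axis=1) / denom
        out.reshape(-1, len(freqs))[:, fi] = re + 1j * im
    return out.reshape(lead + (len(freqs),))


def spectral_coefficients(
    epochs: EpochedRecording,
    freqs: HarmonicSet,
    method: str = "dft",
    rls_forgetting: float = 0.999,
) -> SpectralCoefficients:
    """Complex coefficients at the analysis harmonics for every valid
    (epoch, sensor); invalid entries propagate as NaN.

    Every frequency must be an integer multiple of the epoch's frequency
    resolution (1/epoch_s).
    """
    n = epochs.data.shape[-1]
    df = epochs.fs / n  # bin spacing; 1 Hz for 1-s epochs
    for f in freqs.frequencies:
        if abs(f / df - round(f / df)) > 1e-9:
            raise ValueError(
                f"frequency {f} Hz is off-bin: must be an integer multiple of "
                f"the epoch resolution {df} Hz"
            )
    if method == "dft":
        coeffs = _dft_coefficients(epochs.data, epochs.fs, freqs.frequencies)
    elif method == "rls":
        coeffs = _rls_coefficients(epochs.data, epochs.fs, freqs.frequencies,
                                   forgetting=rls_forgetting)
    else:
        raise ValueError(f"unknown method {method!r}")
    coeffs = coeffs.astype(complex)
    coeffs[~epochs.valid_mask] = complex(np.nan, np.nan)
    return SpectralCoefficients(
        coeffs=coeffs,
        freqs=freqs,
        valid_mask=epochs.valid_mask.copy(),
        subject_id=epochs.subject_id,
        condition_id=epochs.condition_id,
    )
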