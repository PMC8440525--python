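"""Group-delay latency from the slope of phase versus frequency.

A fixed processing delay tau produces a linear phase-frequency relation
``phi(f) = phi0 - 2 pi f tau``; the latency is read off the fitted slope.
Wrapped phases are first lifted onto a consistent branch by searching
integer 2-pi offsets (bounded window, non-positive slope, smallest
physical delay preferred).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ssvep_rca.inferential import wrap_angle

logger = logging.getLogger(__name__)

__all__ = ["LatencyEstimate", "unwrap_phases", "fit_phase_slope",
           "estimate_component_latency"]

BRANCH_WINDOW = 4  # |k| bound on per-point 2-pi offsets


@dataclass
class LatencyEstimate:
    tau_ms: float | None
    se_ms: float | None            # None when < 3 points
    harmonics_used: tuple[float, ...]
    intercept: float | None = None  # radians
    fit_residual: float | None = None  # RMS radians
    estimable: bool = True
    reason: str = ""
    ambiguous_branch: bool = field(default=False)

    @classmethod
    def not_estimable(cls, reason: str,
                      harmonics: tuple[float, ...] = ()) -> "LatencyEstimate":
        return cls(tau_ms=None, se_ms=None, harmonics_used=harmonics,
                   estimable=False, reason=reason)


def _ols_sse(f: np.ndarray, phi: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, SSE)."""
    slope, intercept = np.polyfit(f, phi, 1)
    resid = phi - (intercept + slope * f)
    return float(slope), float(intercept), float(resid @ resid)


def unwrap_phases(
    freqs: np.ndarray,
    wrapped_phases: np.ndarray,
    k_max: int = BRANCH_WINDOW,
    ambiguity_tol: float = 1e-9,
) -> np.ndarray:
    """Lift wrapped phases onto the 2-pi branch best explained by a line
    with non-positive slope.

    Adds integer multiples of 2 pi per point (|k| <= ``k_max``, first point
    anchored at k = 0) to minimize the squared deviation from the
    least-squares line over all branch assignments with non-positive fitted
    slope.  Ties within ``ambiguity_tol`` are resolved toward the smallest
    physical delay and flagged in the log.
    """
    f = np.asarray(freqs, dtype=float)
    phi = np.asarray(wrapped_phases, dtype=float)
    if f.size != phi.size:
        raise ValueError("freqs and phases must have equal length")
    if np.any(np.diff(f) <= 0):
        raise ValueError("freqs must be strictly increasing")
    if f.size < 2:
        return phi.copy()
    if f.size > 6:
        # exhaustive branch search is exponential; fall back to sequential
        # unwrapping for long harmonic ladders
        return np.unwrap(phi)

    two_pi = 2.0 * math.pi
    candidates: list[tuple[float, float, np.ndarray]] = []  # (sse, |slope|, lifted)
    for ks in itertools.product(range(-k_max, k_max + 1), repeat=f.size - 1):
        lifted = phi.copy()
        lifted[1:] += two_pi * np.asarray(ks)
        slope, _, sse = _ols_sse(f, lifted)
        if slope > 1e-12:
            continue
        candidates.append((sse, abs(slope), lifted))
    if not candidates:  # only positive-slope fits exist; fall back to flat branch
        return phi.copy()
    min_sse = min(c[0] for c in candidates)
    # branches whose fit quality is indistinguishable from the best; prefer
    # the smallest physical delay (smallest |slope|) among them
    tol = max(ambiguity_tol, 1e-9 * (1.0 + min_sse))
    eligible = [c for c in candidates if c[0] <= min_sse + tol]
    best = min(eligible, key=lambda c: c[1])
    distinct = {round(c[1], 9) for c in eligible}
    if len(distinct) > 1:
        logger.warning(
            "ambiguous phase branch: %d assignment(s) fit equally well; "
            "smallest-delay branch chosen", len(distinct),
        )
    return best[2]


def fit_phase_slope(freqs: np.ndarray, unwrapped_phases: np.ndarray) -> LatencyEstimate:
    """Ordinary least squares ``phi(f) = b + s f``; latency is
    ``-s / (2 pi) * 1000`` ms.

    The slope's standard error is propagated to ``se_ms`` when there are at
    least 3 points; with exactly 2 points the standard error is unavailable.
    """
    f = np.asarray(freqs, dtype=float)
    phi = np.asarray(unwrapped_phases, dtype=float)
    if f.size < 2:
        raise ValueError(
            "at least 2 significant harmonics are required to fit a phase slope"
        )
    if f.size == 2:
        slope = (phi[1] - phi[0]) / (f[1] - f[0])
        intercept = phi[0] - slope * f[0]
        resid_rms = 0.0
        se_ms = None
    else:
        res = stats.linregress(f, phi)
        slope, intercept = float(res.slope), float(res.intercept)
        resid = phi - (intercept + slope * f)
        resid_rms = float(np.sqrt(np.mean(resid**2)))
        se_ms = float(res.stderr) / (2.0 * math.pi) * 1000.0
    tau_ms = -slope / (2.0 * math.pi) * 1000.0
    return LatencyEstimate(
        tau_ms=tau_ms,
        se_ms=se_ms,
        harmonics_used=tuple(float(x) for x in f),
        intercept=intercept,
        fit_residual=resid_rms,
    )


def estimate_component_latency(
    subject_coeffs: np.ndarray,
    freqs: tuple[float, ...],
    significant: np.ndarray,
) -> LatencyEstimate:
    """Latency of one component from harmonics with significant responses.

    ``subject_coeffs`` is (n_subjects, n_harmonics) complex; the phase at
    each significant harmonic is taken from the group-mean complex
    coefficient (coherent average), unwrapped, and fit.  With fewer than
    two significant harmonics a non-estimable result is returned (no
    exception), mirroring how single-harmonic conditions are reported.
    """
    sig = np.asarray(significant, dtype=bool)
    f_sig = np.asarray(freqs, dtype=float)[sig]
    if f_sig.size < 2:
        return LatencyEstimate.not_estimable(
            f"only {f_sig.size} significant harmonic(s); need >= 2",
            harmonics=tuple(float(x) for x in f_sig),
        )
    group_mean = np.nanmean(np.asarray(subject_coeffs), axis=0)[sig]
    wrapped = wrap_angle(np.angle(group_mean))
    unwrapped = unwrap_phases(f_sig, wrapped)
    return fit_phase_slope(f_sig, unwrapped)
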