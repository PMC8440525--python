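"""Group statistics on component-space complex coefficients.

Per-subject complex means (averaged over that subject's valid epochs) are
the sampling units; all tests operate across the distribution of subjects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "ErrorEllipse",
    "subject_means",
    "hotelling_t2_zero",
    "fdr_adjust",
    "error_ellipse",
    "circular_phase_test",
    "watson_williams",
    "phase_diff_to_latency",
    "wrap_angle",
]


@dataclass
class TestResult:
    statistic: float   # Hotelling T^2
    p: float
    df: tuple[int, int]
    harmonic: float | None = None
    component: int | None = None
    p_fdr: float | None = None
    significant: bool | None = None


@dataclass
class ErrorEllipse:
    center: complex
    semi_axes: tuple[float, float]  # (major, minor)
    orientation: float              # radians, major-axis angle
    degenerate: bool = False


def subject_means(projected: np.ndarray, subject_ids: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Average projected trial coefficients per subject.

    ``projected`` is (n_trials, n_components, n_harmonics) complex; returns
    (n_subjects, n_components, n_harmonics) plus the sorted subject labels.
    Per-subject averaging precedes all group statistics.
    """
    labels = sorted(set(subject_ids.tolist()))
    out = np.stack([
        np.nanmean(projected[subject_ids == s], axis=0) for s in labels
    ])
    return out, labels


def hotelling_t2_zero(samples: np.ndarray) -> TestResult:
    """One-sample Hotelling T^2 of the bivariate (re, im) mean against the
    origin: ``T2 = n m^T S^{-1} m``, F-transformed with (2, n-2) df.
    """
    z = np.asarray(samples).ravel()
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    X = np.column_stack([z.real, z.imag])
    m = X.mean(axis=0)
    S = np.cov(X, rowvar=False)
    if np.linalg.cond(S) > 1e12:
        raise ValueError("singular sample covariance of (re, im) coefficients")
    t2 = float(n * m @ np.linalg.solve(S, m))
    f_stat = (n - 2) / (2.0 * (n - 1)) * t2
    p = float(stats.f.sf(f_stat, 2, n - 2))
    return TestResult(statistic=t2, p=p, df=(2, n - 2))


def fdr_adjust(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` sets the comparison-family size (defaults to ``len(p_values)``);
    monotonicity is enforced and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValueError("family size m cannot be below the number of tests")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def error_ellipse(samples: np.ndarray) -> ErrorEllipse:
    """Standard-error ellipse of the complex mean.

    Axes and orientation come from the eigendecomposition of the (re, im)
    sample covariance divided by n.
    """
    z = np.asarray(samples).ravel()
    if z.size < 3:
        raise ValueError("need at least 3 samples")
    X = np.column_stack([z.real, z.imag])
    S = np.cov(X, rowvar=False) / z.size
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 0.0, None)
    major, minor = math.sqrt(vals[1]), math.sqrt(vals[0])
    orientation = float(math.atan2(vecs[1, 1], vecs[0, 1]))
    degenerate = minor <= 1e-12 * max(major, 1e-300)
    if degenerate:
        logger.warning("collinear samples: error ellipse degenerates to a segment")
    return ErrorEllipse(
        center=complex(X[:, 0].mean(), X[:, 1].mean()),
        semi_axes=(major, minor),
        orientation=orientation,
        degenerate=degenerate,
    )


def wrap_angle(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    out = np.angle(np.exp(1j * np.asarray(phi, dtype=float)))
    # np.angle returns [-pi, pi); map -pi to +pi for the (-pi, pi] convention
    out = np.where(np.isclose(out, -np.pi), np.pi, out)
    return float(out) if np.isscalar(phi) else out


def _kappa_mle(rbar: float, n: int) -> float:
    """Best-Fisher approximation to the von Mises concentration MLE."""
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    if n <= 15:  # small-sample bias correction (Fisher 1993)
        k = max(k - 2.0 / (n * k), 0.0) if k < 2 else k * (n - 1) ** 3 / (n**3 + n)
    return float(k)


def circular_phase_test(
    phases_a: np.ndarray, phases_b: np.ndarray
) -> tuple[float, float]:
    """Paired circular test of zero mean direction of per-subject phase
    differences ``b - a``.

    Returns ``(p, mean_difference)`` with the circular mean difference in
    (-pi, pi].  The p-value comes from the large-sample von Mises test of
    mean direction (z = theta / sigma, sigma = 1/sqrt(n R kappa)).
    """
    a = np.asarray(phases_a, float).ravel()
    b = np.asarray(phases_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = wrap_angle(b - a)
    n = d.size
    C, S = np.cos(d).mean(), np.sin(d).mean()
    rbar = float(np.hypot(C, S))
    if rbar < 1e-12:
        raise ValueError("zero resultant length: mean phase difference undefined")
    theta = float(math.atan2(S, C))
    if rbar < 0.45:
        logger.warning(
            "low resultant length (%.2f): circular test assumptions are weak", rbar
        )
    if rbar > 1 - 1e-12:  # all differences identical
        p = 1.0 if abs(theta) < 1e-12 else 0.0
        return p, wrap_angle(theta)
    kappa = _kappa_mle(rbar, n)
    sigma = 1.0 / math.sqrt(n * rbar * kappa)
    z = theta / sigma
    p = float(2.0 * stats.norm.sf(abs(z)))
    return p, wrap_angle(theta)


def watson_williams(phases_a: np.ndarray, phases_b: np.ndarray) -> float:
    """Two-sample Watson-Williams F-test for equal mean directions (p-value).

    Provided as the unpaired alternative to :func:`circular_phase_test`.
    """
    groups = [np.asarray(g, float).ravel() for g in (phases_a, phases_b)]
    n = sum(g.size for g in groups)
    Rs = [np.hypot(np.cos(g).sum(), np.sin(g).sum()) for g in groups]
    allp = np.concatenate(groups)
    R = float(np.hypot(np.cos(allp).sum(), np.sin(allp).sum()))
    rw = sum(Rs) / n
    kappa = _kappa_mle(rw, n)
    correction = 1 + 3.0 / (8 * kappa) if kappa > 0 else 1.0
    num = (n - 2) * (sum(Rs) - R)
    den = n - sum(Rs)
    if den <= 0:
        return 1.0 if abs(sum(Rs) - R) < 1e-12 else 0.0
    f_stat = correction * num / den
    return float(stats.f.sf(f_stat, 1, n - 2))


def phase_diff_to_latency(delta_phi: float, f_hz: float) -> float:
    """Convert a phase difference to milliseconds at frequency ``f_hz``:
    ``dt = wrap(delta_phi) / (2 pi f) * 1000``.
    """
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    return float(wrap_angle(delta_phi)) / (2.0 * math.pi * f_hz) * 1000.0
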