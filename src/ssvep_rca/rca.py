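"""Reliable Components Analysis.

Spatial filters that maximize trial-to-trial covariance relative to
within-trial covariance of the stacked real/imaginary spectral coefficients.
The solver forms an across-trial covariance (mean cross-covariance over
ordered trial pairs, symmetrized) and a pooled within-trial covariance,
then solves the generalized eigenproblem inside the top-``rank_k``
principal subspace of the within-trial covariance.  Missing
(epoch, sensor) entries are handled by pairwise-complete accumulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from ssvep_rca.spectral import HarmonicSet, SpectralCoefficients

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTrials",
    "RcaModel",
    "build_feature_trials",
    "train_rca",
    "train_joint",
    "forward_model",
    "align_signs",
    "reliability_explained",
    "project",
    "topography_correlation",
]

RANK_EIGENVALUE_FLOOR = 1e-4  # relative within-covariance eigenvalue cutoff


@dataclass
class FeatureTrials:
    """Trial collection: sensor x feature matrices with a missing-entry mask.

    Features are stacked (re, im) pairs over the selected harmonics, so
    ``n_features = 2 * n_harmonics``.  ``X`` holds NaN where a trial's
    sensor was rejected; ``mask`` is True where data are present.
    """

    X: np.ndarray          # (n_trials, n_sensors, n_features)
    mask: np.ndarray       # (n_trials, n_sensors) bool
    freqs: HarmonicSet
    subject_ids: np.ndarray  # (n_trials,) str
    condition_ids: np.ndarray  # (n_trials,) str

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.X.shape[1]

    @property
    def n_features(self) -> int:
        return self.X.shape[2]


@dataclass
class RcaModel:
    """Trained spatial filters with forward models and reliability accounting.

    ``W`` (sensor x component) are the filters, ``A`` the forward-model
    topographies ``R_within W (W^T R_within W)^{-1}``; components are
    ordered by decreasing eigenvalue.
    """

    W: np.ndarray
    A: np.ndarray
    eigenvalues: np.ndarray        # all retained generalized eigenvalues, desc
    reliability_fraction: np.ndarray  # per returned component, in [0, 1]
    rank_k: int
    R_within: np.ndarray
    R_across: np.ndarray
    sign_convention: np.ndarray | None = None  # per-component +-1 applied

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


def build_feature_trials(
    coeffs: SpectralCoefficients | list[SpectralCoefficients],
    harmonic_subset: tuple[float, ...] | None = None,
) -> FeatureTrials:
    """Stack per-epoch complex coefficients into (re, im) feature trials.

    Accepts one or several coefficient blocks (e.g. one per subject); epochs
    are pooled in order.  ``harmonic_subset`` selects a subset of the
    computed frequencies (defaults to all).
    """
    blocks = coeffs if isinstance(coeffs, list) else [coeffs]
    if not blocks or sum(b.coeffs.shape[0] for b in blocks) == 0:
        raise ValueError("empty trial set")
    freqs0 = blocks[0].freqs
    subset = tuple(harmonic_subset) if harmonic_subset is not None \
        else freqs0.frequencies
    missing = [f for f in subset if f not in freqs0.frequencies]
    if missing:
        raise ValueError(f"harmonics {missing} were not computed")
    sel = [freqs0.frequencies.index(f) for f in subset]

    xs, ms, subj, cond = [], [], [], []
    for b in blocks:
        if b.freqs.frequencies != freqs0.frequencies:
            raise ValueError("coefficient blocks have mismatched harmonic sets")
        c = b.coeffs[:, :, sel]
        feat = np.empty(c.shape[:2] + (2 * len(sel),))
        feat[:, :, 0::2] = c.real
        feat[:, :, 1::2] = c.imag
        feat[~b.valid_mask] = np.nan
        xs.append(feat)
        ms.append(b.valid_mask)
        subj.extend([b.subject_id] * c.shape[0])
        cond.extend([b.condition_id] * c.shape[0])
    freqs = replace(freqs0, frequencies=subset)
    return FeatureTrials(
        X=np.concatenate(xs, axis=0),
        mask=np.concatenate(ms, axis=0),
        freqs=freqs,
        subject_ids=np.array(subj),
        condition_ids=np.array(cond),
    )


def _covariances(trials: FeatureTrials) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete within- and across-trial sensor covariances.

    Sum over ordered trial pairs is computed via the identity
    ``sum_{i != j} X_i^T X_j = S^T S - sum_i X_i^T X_i`` with missing
    entries zero-filled and per-entry pair counts tracked separately.
    """
    Z = np.nan_to_num(trials.X, nan=0.0)          # (T, S, F)
    V = trials.mask.astype(float)                  # (T, S)
    F = trials.n_features

    within_sum = np.einsum("tsf,tuf->su", Z, Z)
    S_total = Z.sum(axis=0)                        # (S, F)
    across_sum = S_total @ S_total.T - within_sum

    c = V.sum(axis=0)                              # valid trials per sensor
    cw = V.T @ V                                   # both-valid trial counts
    ca = np.outer(c, c) - cw                       # ordered-pair counts
    with np.errstate(invalid="ignore", divide="ignore"):
        R_within = np.where(cw > 0, within_sum / (cw * F), 0.0)
        R_across = np.where(ca > 0, across_sum / (ca * F), 0.0)
    R_within = 0.5 * (R_within + R_within.T)
    R_across = 0.5 * (R_across + R_across.T)
    return R_within, R_across


def train_rca(
    trials: FeatureTrials,
    n_components: int = 2,
    rank_k: int | None = None,
) -> RcaModel:
    """Solve the symmetrized generalized eigenproblem R_across w = l R_within w.

    The problem is whitened inside the top-``rank_k`` principal subspace of
    ``R_within`` (default: all eigenvalues at >= 1e-4 of the largest) and the
    eigenvectors are mapped back to sensor space, ordered by decreasing
    eigenvalue.  Deterministic given trial order.
    """
    if trials.n_trials < 2:
        raise ValueError("need at least 2 trials")
    if rank_k is not None and rank_k > trials.n_sensors:
        raise ValueError("rank_k cannot exceed the sensor count")
    R_within, R_across = _covariances(trials)

    d, U = np.linalg.eigh(R_within)
    d, U = d[::-1], U[:, ::-1]
    n_eff = int(np.sum(d >= RANK_EIGENVALUE_FLOOR * max(d[0], 1e-300)))
    k = n_eff if rank_k is None else min(rank_k, n_eff)
    if rank_k is not None and n_eff < rank_k:
        logger.warning("within-trial covariance rank %d below requested %d",
                       n_eff, rank_k)
    if n_components > k:
        raise ValueError(
            f"n_components={n_components} exceeds usable rank {k}"
        )

    Y = U[:, :k] / np.sqrt(d[:k])                  # whitening map
    M = Y.T @ R_across @ Y
    M = 0.5 * (M + M.T)
    lam, Q = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam, Q = lam[order], Q[:, order]
    W_full = Y @ Q

    # deterministic sign: largest-|w| entry positive
    for j in range(W_full.shape[1]):
        i = int(np.argmax(np.abs(W_full[:, j])))
        if W_full[i, j] < 0:
            W_full[:, j] *= -1.0

    W = W_full[:, :n_components]
    A = forward_model_matrix(W, R_within)
    return RcaModel(
        W=W,
        A=A,
        eigenvalues=lam,
        reliability_fraction=reliability_explained(lam)[:n_components],
        rank_k=k,
        R_within=R_within,
        R_across=R_across,
    )


def train_joint(
    trials_by_condition: list[FeatureTrials],
    n_components: int = 2,
    rank_k: int | None = None,
) -> RcaModel:
    """Pool trials over conditions and train one shared model.

    Conditions must share sensor count and feature layout (frequency labels
    may differ; feature slots must align).
    """
    if len(trials_by_condition) < 2:
        raise ValueError("need at least 2 conditions for joint training")
    first = trials_by_condition[0]
    for t in trials_by_condition:
        if t.n_trials == 0:
            raise ValueError("a condition has no trials")
        if (t.n_sensors, t.n_features) != (first.n_sensors, first.n_features):
            raise ValueError("incompatible feature layouts across conditions")
    pooled = FeatureTrials(
        X=np.concatenate([t.X for t in trials_by_condition], axis=0),
        mask=np.concatenate([t.mask for t in trials_by_condition], axis=0),
        freqs=first.freqs,
        subject_ids=np.concatenate([t.subject_ids for t in trials_by_condition]),
        condition_ids=np.concatenate([t.condition_ids for t in trials_by_condition]),
    )
    return train_rca(pooled, n_components=n_components, rank_k=rank_k)


def forward_model_matrix(W: np.ndarray, R_within: np.ndarray) -> np.ndarray:
    """Forward-model topographies ``A = R_within W (W^T R_within W)^{-1}``."""
    G = W.T @ R_within @ W
    if np.linalg.cond(G) > 1e12:
        raise ValueError("W^T R_within W is singular; cannot form forward model")
    return R_within @ W @ np.linalg.inv(G)


def forward_model(model: RcaModel, R_within: np.ndarray | None = None) -> np.ndarray:
    """Forward-model topographies of a trained model (sensor x component)."""
    Rw = model.R_within if R_within is None else R_within
    return forward_model_matrix(model.W, Rw)


def reliability_explained(eigenvalues: np.ndarray) -> np.ndarray:
    """Fraction of reliability per component: ``l_i / sum_j max(l_j, 0)``
    over components with positive eigenvalues (negative ones get 0).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    pos = np.clip(lam, 0.0, None)
    total = pos.sum()
    if total <= 0:
        raise ValueError("no positive eigenvalues; reliability undefined")
    return pos / total


def project(trials: FeatureTrials, model: RcaModel) -> np.ndarray:
    """Project sensor-space trials through the filters.

    Returns complex coefficients of shape (n_trials, n_components,
    n_harmonics).  The filter is applied separately to the real and
    imaginary feature planes and recombined; missing sensors contribute
    nothing (zero-filled), matching the training mask policy.
    """
    if trials.n_sensors != model.W.shape[0]:
        raise ValueError(
            f"trial sensor count {trials.n_sensors} does not match model "
            f"({model.W.shape[0]})"
        )
    Z = np.nan_to_num(trials.X, nan=0.0)
    Y = np.einsum("sc,tsf->tcf", model.W, Z)
    return Y[:, :, 0::2] + 1j * Y[:, :, 1::2]


def align_signs(model: RcaModel, trials: FeatureTrials) -> RcaModel:
    """Resolve per-component sign ambiguity against the raw sensor data.

    Each component's sign is flipped so that the correlation between its
    projected feature course and the raw features at the sensor of maximal
    absolute topography weight is positive.  Idempotent.
    """
    Z = np.nan_to_num(trials.X, nan=0.0)
    flips = np.ones(model.n_components)
    for c in range(model.n_components):
        s_star = int(np.argmax(np.abs(model.A[:, c])))
        proj = np.einsum("s,tsf->tf", model.W[:, c], Z).ravel()
        raw = Z[:, s_star, :].ravel()
        if proj.std() == 0 or raw.std() == 0:
            logger.warning("component %d has zero variance; sign left unchanged", c)
            continue
        r = np.corrcoef(proj, raw)[0, 1]
        if r < 0:
            flips[c] = -1.0
    W = model.W * flips
    A = forward_model_matrix(W, model.R_within)
    prior = model.sign_convention if model.sign_convention is not None \
        else np.ones(model.n_components)
    return replace(model, W=W, A=A, sign_convention=prior * flips)


def topography_correlation(A_i: np.ndarray, A_j: np.ndarray) -> float:
    """Pearson correlation across sensors of two forward-model columns."""
    a, b = np.asarray(A_i, float).ravel(), np.asarray(A_j, float).ravel()
    if a.shape != b.shape:
        raise ValueError("topographies must share the montage")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance topography; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
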