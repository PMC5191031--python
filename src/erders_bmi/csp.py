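"""Common spatial patterns (CSP) and normalized log-variance features.

For a band-passed trial V (N channels × T samples) the normalized spatial
covariance is W = V Vᵀ / trace(V Vᵀ). Class covariances W̄1, W̄2 are trial
averages; the composite Wc = W̄1 + W̄2 is factored Wc = Ec λc Ecᵀ, whitened
by M = λc^{-1/2} Ecᵀ (so M Wc Mᵀ = I), and the whitened class covariances
P1 = M W̄1 Mᵀ, P2 = M W̄2 Mᵀ share eigenvectors U with eigenvalues summing
to one: λ1 + λ2 = I. The projection B = Uᵀ M simultaneously diagonalizes
both class covariances; rows of B are spatial filters, ordered by
descending λ1, and the first/last m rows maximize variance for one class
while minimizing it for the other. A trial maps to Z = B V, and the feature
vector is the log of the retained rows' variances normalized by their sum:

    F_j = log( D_j / Σ_{k=1}^{2m} D_k ),   D_j = var(Z_j).

Deterministic sign convention: each filter's largest-magnitude entry is
made positive, so a fit is bit-reproducible on identical input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from .preprocessing import EpochSet


class DegenerateTrialError(ValueError):
    """Trial with zero total power (covariance undefined)."""


class DegenerateFeatureError(ValueError):
    """A projected row has zero variance; log-feature undefined."""


def normalized_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance W = V Vᵀ / trace(V Vᵀ)."""
    v = np.asarray(trial, dtype=float)
    if v.ndim != 2:
        raise ValueError("trial must be channels × samples")
    if not np.all(np.isfinite(v)):
        raise ValueError("trial contains non-finite samples")
    if v.shape[1] < v.shape[0]:
        import warnings

        warnings.warn("fewer samples than channels; covariance is rank-deficient")
    c = v @ v.T
    tr = np.trace(c)
    if tr <= 0.0:
        raise DegenerateTrialError("all-zero trial")
    return c / tr


def trial_covariance(
    trial: np.ndarray,
    fs: float | None = None,
    segment_length_s: float = 0.2,
    mode: str = "segmented",
) -> np.ndarray:
    """Per-trial covariance for CSP fitting.

    ``segmented`` (default): average of per-200 ms-segment normalized
    covariances, matching the short-segment analysis of the feature window;
    ``whole``: one normalized covariance of the full window.
    """
    if mode == "whole" or fs is None:
        return normalized_covariance(trial)
    if mode != "segmented":
        raise ValueError(f"unknown covariance mode {mode!r}")
    seg = int(round(segment_length_s * fs))
    n = trial.shape[1] // seg
    if n < 1:
        return normalized_covariance(trial)
    covs = []
    for k in range(n):
        piece = trial[:, k * seg : (k + 1) * seg]
        if np.trace(piece @ piece.T) <= 0.0:
            continue
        covs.append(normalized_covariance(piece))
    if not covs:
        raise DegenerateTrialError("all segments have zero power")
    return np.mean(covs, axis=0)


@dataclass
class CSPModel:
    """Fitted CSP projection.

    ``full_projection`` holds all N filters (rows) ordered by descending
    class-1 eigenvalue; ``projection`` the retained first and last m rows.
    """

    projection: np.ndarray
    full_projection: np.ndarray
    eigvals_class1: np.ndarray
    eigvals_class2: np.ndarray
    m: int
    channel_labels: tuple[str, ...]
    class_pair: tuple[str, str]
    band: tuple[float, float] | None = None
    window_s: tuple[float, float] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "projection": self.projection.tolist(),
            "full_projection": self.full_projection.tolist(),
            "eigvals_class1": self.eigvals_class1.tolist(),
            "eigvals_class2": self.eigvals_class2.tolist(),
            "m": self.m,
            "channel_labels": list(self.channel_labels),
            "class_pair": list(self.class_pair),
            "band": list(self.band) if self.band else None,
            "window_s": list(self.window_s) if self.window_s else None,
        }
        text = json.dumps(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CSPModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            projection=np.asarray(d["projection"], dtype=float),
            full_projection=np.asarray(d["full_projection"], dtype=float),
            eigvals_class1=np.asarray(d["eigvals_class1"], dtype=float),
            eigvals_class2=np.asarray(d["eigvals_class2"], dtype=float),
            m=int(d["m"]),
            channel_labels=tuple(d["channel_labels"]),
            class_pair=tuple(d["class_pair"]),
            band=tuple(d["band"]) if d["band"] else None,
            window_s=tuple(d["window_s"]) if d["window_s"] else None,
        )


def _class_mean_covariance(
    trials: np.ndarray, fs: float | None, segment_length_s: float, mode: str
) -> np.ndarray:
    return np.mean(
        [trial_covariance(t, fs, segment_length_s, mode) for t in trials], axis=0
    )


def fit_csp(
    data: np.ndarray,
    labels: np.ndarray,
    class_pair: tuple[str, str],
    m: int = 2,
    fs: float | None = None,
    segment_length_s: float = 0.2,
    covariance_mode: str = "segmented",
    channel_labels: tuple[str, ...] | None = None,
    band: tuple[float, float] | None = None,
    window_s: tuple[float, float] | None = None,
    reg_eps: float = 1e-10,
) -> CSPModel:
    """Fit CSP filters on band-passed, windowed trials.

    ``data`` is trials × channels × samples restricted to the analysis band
    and feature window; rows of the result are ordered by descending
    eigenvalue of ``class_pair[0]``. Rank-deficient composite covariances
    are regularized by adding ``reg_eps``-scaled identity (trace-scaled).
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    n = data.shape[1]
    if 2 * m > n:
        raise ValueError(f"m={m} too large for {n} channels (need 2m <= N)")
    masks = [labels == c for c in class_pair]
    for c, mask in zip(class_pair, masks):
        if mask.sum() < 2:
            raise ValueError(f"class {c!r} needs at least 2 trials")
    w1 = _class_mean_covariance(data[masks[0]], fs, segment_length_s, covariance_mode)
    w2 = _class_mean_covariance(data[masks[1]], fs, segment_length_s, covariance_mode)
    wc = w1 + w2

    evals, evecs = linalg.eigh(wc)
    if evals[0] <= evals[-1] * 1e-10:
        import warnings

        warnings.warn("rank-deficient composite covariance; regularizing")
        wc = wc + reg_eps * (np.trace(wc) / n) * np.eye(n)
        evals, evecs = linalg.eigh(wc)
    whitening = (evecs / np.sqrt(evals)).T  # M = λc^{-1/2} Ecᵀ

    p1 = whitening @ w1 @ whitening.T
    p1 = 0.5 * (p1 + p1.T)
    lam1, u = linalg.eigh(p1)
    order = np.argsort(lam1)[::-1]
    lam1 = lam1[order]
    u = u[:, order]
    b = u.T @ whitening

    # deterministic sign: largest-magnitude entry of each filter positive
    idx = np.argmax(np.abs(b), axis=1)
    signs = np.sign(b[np.arange(n), idx])
    signs[signs == 0] = 1.0
    b = b * signs[:, None]

    p2 = whitening @ w2 @ whitening.T
    lam2 = np.diag(u.T @ (0.5 * (p2 + p2.T)) @ u).copy()

    projection = np.vstack([b[:m], b[n - m :]])
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(n))
    return CSPModel(
        projection=projection,
        full_projection=b,
        eigvals_class1=lam1,
        eigvals_class2=lam2,
        m=m,
        channel_labels=tuple(channel_labels),
        class_pair=tuple(class_pair),
        band=band,
        window_s=window_s,
    )


def apply_csp(model: CSPModel, trial: np.ndarray,
              channel_labels: tuple[str, ...] | None = None) -> np.ndarray:
    """Project a trial: Z = B_retained · V (2m × T)."""
    trial = np.asarray(trial, dtype=float)
    if trial.shape[0] != model.full_projection.shape[1]:
        raise ValueError("trial channel count does not match the model")
    if channel_labels is not None and tuple(channel_labels) != model.channel_labels:
        raise ValueError("trial channel order does not match the model")
    return model.projection @ trial


def log_variance_features(z: np.ndarray) -> np.ndarray:
    """Normalized log-variance features F_j = log(D_j / Σ_k D_k)."""
    z = np.asarray(z, dtype=float)
    d = z.var(axis=-1)
    if np.any(d <= 0.0):
        raise DegenerateFeatureError("zero-variance projected row")
    return np.log(d / d.sum(axis=-1, keepdims=True))


def features_from_epochs(
    model: CSPModel,
    epochs: EpochSet | np.ndarray,
    window_s: tuple[float, float] | None = None,
) -> np.ndarray:
    """Feature matrix (n_trials × 2m) from retained epochs.

    When ``epochs`` is an :class:`EpochSet`, the model's stored feature
    window (or ``window_s``) is cut on the trial clock first.
    """
    if isinstance(epochs, EpochSet):
        win = window_s or model.window_s
        data = epochs.data[:, :, epochs.clock_slice(win)] if win else epochs.data
        data = data[epochs.retained()]
    else:
        data = np.asarray(epochs, dtype=float)
    feats = np.empty((data.shape[0], 2 * model.m))
    for i, trial in enumerate(data):
        feats[i] = log_variance_features(apply_csp(model, trial))
    return feats
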