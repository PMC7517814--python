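"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = [
    "hpd",
    "nearest_psd",
    "lag1_autocorr",
    "effective_sample_size",
    "tril_vec",
    "tril_unvec",
    "tril_labels",
]


def hpd(draws, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws (highest posterior
    density interval for unimodal posteriors).

    Computed on the sorted draws: the narrowest window spanning
    ``ceil(prob * m)`` consecutive order statistics.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    m = x.size
    if m < 2:
        return float(x[0]), float(x[0])
    k = int(np.ceil(prob * m))
    k = min(max(k, 1), m)
    widths = x[k - 1:] - x[: m - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def nearest_psd(matrix: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Symmetrize and clip negative eigenvalues at ``eps`` (Frobenius-nearest
    PSD matrix for a symmetric input)."""
    sym = 0.5 * (matrix + matrix.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    vals = np.clip(vals, eps, None)
    return (vecs * vals) @ vecs.T


def lag1_autocorr(series) -> float:
    """Lag-1 autocorrelation; NaN for constant or too-short series."""
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        return float("nan")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return float("nan")
    return float(x[:-1] @ x[1:]) / denom


def effective_sample_size(series, max_lag: int | None = None) -> float:
    """ESS via the initial-positive-sequence estimator on sample
    autocorrelations."""
    x = np.asarray(series, dtype=float)
    m = x.size
    if m < 4:
        return float(m)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return float("nan")
    if max_lag is None:
        max_lag = m // 2
    tau = 1.0
    for lag in range(1, max_lag):
        rho = float(x[:-lag] @ x[lag:]) / denom
        if rho <= 0.0:
            break
        tau += 2.0 * rho
    return float(m / tau)


def tril_vec(matrix: np.ndarray) -> np.ndarray:
    """Lower triangle (including diagonal) as a flat vector, row-major."""
    i, j = np.tril_indices(matrix.shape[-1])
    return np.asarray(matrix)[..., i, j]


def tril_unvec(vec: np.ndarray, t: int) -> np.ndarray:
    """Inverse of :func:`tril_vec` producing a symmetric t x t matrix."""
    out = np.zeros(vec.shape[:-1] + (t, t))
    i, j = np.tril_indices(t)
    out[..., i, j] = vec
    out[..., j, i] = vec
    return out


def tril_labels(names, prefix: str = "") -> list[str]:
    i, j = np.tril_indices(len(names))
    return [f"{prefix}{names[a]}:{names[b]}" for a, b in zip(i, j)]
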