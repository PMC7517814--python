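"""G-matrix eigenstructure, constraint angles, and pairwise comparison.

Three complementary views of G-matrix structure:

* eigen-analysis: eigenvalues/eigenvectors of G; the leading eigenvector
  g_max is the "line of least genetic resistance" along which selection
  responses are biased.  The constraint angle theta is the angle between a
  response vector dz and g_max (folded to [0, 90] since eigenvector sign is
  arbitrary); gamma is the angle between dz and the gradient beta (signed
  directions matter, so it ranges over [0, 180]).
* random skewers: two G-matrices are similar if they convert many random
  unit selection vectors into similar response vectors; the statistic is
  the mean cosine (vector correlation) between the paired responses.
* the Flury hierarchy: nested likelihood-ratio statistics for equality,
  proportionality and common principal components (CPC) of a set of
  covariance matrices, each measured against the unrelated-matrices
  alternative.  The common basis is estimated with the Flury-Gautschi
  pairwise-rotation algorithm.

Significance for the comparison statistics is empirical, from randomized
G estimates produced by the permutation machinery (see ``permtest``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import hpd

__all__ = [
    "EigenSummary",
    "eigen_summary",
    "vector_angle",
    "posterior_theta",
    "AngleReport",
    "random_skewers",
    "rs_significance",
    "flury_cpc",
    "FluryResult",
    "flury_significance",
    "GComparisonReport",
]


# ---------------------------------------------------------------------------
# eigenstructure


@dataclass(frozen=True)
class EigenSummary:
    """Sorted eigensystem of a G-matrix.

    ``vectors[:, k]`` is the k-th PC (unit norm); ``relative`` are
    eigenvalue shares lambda_k / sum(lambda); ``g_max`` is PC1.
    """

    values: np.ndarray
    vectors: np.ndarray = field(repr=False)
    trait_names: list | None = None

    @property
    def g_max(self) -> np.ndarray:
        return self.vectors[:, 0]

    @property
    def relative(self) -> np.ndarray:
        total = self.values.sum()
        return self.values / total if total > 0 else \
            np.full_like(self.values, np.nan)

    def axis_angles(self, axis: int | str) -> np.ndarray:
        """Angle (degrees, folded to [0, 90]) of every PC with a trait axis."""
        if isinstance(axis, str):
            if self.trait_names is None or axis not in self.trait_names:
                raise ValueError(f"unknown trait axis {axis!r}")
            axis = self.trait_names.index(axis)
        e = np.zeros(self.vectors.shape[0])
        e[axis] = 1.0
        return np.array([
            vector_angle(self.vectors[:, k], e, fold=True)
            for k in range(self.vectors.shape[1])
        ])


def _canonical_order(values, vectors):
    """Descending eigenvalues; deterministic tie-break and sign convention.

    Degenerate eigenvalues are ordered lexicographically by their vector
    loadings; each vector's sign makes its largest-magnitude loading
    positive.  Seed-independent by construction.
    """
    order = np.argsort(-values, kind="stable")
    values = values[order]
    vectors = vectors[:, order]
    for k in range(values.size):
        v = vectors[:, k]
        lead = np.argmax(np.abs(v))
        if v[lead] < 0:
            vectors[:, k] = -v
    # lexicographic tie-break among (numerically) equal eigenvalues
    k = 0
    while k < values.size:
        j = k
        while j + 1 < values.size and np.isclose(values[j + 1], values[k],
                                                 rtol=1e-12, atol=1e-12):
            j += 1
        if j > k:
            block = vectors[:, k:j + 1]
            keys = [tuple(np.round(block[:, c], 12)) for c in
                    range(block.shape[1])]
            sub = sorted(range(block.shape[1]), key=lambda c: keys[c])
            vectors[:, k:j + 1] = block[:, sub]
        k = j + 1
    return values, vectors


def eigen_summary(g: np.ndarray, trait_names=None) -> EigenSummary:
    """Eigen-decomposition of a symmetric PSD G, sorted descending."""
    g = np.asarray(g, dtype=float)
    if not np.allclose(g, g.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    values, vectors = np.linalg.eigh(0.5 * (g + g.T))
    values, vectors = _canonical_order(values, vectors)
    return EigenSummary(values=values, vectors=vectors,
                        trait_names=list(trait_names) if trait_names
                        is not None else None)


def vector_angle(a, b, fold: bool = False) -> float:
    """Angle between two vectors in degrees.

    With ``fold=True`` the cosine's absolute value is used (result in
    [0, 90]); use this against eigenvectors, whose sign is arbitrary.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    c = float(a @ b) / (na * nb)
    if fold:
        c = abs(c)
    c = np.clip(c, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass(frozen=True)
class AngleReport:
    """Constraint angles: theta (dz vs g_max, posterior) and gamma
    (dz vs beta, point)."""

    theta_draws: np.ndarray = field(repr=False)
    theta_mean: float = float("nan")
    theta_hpd: tuple = (float("nan"), float("nan"))
    gamma: float | None = None


def posterior_theta(
    g_draws: np.ndarray, dz, beta=None, prob: float = 0.95,
    min_draws: int = 100,
) -> AngleReport:
    """Posterior of theta = angle(dz, g_max of each G draw), folded.

    gamma = angle(dz, beta) is computed once from the point inputs
    (unfolded: both vectors have meaningful signs).
    """
    g_draws = np.asarray(g_draws, dtype=float)
    if g_draws.shape[0] < min_draws:
        raise ValueError(f"need >= {min_draws} draws, got {g_draws.shape[0]}")
    dz = np.asarray(dz, dtype=float).ravel()
    thetas = np.empty(g_draws.shape[0])
    for k in range(g_draws.shape[0]):
        vals, vecs = np.linalg.eigh(g_draws[k])
        gmax = vecs[:, np.argmax(vals)]
        thetas[k] = vector_angle(dz, gmax, fold=True)
    lo, hi = hpd(thetas, prob)
    gamma = vector_angle(dz, beta, fold=False) if beta is not None else None
    return AngleReport(theta_draws=thetas, theta_mean=float(thetas.mean()),
                       theta_hpd=(lo, hi), gamma=gamma)


# ---------------------------------------------------------------------------
# random skewers


def random_skewers(
    g1, g2, n_skewers: int = 10_000, seed=None, dist: str = "normal",
) -> tuple[float, np.ndarray]:
    """Mean vector correlation of responses to random selection skewers.

    Skewers are unit vectors; with ``dist="normal"`` they are normalized
    i.i.d. standard normals (isotropic, rotation-invariant); ``"uniform"``
    draws components uniform on [-1, 1] before normalizing.  The per-skewer
    statistic is the cosine of the angle between the two response vectors
    r_k = G_k s.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.shape[0] != g1.shape[1]:
        raise ValueError("G matrices must be square with equal dimension")
    t = g1.shape[0]
    rng = np.random.default_rng(seed)
    if dist == "normal":
        s = rng.standard_normal((n_skewers, t))
    elif dist == "uniform":
        s = rng.uniform(-1.0, 1.0, size=(n_skewers, t))
    else:
        raise ValueError(f"unknown skewer distribution {dist!r}")
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    if np.array_equal(g1, g2):
        # identical matrices give identical responses: correlation 1 exactly
        return 1.0, np.ones(n_skewers)
    r1 = s @ g1.T
    r2 = s @ g2.T
    num = np.einsum("ij,ij->i", r1, r2)
    den = np.linalg.norm(r1, axis=1) * np.linalg.norm(r2, axis=1)
    corr = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(np.nanmean(corr)), corr


def _empirical_tails(null: np.ndarray, observed: float) -> dict:
    null = np.asarray(null, dtype=float)
    n = null.size
    p_left = max(np.mean(null <= observed), 1.0 / (n + 1))
    p_right = max(np.mean(null >= observed), 1.0 / (n + 1))
    tail = "left" if p_left <= p_right else "right"
    return {"p_left": float(min(p_left, 1.0)),
            "p_right": float(min(p_right, 1.0)), "tail": tail,
            "n_null": int(n)}


def rs_significance(
    null_g1, null_g2, observed_rs: float, *, n_skewers: int = 1000,
    seed=None, pairing: str = "independent",
) -> dict:
    """Empirical P-value of an observed random-skewers correlation.

    The null distribution pairs randomized estimates of the two matrices
    (independently shuffled pairing by default, index-paired with
    ``pairing="index"``) and recomputes the RS statistic for each pair.
    Both tail probabilities are returned with the extreme tail flagged.
    """
    null_g1 = list(null_g1)
    null_g2 = list(null_g2)
    n = min(len(null_g1), len(null_g2))
    if n < 1:
        raise ValueError("need at least one null replicate")
    if n < 50:
        import warnings

        warnings.warn(f"only {n} null replicates: coarse P resolution",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n) if pairing == "independent" else np.arange(n)
    stats = np.empty(n)
    for k in range(n):
        stats[k], _ = random_skewers(
            null_g1[k], null_g2[order[k]], n_skewers=n_skewers,
            seed=rng.integers(2**31 - 1),
        )
    out = _empirical_tails(stats, observed_rs)
    out["null_stats"] = stats
    return out


# ---------------------------------------------------------------------------
# Flury hierarchy


def _logdet(m) -> float:
    sign, val = np.linalg.slogdet(m)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return float(val)


def _equality_stat(mats, ns) -> float:
    pooled = sum(n * m for n, m in zip(ns, mats)) / sum(ns)
    ld = _logdet(pooled)
    return float(sum(n * (ld - _logdet(m)) for n, m in zip(ns, mats)))


def _proportionality_stat(mats, ns, tol=1e-10, max_iter=500):
    """ML fit of S_i = rho_i * Sigma; returns the LR statistic vs
    unrelated."""
    t = mats[0].shape[0]
    rho = np.ones(len(mats))
    prev = np.inf
    for _ in range(max_iter):
        sigma = sum(n / r * m for n, r, m in zip(ns, rho, mats)) / sum(ns)
        rho = np.array([
            np.trace(np.linalg.solve(sigma, m)) / t for m in mats
        ])
        stat = float(sum(
            n * (np.log(r ** t) + _logdet(sigma) - _logdet(m))
            for n, r, m in zip(ns, rho, mats)
        ))
        if abs(prev - stat) < tol:
            break
        prev = stat
    return stat


def _fg_pair_rotation(h_list, ns, n_grid: int = 64):
    """Optimal 2x2 rotation for one FG pair.

    The pair objective f(angle) = sum_i n_i (log d_i1 + log d_i2), with
    d_i1/d_i2 the rotated diagonal entries of the 2x2 subproblems, is
    smooth and pi-periodic; a coarse grid locates the global basin and a
    bounded Brent step polishes it.  This avoids the saddle points that a
    fixed-point eigen-iteration can latch onto.
    """
    from scipy.optimize import minimize_scalar

    h11 = np.array([h[0, 0] for h in h_list])
    h12 = np.array([h[0, 1] for h in h_list])
    h22 = np.array([h[1, 1] for h in h_list])
    ns_arr = np.asarray(ns, dtype=float)

    def f(theta):
        c, s = np.cos(theta), np.sin(theta)
        d1 = c * c * h11 + 2 * c * s * h12 + s * s * h22
        d2 = s * s * h11 - 2 * c * s * h12 + c * c * h22
        if np.any(d1 <= 0) or np.any(d2 <= 0):
            return np.inf
        return float(ns_arr @ (np.log(d1) + np.log(d2)))

    grid = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    vals = [f(th) for th in grid]
    k = int(np.argmin(vals))
    span = np.pi / n_grid
    res = minimize_scalar(f, bounds=(grid[k] - span, grid[k] + span),
                          method="bounded",
                          options={"xatol": 1e-12})
    theta = res.x if res.fun <= vals[k] else grid[k]
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _fg_objective(b, mats, ns) -> float:
    total = 0.0
    for n, m in zip(ns, mats):
        bt = b.T @ m @ b
        total += n * (float(np.sum(np.log(np.diag(bt)))) - _logdet(m))
    return total


@dataclass
class FluryResult:
    """Common-basis estimate and hierarchy statistics vs unrelated.

    ``stats`` maps ``equality | proportionality | cpc`` to log-likelihood-
    ratio statistics (each >= 0; 0 means the level fits perfectly).
    """

    basis: np.ndarray = field(repr=False)
    stats: dict = field(default_factory=dict)
    converged: bool = True
    n_sweeps: int = 0
    objective: float = float("nan")


def flury_cpc(
    mats, weights=None, *, tol: float = 1e-8, max_sweeps: int = 500,
) -> FluryResult:
    """Common principal components by the Flury-Gautschi algorithm.

    Finds an orthonormal basis B minimizing

        sum_i n_i * log( det(diag(B^T S_i B)) / det(B^T S_i B) )

    by pairwise Jacobi-style rotations, and evaluates the hierarchy
    statistics (equality, proportionality, CPC; each against unrelated).

    Parameters
    ----------
    mats : sequence of (t, t) symmetric PD matrices
    weights : sequence of sample sizes n_i (default: all 1)
    """
    mats = [np.asarray(m, dtype=float) for m in mats]
    if len(mats) < 2:
        raise ValueError("need at least two matrices")
    t = mats[0].shape[0]
    for m in mats:
        if m.shape != (t, t):
            raise ValueError("matrices must share dimension")
    ns = list(weights) if weights is not None else [1.0] * len(mats)
    if any(n <= 0 for n in ns):
        raise ValueError("weights must be positive")

    pooled = sum(n * m for n, m in zip(ns, mats)) / sum(ns)
    _, b = np.linalg.eigh(pooled)
    obj = _fg_objective(b, mats, ns)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        for p in range(t - 1):
            for q_col in range(p + 1, t):
                j = b[:, [p, q_col]]
                h_list = [j.T @ m @ j for m in mats]
                rot = _fg_pair_rotation(h_list, ns)
                b[:, [p, q_col]] = j @ rot
        # re-orthonormalize against drift
        u, _, vt = np.linalg.svd(b)
        b = u @ vt
        new_obj = _fg_objective(b, mats, ns)
        if abs(obj - new_obj) < tol:
            obj = new_obj
            converged = True
            break
        obj = new_obj

    stats = {
        "equality": _equality_stat(mats, ns),
        "proportionality": _proportionality_stat(mats, ns),
        "cpc": max(obj, 0.0),
    }
    return FluryResult(basis=b, stats=stats, converged=converged,
                       n_sweeps=sweeps, objective=obj)


def flury_significance(
    observed_stats: dict, null_g1, null_g2, weights=None, seed=None,
    pairing: str = "independent",
) -> pd.DataFrame:
    """Empirical P-values for the hierarchy statistics.

    Null statistics are recomputed on pairs of randomized G estimates; the
    P-value per level is the rank of the observed statistic in that null
    distribution (both tails reported, extreme tail flagged).
    """
    null_g1 = list(null_g1)
    null_g2 = list(null_g2)
    n = min(len(null_g1), len(null_g2))
    if n < 1:
        raise ValueError("need at least one null replicate")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n) if pairing == "independent" else np.arange(n)
    levels = list(observed_stats)
    null_vals = {lev: np.empty(n) for lev in levels}
    for k in range(n):
        res = flury_cpc([null_g1[k], null_g2[order[k]]], weights)
        for lev in levels:
            null_vals[lev][k] = res.stats[lev]
    rows = []
    for lev in levels:
        tails = _empirical_tails(null_vals[lev], observed_stats[lev])
        rows.append((lev, observed_stats[lev], tails["p_left"],
                     tails["p_right"], tails["tail"]))
    return pd.DataFrame(
        rows, columns=["level", "stat", "p_left", "p_right", "tail"]
    )


@dataclass
class GComparisonReport:
    """Full pairwise comparison: random skewers + Flury hierarchy."""

    rs_mean: float
    rs_p: dict
    flury: FluryResult
    flury_p: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("random_skewers", self.rs_mean,
                 self.rs_p.get("p_left", np.nan),
                 self.rs_p.get("p_right", np.nan),
                 self.rs_p.get("tail", ""))]
        for lev, stat in self.flury.stats.items():
            if self.flury_p is not None:
                sub = self.flury_p.set_index("level").loc[lev]
                rows.append((lev, stat, sub["p_left"], sub["p_right"],
                             sub["tail"]))
            else:
                rows.append((lev, stat, np.nan, np.nan, ""))
        return pd.DataFrame(
            rows, columns=["stat", "value", "p_left", "p_right", "tail"]
        )
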