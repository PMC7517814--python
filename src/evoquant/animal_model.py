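"""Bayesian multivariate animal model.

The model partitions each individual's trait vector into a generation mean
(fixed block effect), an additive genetic effect structured by pedigree
relatedness, optional among-dam and among-sire effects (absorbing maternal
and paternal environmental/common-environment variance), and a residual:

    y_i = mu_gen(i) + a_i + d_dam(i) + s_sire(i) + e_i

    vec(a) ~ MVN(0, G (x) A)      vec(d) ~ MVN(0, D (x) I)
    vec(s) ~ MVN(0, S (x) I)      vec(e) ~ MVN(0, R (x) I)

with A the additive relationship matrix.  G is the genetic
variance-covariance matrix of the traits; its posterior is the object of
interest.

Estimation is a blocked Gibbs sampler.  Covariance components get
conditional inverse-Wishart updates under a weakly informative
inverse-Wishart prior stated in the (V, nu) convention -- limit variance 1,
covariance 0, degree of belief nu = 0.002 -- i.e. scale matrix
Psi = nu * V with V = I and df = nu.  Breeding values are sampled as one
exact block using the eigendecomposition A = U Lam U^T, which diagonalizes
the prior so each rotated individual has an independent t-variate normal
full conditional.  Missing trait values are imputed each sweep from their
conditional normal given the observed traits (data augmentation), so
trait-wise missingness is handled without dropping individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, invwishart

from ._utils import (
    effective_sample_size,
    hpd,
    lag1_autocorr,
    nearest_psd,
    tril_labels,
    tril_unvec,
    tril_vec,
)
from .pedigree import Pedigree, build_a_matrix
from .traits import TraitMatrix

__all__ = ["AnimalModel", "AnimalModelResults", "ChainSettings", "FULL_CHAIN",
           "DEFAULT_CHAIN"]


@dataclass(frozen=True)
class ChainSettings:
    """MCMC chain configuration (iterations include burn-in)."""

    n_iter: int = 20_000
    burnin: int = 5_000
    thin: int = 15

    def __post_init__(self):
        if self.n_iter <= self.burnin:
            raise ValueError("chain length must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burnin) // self.thin


#: full-length settings used for publication-scale runs (2000 draws)
FULL_CHAIN = ChainSettings(n_iter=1_200_000, burnin=200_000, thin=500)
#: scaled-down default for desk-scale analyses and tests
DEFAULT_CHAIN = ChainSettings(n_iter=20_000, burnin=5_000, thin=15)


class AnimalModel:
    """Multivariate animal model for pedigreed phenotype data.

    Parameters
    ----------
    traits : TraitMatrix
        Phenotypes (typically already ln/z transformed); NaN = missing.
        Every phenotyped id must appear in the pedigree.
    pedigree : Pedigree
        Validated pedigree; the relationship matrix is built internally.
    dam_sire_effects : bool
        Include among-dam and among-sire covariance components.  A term
        whose groups are all singletons is dropped with a warning (it would
        be confounded with the residual).
    prior_variance : float
        Limit variance of the inverse-Wishart prior (diagonal of V).
    prior_nu : float
        Degree of belief nu; the prior scale matrix is Psi = nu * V.
    """

    def __init__(
        self,
        traits: TraitMatrix,
        pedigree: Pedigree,
        *,
        dam_sire_effects: bool = True,
        prior_variance: float = 1.0,
        prior_nu: float = 0.002,
    ):
        self.traits = traits
        self.pedigree = pedigree
        self.prior_variance = float(prior_variance)
        self.prior_nu = float(prior_nu)

        ids = traits.ids
        ped_ids = set(pedigree.ids)
        missing = [i for i in ids if i not in ped_ids]
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped ids absent from pedigree, e.g. "
                f"{missing[:3]}"
            )

        a_full = build_a_matrix(pedigree)
        self.a_matrix = a_full.restrict(ids)
        lam, u = np.linalg.eigh(self.a_matrix.values)
        self._lam = np.clip(lam, 1e-10, None)
        self._u = u
        if np.allclose(self.a_matrix.values, np.eye(len(ids))):
            warnings.warn(
                "relationship matrix is the identity (founders only): "
                "additive and residual variances are not separately "
                "identifiable", stacklevel=2,
            )

        gen = traits.generation
        self.generation_levels = list(pd.unique(gen))
        self._gen_idx = gen.map(
            {g: k for k, g in enumerate(self.generation_levels)}
        ).to_numpy()
        counts = np.bincount(self._gen_idx)
        if (counts == 1).any():
            warnings.warn(
                "a generation block contains a single individual; its mean "
                "is weakly determined", stacklevel=2,
            )

        ped = pedigree.frame.set_index("id")
        self._dam_idx, self.dam_levels = self._parent_groups(
            ped, "dam", ids, dam_sire_effects
        )
        self._sire_idx, self.sire_levels = self._parent_groups(
            ped, "sire", ids, dam_sire_effects
        )

    @staticmethod
    def _parent_groups(ped, which, ids, enabled):
        if not enabled:
            return None, []
        parents = ped.loc[ids, which]
        known = parents.dropna()
        levels = list(pd.unique(known))
        if not levels:
            return None, []
        counts = known.value_counts()
        if (counts <= 1).all():
            warnings.warn(
                f"all {which} groups are singletons; {which} effect dropped "
                "(confounded with residual)", stacklevel=3,
            )
            return None, []
        lookup = {p: k for k, p in enumerate(levels)}
        idx = np.array([lookup.get(p, -1) if pd.notna(p) else -1
                        for p in parents])
        return idx, levels

    # ------------------------------------------------------------------
    def fit(
        self,
        chain: ChainSettings = DEFAULT_CHAIN,
        seed: int | None = None,
        start: dict | None = None,
    ) -> "AnimalModelResults":
        """Run the Gibbs sampler and return the posterior.

        Same seed and inputs produce an identical draw sequence.
        """
        rng = np.random.default_rng(seed)
        t = self.traits.t
        n = self.traits.n
        y_obs = self.traits.values()
        miss = ~np.isfinite(y_obs)
        y = y_obs.copy()
        if miss.any():
            col_means = np.nanmean(y_obs, axis=0)
            y[miss] = np.take(col_means, np.where(miss)[1])

        gen_idx = self._gen_idx
        n_gen = len(self.generation_levels)
        gen_counts = np.bincount(gen_idx, minlength=n_gen).astype(float)
        u, lam = self._u, self._lam
        psi = self.prior_nu * self.prior_variance * np.eye(t)
        nu = self.prior_nu

        use_dam = self._dam_idx is not None
        use_sire = self._sire_idx is not None
        dam_plan = self._group_plan(self._dam_idx, len(self.dam_levels)) \
            if use_dam else None
        sire_plan = self._group_plan(self._sire_idx, len(self.sire_levels)) \
            if use_sire else None

        # initial state: split the sample covariance among components
        n_comp = 2 + use_dam + use_sire
        samp_cov = np.cov(y, rowvar=False).reshape(t, t)
        samp_cov = nearest_psd(samp_cov, 1e-6) + 1e-6 * np.eye(t)
        g = samp_cov / n_comp
        r = samp_cov / n_comp
        d_cov = samp_cov / (4 * n_comp) if use_dam else None
        s_cov = samp_cov / (4 * n_comp) if use_sire else None
        if start:
            g = np.array(start.get("G", g), dtype=float)
            r = np.array(start.get("R", r), dtype=float)
        a = np.zeros((n, t))
        at = np.zeros((n, t))
        d_eff = np.zeros((len(self.dam_levels), t)) if use_dam else None
        s_eff = np.zeros((len(self.sire_levels), t)) if use_sire else None
        mu = np.zeros((n_gen, t))

        miss_patterns = self._missing_patterns(miss)

        m = chain.n_draws
        g_draws = np.empty((m, t, t))
        r_draws = np.empty((m, t, t))
        d_draws = np.empty((m, t, t)) if use_dam else None
        s_draws = np.empty((m, t, t)) if use_sire else None
        mu_draws = np.empty((m, n_gen, t))
        n_clipped = 0
        k_out = 0

        for it in range(chain.n_iter):
            fitted_re = a.copy()
            if use_dam:
                np.add(fitted_re, self._gather(d_eff, self._dam_idx, t),
                       out=fitted_re)
            if use_sire:
                np.add(fitted_re, self._gather(s_eff, self._sire_idx, t),
                       out=fitted_re)

            # -- impute missing trait values (data augmentation)
            if miss_patterns:
                mean_all = mu[gen_idx] + fitted_re
                self._impute(y, mean_all, r, miss_patterns, rng)

            # -- fixed generation means (flat prior)
            resid = y - fitted_re
            chol_r = np.linalg.cholesky(r)
            for gidx in range(n_gen):
                rows = gen_idx == gidx
                mean = resid[rows].mean(axis=0)
                mu[gidx] = mean + (chol_r @ rng.standard_normal(t)) \
                    / np.sqrt(gen_counts[gidx])

            r_inv = np.linalg.inv(r)
            # -- breeding values, one exact block via A = U Lam U^T
            ystar = y - mu[gen_idx] - (fitted_re - a)
            yt = u.T @ ystar
            g_inv = np.linalg.inv(g)
            prec = g_inv[None, :, :] / lam[:, None, None] + r_inv[None, :, :]
            cov = np.linalg.inv(prec)
            mean_t = np.einsum("kij,kj->ki", cov, yt @ r_inv.T)
            chol = np.linalg.cholesky(cov)
            at = mean_t + np.einsum(
                "kij,kj->ki", chol, rng.standard_normal((n, t))
            )
            a = u @ at

            # -- dam and sire effects, grouped by family size
            if use_dam:
                ystar = y - mu[gen_idx] - a
                if use_sire:
                    ystar -= self._gather(s_eff, self._sire_idx, t)
                self._sample_parent(
                    d_eff, dam_plan, ystar, np.linalg.inv(d_cov), r_inv, rng
                )
            if use_sire:
                ystar = y - mu[gen_idx] - a
                if use_dam:
                    ystar -= self._gather(d_eff, self._dam_idx, t)
                self._sample_parent(
                    s_eff, sire_plan, ystar, np.linalg.inv(s_cov), r_inv, rng
                )

            # -- covariance components: conditional inverse-Wishart
            e = y - mu[gen_idx] - a
            if use_dam:
                e -= self._gather(d_eff, self._dam_idx, t)
            if use_sire:
                e -= self._gather(s_eff, self._sire_idx, t)
            r = np.asarray(invwishart.rvs(df=nu + n, scale=psi + e.T @ e,
                                          random_state=rng)).reshape(t, t)
            quad = (at * (1.0 / lam)[:, None]).T @ at
            g = np.asarray(invwishart.rvs(df=nu + n, scale=psi + quad,
                                          random_state=rng)).reshape(t, t)
            if use_dam:
                d_cov = np.asarray(invwishart.rvs(
                    df=nu + len(self.dam_levels),
                    scale=psi + d_eff.T @ d_eff, random_state=rng,
                )).reshape(t, t)
            if use_sire:
                s_cov = np.asarray(invwishart.rvs(
                    df=nu + len(self.sire_levels),
                    scale=psi + s_eff.T @ s_eff, random_state=rng,
                )).reshape(t, t)

            if it >= chain.burnin and (it - chain.burnin) % chain.thin == 0:
                gd = 0.5 * (g + g.T)
                if np.linalg.eigvalsh(gd)[0] < 0:
                    gd = nearest_psd(gd)
                    n_clipped += 1
                g_draws[k_out] = gd
                r_draws[k_out] = 0.5 * (r + r.T)
                if use_dam:
                    d_draws[k_out] = 0.5 * (d_cov + d_cov.T)
                if use_sire:
                    s_draws[k_out] = 0.5 * (s_cov + s_cov.T)
                mu_draws[k_out] = mu
                k_out += 1

        return AnimalModelResults(
            model=self,
            trait_names=self.traits.trait_names,
            g_draws=g_draws[:k_out],
            r_draws=r_draws[:k_out],
            d_draws=d_draws[:k_out] if use_dam else None,
            s_draws=s_draws[:k_out] if use_sire else None,
            mu_draws=mu_draws[:k_out],
            chain=chain,
            seed=seed,
            n_clipped=n_clipped,
        )

    # -- sampler internals ------------------------------------------------
    @staticmethod
    def _gather(effects, idx, t):
        out = np.zeros((idx.shape[0], t))
        known = idx >= 0
        out[known] = effects[idx[known]]
        return out

    @staticmethod
    def _group_plan(idx, n_groups):
        """Group parent levels by family size for vectorized updates."""
        sizes = np.bincount(idx[idx >= 0], minlength=n_groups)
        plan = []
        for size in np.unique(sizes):
            if size == 0:
                continue
            groups = np.where(sizes == size)[0]
            members = {g: [] for g in groups}
            for row, g in enumerate(idx):
                if g in members:
                    members[g].append(row)
            rows = np.array([members[g] for g in groups])  # (q, size)
            plan.append((int(size), groups, rows))
        return plan

    @staticmethod
    def _sample_parent(effects, plan, ystar, c_inv, r_inv, rng):
        t = ystar.shape[1]
        for size, groups, rows in plan:
            resid_sum = ystar[rows].sum(axis=1)          # (q, t)
            prec = c_inv + size * r_inv
            cov = np.linalg.inv(prec)
            mean = resid_sum @ (cov @ r_inv).T
            chol = np.linalg.cholesky(cov)
            effects[groups] = mean + rng.standard_normal(
                (len(groups), t)
            ) @ chol.T

    @staticmethod
    def _missing_patterns(miss):
        if not miss.any():
            return []
        patterns = {}
        for row, pat in enumerate(map(tuple, miss)):
            if any(pat):
                patterns.setdefault(pat, []).append(row)
        return [(np.array(p, dtype=bool), np.array(rows))
                for p, rows in patterns.items()]

    @staticmethod
    def _impute(y, mean_all, r, patterns, rng):
        for pat, rows in patterns:
            obs = ~pat
            mu_m = mean_all[np.ix_(rows, pat)]
            if obs.any():
                r_oo = r[np.ix_(obs, obs)]
                r_mo = r[np.ix_(pat, obs)]
                gain = r_mo @ np.linalg.inv(r_oo)
                resid_o = y[np.ix_(rows, obs)] - mean_all[np.ix_(rows, obs)]
                mu_m = mu_m + resid_o @ gain.T
                cov = r[np.ix_(pat, pat)] - gain @ r_mo.T
            else:
                cov = r[np.ix_(pat, pat)]
            cov = 0.5 * (cov + cov.T) + 1e-12 * np.eye(pat.sum())
            chol = np.linalg.cholesky(cov)
            y[np.ix_(rows, pat)] = mu_m + rng.standard_normal(
                (len(rows), int(pat.sum()))
            ) @ chol.T


@dataclass
class AnimalModelResults:
    """Posterior draws of the covariance components and fixed effects.

    Every stored G draw is symmetric PSD (non-PSD draws were repaired by
    eigenvalue clipping; ``n_clipped`` counts them).
    """

    model: AnimalModel = field(repr=False)
    trait_names: list
    g_draws: np.ndarray = field(repr=False)
    r_draws: np.ndarray = field(repr=False)
    d_draws: np.ndarray | None = field(repr=False)
    s_draws: np.ndarray | None = field(repr=False)
    mu_draws: np.ndarray = field(repr=False)
    chain: ChainSettings = DEFAULT_CHAIN
    seed: int | None = None
    n_clipped: int = 0

    @property
    def n_draws(self) -> int:
        return self.g_draws.shape[0]

    @property
    def t(self) -> int:
        return len(self.trait_names)

    # -- point estimates ------------------------------------------------
    def posterior_mean(self, component: str = "G") -> np.ndarray:
        return self._component(component).mean(axis=0)

    def posterior_mode(
        self, component: str = "G", estimator: str = "kde", grid: int = 512
    ) -> np.ndarray:
        """Elementwise point estimate projected to the nearest PSD matrix.

        ``estimator="kde"`` takes the mode of a Gaussian kernel density per
        element (the convention for summarizing MCMC covariance draws);
        ``"mean"`` uses the posterior mean.
        """
        draws = self._component(component)
        if draws.shape[0] < 2 or estimator == "mean":
            return nearest_psd(draws.mean(axis=0))
        t = draws.shape[1]
        out = np.empty((t, t))
        for i in range(t):
            for j in range(i + 1):
                x = draws[:, i, j]
                if np.ptp(x) < 1e-14:
                    out[i, j] = out[j, i] = x[0]
                    continue
                kde = gaussian_kde(x)
                xs = np.linspace(x.min(), x.max(), grid)
                out[i, j] = out[j, i] = xs[np.argmax(kde(xs))]
        return nearest_psd(out)

    def _component(self, component: str) -> np.ndarray:
        draws = {
            "G": self.g_draws, "R": self.r_draws,
            "D": self.d_draws, "S": self.s_draws,
        }.get(component.upper())
        if draws is None:
            raise ValueError(f"component {component!r} not in this fit")
        return draws

    def heritability_draws(self) -> np.ndarray:
        """Per-trait h2 = G_ii / (G_ii + D_ii + S_ii + R_ii) per draw."""
        total = np.diagonal(self.g_draws, axis1=1, axis2=2) + \
            np.diagonal(self.r_draws, axis1=1, axis2=2)
        if self.d_draws is not None:
            total = total + np.diagonal(self.d_draws, axis1=1, axis2=2)
        if self.s_draws is not None:
            total = total + np.diagonal(self.s_draws, axis1=1, axis2=2)
        return np.diagonal(self.g_draws, axis1=1, axis2=2) / total

    # -- diagnostics -----------------------------------------------------
    def diagnostics(self, threshold: float = 0.1) -> pd.DataFrame:
        """Lag-1 autocorrelation and ESS per G element; mixing is flagged
        when |autocorrelation| >= ``threshold`` (or is undefined)."""
        if self.n_draws < 10:
            raise ValueError("need at least 10 draws for diagnostics")
        vecs = tril_vec(self.g_draws)
        labels = tril_labels(self.trait_names)
        rows = []
        for k, label in enumerate(labels):
            ac = lag1_autocorr(vecs[:, k])
            ess = effective_sample_size(vecs[:, k])
            flagged = bool(np.isnan(ac) or abs(ac) >= threshold)
            rows.append((label, ac, ess, flagged))
        return pd.DataFrame(
            rows, columns=["element", "lag1_autocorr", "ess", "flagged"]
        )

    # -- summaries / serialization --------------------------------------
    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        """Posterior mean and HPD interval for every G element."""
        vecs = tril_vec(self.g_draws)
        labels = tril_labels(self.trait_names)
        rows = []
        for k, label in enumerate(labels):
            lo, hi = hpd(vecs[:, k], prob)
            rows.append((label, vecs[:, k].mean(), lo, hi))
        return pd.DataFrame(
            rows, columns=["element", "mean", "hpd_lo", "hpd_hi"]
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per draw; columns are vectorized lower triangles of the
        stored components (lossless re-loading via :meth:`from_frame`)."""
        parts = {"G": self.g_draws, "R": self.r_draws}
        if self.d_draws is not None:
            parts["D"] = self.d_draws
        if self.s_draws is not None:
            parts["S"] = self.s_draws
        cols = {}
        for name, draws in parts.items():
            vec = tril_vec(draws)
            for k, lab in enumerate(tril_labels(self.trait_names,
                                                prefix=f"{name}.")):
                cols[lab] = vec[:, k]
        return pd.DataFrame(cols)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, trait_names) -> \
            "AnimalModelResults":
        t = len(trait_names)
        labels = tril_labels(trait_names)

        def unpack(prefix):
            cols = [f"{prefix}.{lab}" for lab in labels]
            if not all(c in frame.columns for c in cols):
                return None
            return tril_unvec(frame[cols].to_numpy(), t)

        g = unpack("G")
        if g is None:
            raise ValueError("frame lacks G columns")
        r = unpack("R")
        return cls(
            model=None, trait_names=list(trait_names), g_draws=g,
            r_draws=r if r is not None else np.zeros_like(g),
            d_draws=unpack("D"), s_draws=unpack("S"),
            mu_draws=np.zeros((g.shape[0], 0, t)),
        )
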