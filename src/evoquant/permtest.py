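"""Permutation-based significance of G-matrix elements.

The accuracy of a G estimate is probed by destroying the parent-offspring
signal: within each generation, offspring are reassigned dams and sires by
permuting the original dam and sire lists (independently by default, as
pairs with ``preserve_pairs=True``), the G-matrix is re-estimated on each
shuffled pedigree, and the observed elements are ranked against the
distribution of randomized point estimates.  The empirical rule is

    P = (number of random estimates below the observed value) / N,
    reported as 1 - P when the observed value sits at or above the null
    mean (so an extreme rank in either direction gives a small P),

with extreme ranks floored at 1/N (never reported as 0).  Element-wise
P-values are corrected with Benjamini-Hochberg FDR; by default all unique
elements of the symmetric G (variances and covariances) form one family,
with per-class summaries also emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .animal_model import DEFAULT_CHAIN, AnimalModel, ChainSettings
from .pedigree import Pedigree, validate_pedigree
from .traits import TraitMatrix

__all__ = [
    "shuffle_pedigree",
    "build_null",
    "element_pvalues",
    "fdr_adjust",
    "significance_summary",
    "PermutationNull",
]


def shuffle_pedigree(
    pedigree: Pedigree, seed=None, preserve_pairs: bool = False
) -> Pedigree:
    """Reassign dams and sires within each generation by permutation.

    The multiset of dam ids and sire ids per generation is preserved
    exactly; only the offspring-to-parent assignment changes.  With
    ``preserve_pairs`` the (dam, sire) couples are kept together and
    permuted as units.  Founders (both parents unknown) are untouched.
    A generation with a single offspring family cannot be shuffled and
    triggers a warning.
    """
    rng = np.random.default_rng(seed)
    f = pedigree.frame.copy()
    for gen, idx in f.groupby("generation").groups.items():
        rows = f.loc[idx]
        has_parent = rows["sire"].notna() | rows["dam"].notna()
        sub = rows.index[has_parent]
        if len(sub) == 0:
            continue
        if len(sub) == 1:
            warnings.warn(
                f"generation {gen!r} has a single non-founder; shuffle is "
                "the identity", stacklevel=2,
            )
            continue
        if preserve_pairs:
            perm = rng.permutation(len(sub))
            f.loc[sub, ["dam", "sire"]] = \
                f.loc[sub, ["dam", "sire"]].to_numpy()[perm]
        else:
            f.loc[sub, "dam"] = f.loc[sub, "dam"].to_numpy()[
                rng.permutation(len(sub))
            ]
            f.loc[sub, "sire"] = f.loc[sub, "sire"].to_numpy()[
                rng.permutation(len(sub))
            ]
    return validate_pedigree(Pedigree(f))


@dataclass
class PermutationNull:
    """N randomized point estimates of G plus the shuffle/seed manifest."""

    matrices: list = field(repr=False)
    trait_names: list
    seeds: list
    preserve_pairs: bool = False
    n_failed: int = 0

    @property
    def n(self) -> int:
        return len(self.matrices)

    def stack(self) -> np.ndarray:
        return np.stack(self.matrices)


def _replicate_seed(master_seed, k: int) -> np.random.SeedSequence:
    # spawn-key derivation: identical replicates regardless of batching
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(k,))


def build_null(
    pedigree: Pedigree,
    traits: TraitMatrix,
    n_replicates: int = 500,
    seed=None,
    *,
    chain: ChainSettings = DEFAULT_CHAIN,
    estimator: str = "mode",
    preserve_pairs: bool = False,
    dam_sire_effects: bool = True,
    first_replicate: int = 0,
    max_retries: int = 3,
) -> PermutationNull:
    """Randomized G point estimates from parent-shuffled re-fits.

    Each replicate k derives its own seed from ``(seed, k)``, so a null
    built in independent batches (via ``first_replicate``) is identical to
    a single run.  A failed re-fit is redrawn (with a fresh child seed) up
    to ``max_retries`` times and counted in ``n_failed``.
    """
    if n_replicates < 50:
        warnings.warn(
            f"N = {n_replicates} null replicates gives coarse P resolution",
            stacklevel=2,
        )
    matrices, seeds = [], []
    n_failed = 0
    for k in range(first_replicate, first_replicate + n_replicates):
        ss = _replicate_seed(seed, k)
        child = np.random.default_rng(ss)
        for attempt in range(max_retries + 1):
            shuffle_seed = int(child.integers(2**31 - 1))
            fit_seed = int(child.integers(2**31 - 1))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    shuffled = shuffle_pedigree(
                        pedigree, seed=shuffle_seed,
                        preserve_pairs=preserve_pairs,
                    )
                    model = AnimalModel(
                        traits, shuffled, dam_sire_effects=dam_sire_effects
                    )
                    res = model.fit(chain=chain, seed=fit_seed)
                matrices.append(res.posterior_mode(estimator=estimator))
                seeds.append((shuffle_seed, fit_seed))
                break
            except (np.linalg.LinAlgError, ValueError):
                n_failed += 1
                if attempt == max_retries:
                    raise
    return PermutationNull(
        matrices=matrices, trait_names=traits.trait_names, seeds=seeds,
        preserve_pairs=preserve_pairs, n_failed=n_failed,
    )


def element_pvalues(observed: np.ndarray, null: PermutationNull | np.ndarray
                    ) -> pd.DataFrame:
    """Empirical per-element P-values of an observed G against the null.

    Applies the rank rule literally: P = N_below / N, flipped to 1 - P when
    the observed element is below the null mean; values are floored at 1/N.
    Returns one row per unique element (i >= j).
    """
    stack = null.stack() if isinstance(null, PermutationNull) else \
        np.asarray(null, dtype=float)
    n = stack.shape[0]
    observed = np.asarray(observed, dtype=float)
    t = observed.shape[0]
    rows = []
    for i in range(t):
        for j in range(i + 1):
            obs = observed[i, j]
            nulls = stack[:, i, j]
            p = np.count_nonzero(nulls < obs) / n
            if obs >= nulls.mean():
                p = 1.0 - p
            p = min(max(p, 1.0 / n), 1.0)
            rows.append((i, j, obs, p, "variance" if i == j else
                         "covariance"))
    return pd.DataFrame(
        rows, columns=["element_i", "element_j", "observed", "P", "class"]
    )


def fdr_adjust(pvalues, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({"P": p, "q": q, "flag": q < alpha})


def significance_summary(
    observed: np.ndarray,
    null: PermutationNull,
    alpha: float = 0.05,
    family: str = "joint",
) -> pd.DataFrame:
    """Element table ``element_i, element_j, observed, P, q, flag``.

    ``family="joint"`` adjusts all unique elements together;
    ``"separate"`` adjusts variances and covariances as two families.
    """
    table = element_pvalues(observed, null)
    if family == "joint":
        adj = fdr_adjust(table["P"], alpha)
        table["q"] = adj["q"].to_numpy()
    elif family == "separate":
        table["q"] = np.nan
        for cls in ("variance", "covariance"):
            mask = table["class"] == cls
            table.loc[mask, "q"] = fdr_adjust(
                table.loc[mask, "P"], alpha
            )["q"].to_numpy()
    else:
        raise ValueError(f"unknown family {family!r}")
    table["flag"] = table["q"] < alpha
    return table
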