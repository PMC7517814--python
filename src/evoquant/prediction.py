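"""Multi-trait selection-response prediction and decomposition.

The multivariate breeder's equation (Lande's equation) predicts the
per-generation change in a vector of trait means as

    dz = G beta,

with G the genetic variance-covariance matrix and beta the directional
selection gradients.  Each trait's response splits exactly into a direct
component G_ii * beta_i (selection on the trait itself) and an indirect
component sum_{j != i} G_ij * beta_j (selection on genetically correlated
traits); direct + indirect = total.

Propagating the posterior draws of G through the equation yields posterior
distributions of the total, direct and indirect responses, summarized by
their means and 95% highest-posterior-density (shortest) intervals.
Observed changes are last-generation minus parental-generation trait means,
scaled by the parental-generation phenotypic SD, so predictions and
observations share parental-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import hpd
from .traits import TraitMatrix

__all__ = [
    "predict_response",
    "decompose_response",
    "posterior_response",
    "observed_change",
    "classify_trait",
    "ResponsePrediction",
]


def _check_dims(g: np.ndarray, beta: np.ndarray):
    g = np.asarray(g, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    if g.shape[-1] != beta.shape[0] or g.shape[-2] != beta.shape[0]:
        raise ValueError(
            f"dimension mismatch: G is {g.shape}, beta has {beta.shape[0]}"
        )
    return g, beta


def predict_response(g, beta) -> np.ndarray:
    """Total predicted response dz = G beta."""
    g, beta = _check_dims(g, beta)
    return g @ beta


def decompose_response(g, beta) -> tuple[np.ndarray, np.ndarray]:
    """(direct, indirect) components; they sum to ``predict_response``.

    direct_i = G_ii beta_i; indirect_i = sum_{j != i} G_ij beta_j.
    """
    g, beta = _check_dims(g, beta)
    diag = np.diagonal(g, axis1=-2, axis2=-1)
    direct = diag * beta
    indirect = g @ beta - direct
    return direct, indirect


def observed_change(
    traits: TraitMatrix,
    first,
    last,
    *,
    scale: str = "parental_sd",
    ddof: int = 1,
) -> pd.Series:
    """Observed change dz_obs = mean(last generation) - mean(first
    generation), scaled by the first (parental) generation's phenotypic SD.

    ``scale="raw"`` skips the SD scaling.
    """
    means = traits.generation_means()
    for gen in (first, last):
        if gen not in means.index:
            raise ValueError(f"generation {gen!r} not present")
    diff = means.loc[last] - means.loc[first]
    if scale == "raw":
        return diff
    if scale != "parental_sd":
        raise ValueError(f"unknown scale {scale!r}")
    sd = traits.generation_sds(ddof=ddof).loc[first]
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"zero parental-generation SD for {bad}")
    return diff / sd


@dataclass
class ResponsePrediction:
    """Posterior summaries of total/direct/indirect responses per trait.

    ``table`` is tidy: one row per (trait, component) with mean, 95% HPD
    bounds and a significance flag (HPD excludes zero); ``observed`` holds
    dz_obs when provided.  All values are in parental-SD units when the
    inputs were standardized and scaled accordingly.
    """

    trait_names: list
    table: pd.DataFrame = field(repr=False)
    draws: dict = field(repr=False)
    observed: pd.Series | None = None

    def component(self, name: str) -> pd.DataFrame:
        return self.table[self.table["component"] == name].set_index("trait")

    def classify(self) -> pd.Series:
        return pd.Series(
            {trait: classify_trait(self, trait) for trait in self.trait_names}
        )

    def to_csv(self, path) -> None:
        out = self.table.copy()
        if self.observed is not None:
            out["observed"] = out["trait"].map(self.observed).values
        out["tag"] = out["trait"].map(
            lambda tr: "+".join(sorted(classify_trait(self, tr)))
        )
        out.to_csv(path, index=False)


def posterior_response(
    g_draws: np.ndarray,
    beta,
    *,
    trait_names=None,
    observed: pd.Series | None = None,
    prob: float = 0.95,
    min_draws: int = 100,
) -> ResponsePrediction:
    """Posterior distribution of predicted responses from G draws.

    Parameters
    ----------
    g_draws : (m, t, t) array
        Posterior draws of G (e.g. ``AnimalModelResults.g_draws``).
    beta : length-t vector or pandas.Series
        Directional selection gradients.
    observed : optional
        Observed SD-scaled changes for the same traits.
    """
    g_draws = np.asarray(g_draws, dtype=float)
    if g_draws.ndim != 3:
        raise ValueError("g_draws must be (m, t, t)")
    if g_draws.shape[0] < min_draws:
        raise ValueError(
            f"need >= {min_draws} draws for stable HPD intervals, got "
            f"{g_draws.shape[0]}"
        )
    if isinstance(beta, pd.Series):
        names = list(beta.index)
        beta_vec = beta.to_numpy(dtype=float)
    else:
        beta_vec = np.asarray(beta, dtype=float).ravel()
        names = list(trait_names) if trait_names is not None else \
            [f"trait{k}" for k in range(beta_vec.size)]
    direct, indirect = decompose_response(g_draws, beta_vec)
    total = direct + indirect

    draws = {"total": total, "direct": direct, "indirect": indirect}
    rows = []
    for comp, mat in draws.items():
        for k, name in enumerate(names):
            lo, hi = hpd(mat[:, k], prob)
            mean = float(mat[:, k].mean())
            rows.append(
                (name, comp, mean, lo, hi, bool(lo > 0 or hi < 0))
            )
    table = pd.DataFrame(
        rows,
        columns=["trait", "component", "mean", "hpd_lo", "hpd_hi",
                 "significant"],
    )
    obs = None
    if observed is not None:
        obs = pd.Series(observed).reindex(names)
    return ResponsePrediction(
        trait_names=names, table=table, draws=draws, observed=obs
    )


def classify_trait(
    pred: ResponsePrediction, trait, atol: float = 1e-12
) -> frozenset:
    """Qualitative classification of a trait's response structure.

    Rule table (signs taken from posterior means; "~0" means the HPD of the
    total response includes zero and the observed value, if any, is absent):

    * ``enhanced``     -- direct and indirect components share a sign
      (covariance augments the direct response);
    * ``constrained``  -- direct and indirect components oppose, or the
      total is opposed to / smaller in magnitude than the direct component
      (covariance constrains the response);
    * ``direct-target candidate`` -- an observed change is available,
      falls inside the total's HPD, and shares the direct component's sign;
    * ``indeterminate`` -- all components effectively zero.

    Returns the (frozen) set of applicable tags.
    """
    row = {
        comp: pred.component(comp).loc[trait]
        for comp in ("total", "direct", "indirect")
    }
    total_m = row["total"]["mean"]
    direct_m = row["direct"]["mean"]
    indirect_m = row["indirect"]["mean"]

    if all(abs(v) <= atol for v in (total_m, direct_m, indirect_m)):
        return frozenset({"indeterminate"})

    tags = set()
    if direct_m * indirect_m > 0:
        tags.add("enhanced")
    if (direct_m * indirect_m < 0) or (total_m * direct_m < 0) or (
        abs(total_m) < abs(direct_m)
    ):
        tags.add("constrained")

    if pred.observed is not None and trait in pred.observed.index:
        obs = pred.observed[trait]
        if np.isfinite(obs):
            inside = row["total"]["hpd_lo"] <= obs <= row["total"]["hpd_hi"]
            if inside and obs * direct_m > 0:
                tags.add("direct-target candidate")
            elif obs * direct_m < 0:
                # observed and direct responses opposed: indirectly driven
                tags.add("constrained")

    return frozenset(tags) if tags else frozenset({"indeterminate"})
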