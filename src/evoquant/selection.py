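"""Selection differentials and gradients.

Two estimators are provided, matching the two experimental designs:

* truncation (artificial) selection on a single trait: the selection
  differential S = mean(selected) - mean(all measured in the generation)
  and the univariate gradient beta_h = S / V_P, summed over generations to
  give the cumulative gradient;
* fitness-based (pollinator-style) selection: directional gradients as the
  partial regression coefficients of relative fitness w on the standardized
  traits (the Lande-Arnold estimator), with replicate as an additive fixed
  factor and all generations/replicates pooled.  Non-significant gradients
  are retained as the best available estimates.  Quadratic/correlational
  gradients are available from the extended regression but are not used by
  the response predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .traits import TraitMatrix

__all__ = [
    "relative_fitness",
    "selection_differential",
    "gradient_from_differential",
    "cumulative_gradient",
    "FitnessTable",
    "LandeArnoldModel",
    "SelectionGradientResults",
    "read_fitness",
]


def selection_differential(values, selected) -> float:
    """S = mean(trait among selected) - mean(trait among all measured).

    ``selected`` is a boolean mask or an index array into ``values``.
    """
    values = np.asarray(values, dtype=float)
    sel = np.asarray(selected)
    chosen = values[sel] if sel.dtype != bool else values[sel]
    if chosen.size == 0:
        raise ValueError("empty selection")
    return float(chosen.mean() - values.mean())


def gradient_from_differential(s: float, v_p: float) -> float:
    """Univariate directional gradient beta_h = S / V_P."""
    if v_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    return float(s) / float(v_p)


def cumulative_gradient(per_generation) -> float:
    """Cumulative gradient over generations (sum of per-generation values)."""
    return float(np.sum(np.asarray(per_generation, dtype=float)))


@dataclass(frozen=True)
class FitnessTable:
    """Absolute fitness (seed set) with replicate structure.

    Relative fitness ``w`` is seed count divided by the mean seed count of
    the plant's replicate, so w averages 1 within every replicate.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"id", "seeds", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"fitness table lacks columns {sorted(missing)}")
        f = self.frame.copy()
        f["id"] = f["id"].astype(str)
        if (f["seeds"] < 0).any():
            raise ValueError("negative seed counts")
        # each generation is its own selection episode: normalize within
        # replicate x generation cohort when a generation column exists
        group = f["replicate"].astype(str)
        if "generation" in f.columns:
            group = group + "/" + f["generation"].astype(str)
        f["w"] = relative_fitness(f["seeds"], group).to_numpy()
        object.__setattr__(self, "frame", f)

    @property
    def w(self) -> pd.Series:
        return self.frame.set_index("id")["w"]


def relative_fitness(seeds, replicate) -> pd.Series:
    """w = seeds / mean(seeds within replicate)."""
    seeds = pd.Series(np.asarray(seeds, dtype=float))
    replicate = pd.Series(np.asarray(replicate), index=seeds.index)
    means = seeds.groupby(replicate).transform("mean")
    if (means == 0).any():
        raise ValueError("a replicate has zero total seed set")
    return seeds / means


def read_fitness(path) -> FitnessTable:
    """Read ``id,seeds,replicate[,treatment][,generation]`` CSV."""
    return FitnessTable(pd.read_csv(path, dtype={"id": str}))


class LandeArnoldModel:
    """Directional (and optionally quadratic) selection-gradient regression.

    Parameters
    ----------
    traits : TraitMatrix
        Standardized trait values; rows are matched to the fitness table by
        individual id (plants without fitness records are dropped).
    fitness : FitnessTable
    """

    def __init__(self, traits: TraitMatrix, fitness: FitnessTable):
        self.traits = traits
        self.fitness = fitness
        f = fitness.frame.set_index("id")
        common = [i for i in traits.ids if i in f.index]
        if len(common) < traits.t + 2:
            raise ValueError("too few individuals with both traits and "
                             "fitness")
        self._z = traits.data.loc[common]
        self._w = f.loc[common, "w"]
        self._replicate = f.loc[common, "replicate"]

    def _design(self, quadratic: bool):
        z = self._z
        names = list(z.columns)
        blocks = [z.to_numpy(dtype=float)]
        labels = list(names)
        if quadratic:
            zz = z.to_numpy(dtype=float)
            for i in range(len(names)):
                blocks.append((zz[:, i] ** 2)[:, None])
                labels.append(f"{names[i]}^2")
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    blocks.append((zz[:, i] * zz[:, j])[:, None])
                    labels.append(f"{names[i]}*{names[j]}")
        x = np.hstack(blocks)
        reps = pd.get_dummies(self._replicate.astype(str), drop_first=True)
        if reps.shape[1] > 0:
            x = np.hstack([x, reps.to_numpy(dtype=float)])
            labels += [f"replicate[{c}]" for c in reps.columns]
        x = sm.add_constant(x, prepend=True)
        labels = ["const"] + labels
        return x, labels

    def fit(self, quadratic: bool = False,
            cond_threshold: float = 1e8) -> "SelectionGradientResults":
        """OLS of relative fitness on the (standardized) traits.

        Collinear trait columns are reported via the design condition
        number, not silently dropped.
        """
        x, labels = self._design(quadratic)
        cond = np.linalg.cond(x)
        if cond > cond_threshold:
            raise ValueError(
                f"design matrix ill-conditioned (cond = {cond:.3g}); "
                "check for collinear trait columns"
            )
        ols = sm.OLS(self._w.to_numpy(dtype=float), x).fit()
        params = pd.Series(ols.params, index=labels)
        bse = pd.Series(ols.bse, index=labels)
        pvalues = pd.Series(ols.pvalues, index=labels)
        names = self.traits.trait_names
        beta = params[names]

        gamma = None
        if quadratic:
            t = len(names)
            gamma = np.zeros((t, t))
            for i in range(t):
                # doubled diagonal: w ~ .5 gamma_ii z^2 convention
                gamma[i, i] = 2.0 * params[f"{names[i]}^2"]
            for i in range(t):
                for j in range(i + 1, t):
                    gamma[i, j] = gamma[j, i] = params[f"{names[i]}*{names[j]}"]
            gamma = pd.DataFrame(gamma, index=names, columns=names)

        return SelectionGradientResults(
            beta=beta, bse=bse[names], pvalues=pvalues[names],
            method="lande-arnold-regression", gamma_quad=gamma,
            condition_number=cond, n_obs=int(ols.nobs), ols=ols,
        )


@dataclass
class SelectionGradientResults:
    """Directional gradient vector with provenance.

    ``beta`` is in units of relative fitness per phenotypic SD when the
    traits were standardized.  ``per_generation`` carries the summed
    components for the univariate-differential method (cumulative beta =
    their sum).
    """

    beta: pd.Series
    method: str
    bse: pd.Series | None = None
    pvalues: pd.Series | None = None
    gamma_quad: pd.DataFrame | None = None
    per_generation: pd.DataFrame | None = None
    condition_number: float | None = None
    n_obs: int | None = None
    ols: object | None = field(default=None, repr=False)

    @property
    def trait_names(self) -> list:
        return list(self.beta.index)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"beta": self.beta})
        if self.bse is not None:
            out["se"] = self.bse
            out["p"] = self.pvalues
        return out

    @classmethod
    def from_differentials(
        cls, per_generation: pd.DataFrame, trait_names, target_trait
    ) -> "SelectionGradientResults":
        """Cumulative gradient vector from per-generation beta_h values on a
        single selected trait (other traits get beta = 0).

        ``per_generation`` needs columns ``generation, S, V_P, beta``.
        """
        beta = pd.Series(0.0, index=list(trait_names))
        beta[target_trait] = per_generation["beta"].sum()
        return cls(beta=beta, method="univariate-differential",
                   per_generation=per_generation)
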