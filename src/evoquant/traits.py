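"""Trait matrices and the study's standard transformations.

Floral volatile amounts are strongly right-skewed, so the pipeline applies
ln(x + 1) before analysis; all traits are then z-scored (mean 0, SD 1) to
put morphological and chemical traits on a common scale.  Z-scoring is done
within generation by default, which removes scale differences between
generations; a global option is provided.  The transformation record keeps
the per-generation means and SDs of the raw-scale traits so that predicted
changes can be mapped back to raw units and observed changes can be scaled
by the parental-generation SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["TraitMatrix", "transform_traits", "read_traits"]


@dataclass(frozen=True)
class TraitMatrix:
    """Phenotypes of ``n`` individuals for ``t`` traits.

    Parameters
    ----------
    data : pandas.DataFrame
        Indexed by individual id, one column per trait; NaN marks missing.
    generation : pandas.Series
        Generation label per individual (aligned to ``data.index``).
    transforms : tuple of dict
        Append-only log of applied transformations, so the raw scale is
        recoverable.
    scale : pandas.DataFrame or None
        Per-(generation, trait) mean and SD of the values the latest
        z-score step consumed (raw or ln-transformed scale).
    """

    data: pd.DataFrame = field(repr=False)
    generation: pd.Series = field(repr=False)
    transforms: tuple = ()
    scale: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.data.index.equals(self.generation.index):
            gen = self.generation.reindex(self.data.index)
            if gen.isna().any():
                raise ValueError("generation labels missing for some ids")
            object.__setattr__(self, "generation", gen)

    @property
    def trait_names(self) -> list:
        return list(self.data.columns)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def t(self) -> int:
        return self.data.shape[1]

    @property
    def ids(self) -> list:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def generation_means(self) -> pd.DataFrame:
        return self.data.groupby(self.generation).mean()

    def generation_sds(self, ddof: int = 1) -> pd.DataFrame:
        return self.data.groupby(self.generation).std(ddof=ddof)

    def restrict(self, ids) -> "TraitMatrix":
        return replace(
            self, data=self.data.loc[ids], generation=self.generation.loc[ids]
        )

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "generation", self.generation)
        out.to_csv(path, index_label="id")


def read_traits(path, generation_col: str = "generation") -> TraitMatrix:
    """Read an ``id,<trait1>,...`` CSV (optionally with a generation column)."""
    frame = pd.read_csv(path, index_col="id")
    frame.index = frame.index.astype(str)
    if generation_col in frame.columns:
        gen = frame.pop(generation_col)
    else:
        gen = pd.Series(0, index=frame.index)
    return TraitMatrix(frame.astype(float), gen)


def _zscore_block(block: pd.DataFrame, on_constant: str, ddof: int):
    mean = block.mean()
    sd = block.std(ddof=ddof)
    zero = sd <= 0
    if zero.any():
        cols = list(sd.index[zero])
        if on_constant == "error":
            raise ValueError(f"zero SD under z-score for traits {cols}")
        warnings.warn(
            f"constant trait column(s) {cols}: z-score set to 0", stacklevel=3
        )
        sd = sd.mask(zero, 1.0)
    return (block - mean) / sd, mean, sd


def transform_traits(
    traits: TraitMatrix,
    plan: dict | str = "log1p+zscore",
    *,
    zscore_scope: str = "generation",
    on_constant: str = "warn",
    ddof: int = 1,
) -> TraitMatrix:
    """Apply per-trait transformations, recording scale for back-mapping.

    Parameters
    ----------
    plan : dict or str
        Mapping ``trait -> rule`` with rules in ``{"none", "log1p",
        "zscore", "log1p+zscore"}``, or a single rule applied to all traits.
    zscore_scope : {"generation", "global"}
        Whether z-scoring uses within-generation or whole-data moments.
    on_constant : {"warn", "error"}
        Handling of a zero-SD column under z-scoring (degenerate case).

    Raises
    ------
    ValueError
        On a negative value under the ln(x+1) rule, or a constant column
        when ``on_constant="error"``.
    """
    if isinstance(plan, str):
        plan = {name: plan for name in traits.trait_names}
    unknown = set(plan) - set(traits.trait_names)
    if unknown:
        raise ValueError(f"plan names unknown traits: {sorted(unknown)}")

    data = traits.data.copy()
    log_cols = [c for c, r in plan.items() if "log1p" in r]
    z_cols = [c for c, r in plan.items() if "zscore" in r]

    if log_cols:
        block = data[log_cols]
        if (block < 0).any().any():
            bad = [c for c in log_cols if (block[c] < 0).any()]
            raise ValueError(f"negative values under ln(x+1) for {bad}")
        data[log_cols] = np.log1p(block)

    scale = None
    if z_cols:
        records = []
        if zscore_scope == "generation":
            parts = []
            for gen, idx in data.groupby(traits.generation).groups.items():
                z, mean, sd = _zscore_block(
                    data.loc[idx, z_cols], on_constant, ddof
                )
                parts.append(z)
                records.append(
                    pd.DataFrame({"generation": gen, "trait": z_cols,
                                  "mean": mean.values, "sd": sd.values})
                )
            data[z_cols] = pd.concat(parts).loc[data.index]
        elif zscore_scope == "global":
            z, mean, sd = _zscore_block(data[z_cols], on_constant, ddof)
            data[z_cols] = z
            records.append(
                pd.DataFrame({"generation": "all", "trait": z_cols,
                              "mean": mean.values, "sd": sd.values})
            )
        else:
            raise ValueError(f"unknown zscore_scope {zscore_scope!r}")
        scale = pd.concat(records, ignore_index=True)

    log_entry = {
        "plan": dict(plan),
        "zscore_scope": zscore_scope,
        "ddof": ddof,
    }
    return TraitMatrix(
        data,
        traits.generation,
        transforms=traits.transforms + (log_entry,),
        scale=scale if scale is not None else traits.scale,
    )
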