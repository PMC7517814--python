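"""Synthetic breeding-experiment simulator with known ground truth.

Simulates pedigreed multivariate trait data under the infinitesimal model
so every pipeline stage can be validated against a known G-matrix:

* phenotype = generation intercept + breeding value + dam effect + sire
  effect + residual, with breeding values MVN(0, G_true) in founders and
  transmitted as the parental midpoint plus a Mendelian-sampling deviation
  MVN(0, 0.5 * (1 - (F_sire + F_dam) / 2) * G_true);
* an artificial-selection design: a parental cohort from which a "tall"
  line (top plants on trait 1), a "short" line (bottom plants) and a
  random "control" line are bred for several generations, with realized
  selection differentials logged;
* a pollinator-style design: replicates of a fixed cohort size where
  fitness is a linear-with-floor function of the traits
  (w = max(0, 1 + beta_true' z + noise)), pollinator visitation subsamples
  the plants, seed set is proportional to fitness, and offspring are sown
  proportionally to seed set (counts below 0.5 rounded up to 1), with a
  final random inter-replicate crossing generation;
* a random-mating design (no selection) for calibration checks.

All randomness flows from one master seed through named substreams, so
founders, selection, mating and noise are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .selection import FitnessTable
from .traits import TraitMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "default_g",
    "default_config",
    "simulate_founders",
    "breed",
    "run_artificial_design",
    "run_pollinator_design",
    "run_random_mating",
    "proportional_offspring_counts",
]


def default_g(t: int = 4, v_a: float = 0.35, rho: float = 0.4) -> np.ndarray:
    """A realistic default G: additive variance ``v_a`` per trait, positive
    genetic correlation ``rho`` of every trait with trait 1 (the
    height-like trait) and ``rho/2`` among the rest."""
    g = np.full((t, t), rho / 2 * v_a)
    g[0, :] = g[:, 0] = rho * v_a
    np.fill_diagonal(g, v_a)
    return g


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and design parameters for a simulated study.

    Covariances are on the raw trait scale (trait units squared).  The
    defaults reproduce the study designs: 150-plant parental cohort with
    10 selected per line over 3 generations (~50 offspring per line per
    generation) for the artificial design; 3 replicates of 36 plants over
    9 selection rounds plus an inter-replicate crossing generation for the
    pollinator design.
    """

    t: int = 4
    g_true: np.ndarray = None
    d_true: np.ndarray = None
    s_true: np.ndarray = None
    r_true: np.ndarray = None
    intercept: np.ndarray = None
    design: str = "artificial-selection"
    # artificial-selection parameters
    n_founders: int = 150
    n_select: int = 10
    lines: tuple = ("tall", "short", "control")
    n_generations: int = 3
    offspring_per_line: int = 50
    selfing_rate: float = 0.0
    # pollinator parameters
    beta_true: np.ndarray = None
    fitness_noise_sd: float = 0.3
    replicates: int = 3
    plants_per_replicate: int = 36
    baseline_seeds: float = 30.0
    n_pollinators: int = 5
    max_visits: int = 3
    final_cross: bool = True
    seed: int | None = None

    def __post_init__(self):
        t = self.t
        def setdef(name, value):
            object.__setattr__(self, name, np.asarray(value, dtype=float))
        setdef("g_true", self.g_true if self.g_true is not None
               else default_g(t))
        setdef("d_true", self.d_true if self.d_true is not None
               else 0.05 * np.eye(t))
        setdef("s_true", self.s_true if self.s_true is not None
               else 0.05 * np.eye(t))
        setdef("r_true", self.r_true if self.r_true is not None
               else 0.55 * np.eye(t))
        setdef("intercept", self.intercept if self.intercept is not None
               else np.zeros(t))
        setdef("beta_true", self.beta_true if self.beta_true is not None
               else np.r_[0.3, np.zeros(t - 1)])
        for name in ("g_true", "d_true", "s_true", "r_true"):
            m = getattr(self, name)
            if m.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{name} must be PSD")

    def stream(self, name: str) -> np.random.Generator:
        """Named, reproducible random substream of the master seed."""
        names = ("founders", "selection", "mating", "noise", "fitness")
        key = names.index(name)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed or 0, spawn_key=(key,))
        )


def default_config(design: str = "artificial-selection", t: int = 4,
                   seed: int | None = None, **kwargs) -> SimulationConfig:
    return SimulationConfig(t=t, design=design, seed=seed, **kwargs)


class _KinshipTracker:
    """Incremental coefficient-of-kinship bookkeeping for F computation."""

    def __init__(self):
        self.parents: dict = {}
        self.order: dict = {}
        self._memo: dict = {}

    def add(self, ind, sire=None, dam=None):
        self.parents[ind] = (sire, dam)
        self.order[ind] = len(self.order)

    def kinship(self, i, j) -> float:
        key = (i, j) if self.order[i] <= self.order[j] else (j, i)
        if key in self._memo:
            return self._memo[key]
        a, b = key
        if a == b:
            sire, dam = self.parents[a]
            f = self.kinship(sire, dam) if sire is not None and \
                dam is not None else 0.0
            val = 0.5 * (1.0 + f)
        else:
            sire, dam = self.parents[b]  # b is the later individual
            val = 0.0
            if sire is not None:
                val += 0.5 * self.kinship(a, sire)
            if dam is not None:
                val += 0.5 * self.kinship(a, dam)
        self._memo[key] = val
        return val

    def inbreeding(self, ind) -> float:
        sire, dam = self.parents[ind]
        if sire is None or dam is None:
            return 0.0
        return self.kinship(sire, dam)


@dataclass
class SimulatedStudy:
    """Simulator output: pedigree, raw-scale traits, optional fitness, and
    a truth log (breeding values, true generation means, realized
    differentials) consistent with the emitted phenotypes."""

    pedigree: Pedigree
    traits: TraitMatrix = field(repr=False)
    fitness: FitnessTable | None = None
    truth: dict = field(default_factory=dict, repr=False)
    config: SimulationConfig | None = None

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.pedigree.to_csv(directory / "pedigree.csv")
        self.traits.to_csv(directory / "phenotypes.csv")
        if self.fitness is not None:
            self.fitness.frame.to_csv(directory / "fitness.csv", index=False)
        self.truth["breeding_values"].to_csv(
            directory / "truth_breeding_values.csv", index_label="id"
        )
        if "realized_selection" in self.truth:
            self.truth["realized_selection"].to_csv(
                directory / "truth_realized_selection.csv", index=False
            )


class _Population:
    """Mutable simulation state shared by the design drivers."""

    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.kin = _KinshipTracker()
        self.records = []          # pedigree rows
        self.bv: dict = {}         # id -> breeding value vector
        self.pheno: dict = {}      # id -> phenotype vector
        self.gen_label: dict = {}
        self._dam_eff: dict = {}
        self._sire_eff: dict = {}
        c = config
        self._chol_g = _safe_chol(c.g_true)
        self._chol_d = _safe_chol(c.d_true)
        self._chol_s = _safe_chol(c.s_true)
        self._chol_r = _safe_chol(c.r_true)
        self.rng_founders = config.stream("founders")
        self.rng_mating = config.stream("mating")
        self.rng_noise = config.stream("noise")

    def _parent_effect(self, pool: dict, chol, parent) -> np.ndarray:
        if parent not in pool:
            pool[parent] = chol @ self.rng_noise.standard_normal(self.cfg.t)
        return pool[parent]

    def add_founder(self, ind, generation: int, line) -> None:
        c = self.cfg
        a = self._chol_g @ self.rng_founders.standard_normal(c.t)
        e = self._chol_r @ self.rng_noise.standard_normal(c.t)
        self.kin.add(ind)
        self.bv[ind] = a
        self.pheno[ind] = c.intercept + a + e
        self.gen_label[ind] = generation
        self.records.append((ind, None, None, generation, line))

    def add_offspring(self, ind, sire, dam, generation: int, line) -> None:
        c = self.cfg
        f_s = self.kin.inbreeding(sire)
        f_d = self.kin.inbreeding(dam)
        scale = np.sqrt(max(0.5 * (1.0 - 0.5 * (f_s + f_d)), 0.0))
        mendelian = scale * (
            self._chol_g @ self.rng_mating.standard_normal(c.t)
        )
        a = 0.5 * (self.bv[sire] + self.bv[dam]) + mendelian
        d_eff = self._parent_effect(self._dam_eff, self._chol_d, dam)
        s_eff = self._parent_effect(self._sire_eff, self._chol_s, sire)
        e = self._chol_r @ self.rng_noise.standard_normal(c.t)
        self.kin.add(ind, sire, dam)
        self.bv[ind] = a
        self.pheno[ind] = c.intercept + a + d_eff + s_eff + e
        self.gen_label[ind] = generation
        self.records.append((ind, sire, dam, generation, line))

    def phenotypes(self, ids) -> np.ndarray:
        return np.array([self.pheno[i] for i in ids])

    def study(self, fitness_rows=None, truth_extra=None) -> SimulatedStudy:
        c = self.cfg
        ped = Pedigree.from_records(self.records)
        names = [f"trait{k + 1}" for k in range(c.t)]
        ids = [r[0] for r in self.records]
        data = pd.DataFrame(self.phenotypes(ids), index=ids, columns=names)
        gen = pd.Series([self.gen_label[i] for i in ids], index=ids)
        traits = TraitMatrix(data, gen)
        fitness = None
        if fitness_rows:
            fitness = FitnessTable(pd.DataFrame(
                fitness_rows,
                columns=["id", "seeds", "replicate", "treatment",
                         "generation"],
            ))
        bvs = pd.DataFrame(
            np.array([self.bv[i] for i in ids]), index=ids, columns=names
        )
        truth = {"breeding_values": bvs, "config": c}
        line_of = {r[0]: r[4] for r in self.records}
        bv_frame = bvs.copy()
        bv_frame["generation"] = gen
        bv_frame["line"] = [line_of[i] for i in ids]
        truth["true_generation_means"] = bv_frame.groupby(
            ["line", "generation"]
        )[names].mean()
        if truth_extra:
            truth.update(truth_extra)
        return SimulatedStudy(pedigree=ped, traits=traits, fitness=fitness,
                              truth=truth, config=c)


def _safe_chol(m: np.ndarray) -> np.ndarray:
    vals = np.linalg.eigvalsh(m)
    if vals.min() <= 0:
        # PSD-but-singular ground truth (e.g. G = 0): use a square root
        v, q = np.linalg.eigh(m)
        return q @ np.diag(np.sqrt(np.clip(v, 0, None)))
    return np.linalg.cholesky(m)


def simulate_founders(config: SimulationConfig, n: int | None = None):
    """Founder cohort only: returns (ids, breeding values, phenotypes)."""
    pop = _Population(config)
    n = n or config.n_founders
    ids = [f"P{k + 1}" for k in range(n)]
    for ind in ids:
        pop.add_founder(ind, 0, "parental")
    return ids, np.array([pop.bv[i] for i in ids]), pop.phenotypes(ids)


def breed(config: SimulationConfig, pairs, parent_bv: dict,
          inbreeding: dict | None = None, rng=None):
    """Offspring breeding values for (sire, dam) pairs under the
    infinitesimal model (exposed for direct testing of transmission)."""
    rng = rng or np.random.default_rng(0)
    chol = _safe_chol(config.g_true)
    inbreeding = inbreeding or {}
    out = []
    for sire, dam in pairs:
        f_s = inbreeding.get(sire, 0.0)
        f_d = inbreeding.get(dam, 0.0)
        scale = np.sqrt(max(0.5 * (1.0 - 0.5 * (f_s + f_d)), 0.0))
        m = scale * (chol @ rng.standard_normal(config.t))
        out.append(0.5 * (parent_bv[sire] + parent_bv[dam]) + m)
    return np.array(out)


# ---------------------------------------------------------------------------
# artificial selection design


def _select(line: str, ids, phenos, k: int, rng) -> list:
    height = phenos[:, 0]
    if line == "tall":
        idx = np.argsort(-height, kind="stable")[:k]
    elif line == "short":
        idx = np.argsort(height, kind="stable")[:k]
    else:  # control / random line
        idx = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in idx]


def run_artificial_design(config: SimulationConfig) -> SimulatedStudy:
    """Bidirectional artificial selection on trait 1 plus a control line.

    All lines share the parental cohort.  Each generation the selected
    plants of a line are randomly hand-pollinated among themselves (random
    dam/sire pairs, no selfing unless ``selfing_rate > 0``); realized
    selection differentials (selected mean - cohort mean, all traits) are
    logged per line and generation.
    """
    c = config
    pop = _Population(c)
    rng_sel = c.stream("selection")
    founders = [f"P{k + 1}" for k in range(c.n_founders)]
    for ind in founders:
        pop.add_founder(ind, 0, "parental")

    rows = []
    for line in c.lines:
        current = list(founders)
        for gen in range(1, c.n_generations + 1):
            phenos = pop.phenotypes(current)
            selected = _select(line, current, phenos, c.n_select, rng_sel)
            sel_phen = pop.phenotypes(selected)
            for k in range(c.t):
                rows.append((line, gen - 1, f"trait{k + 1}",
                             float(sel_phen[:, k].mean()
                                   - phenos[:, k].mean()),
                             float(phenos[:, k].var(ddof=1))))
            for j in range(c.offspring_per_line):
                if c.selfing_rate > 0 and \
                        pop.rng_mating.random() < c.selfing_rate:
                    sire = dam = selected[
                        pop.rng_mating.integers(len(selected))
                    ]
                else:
                    pick = pop.rng_mating.choice(
                        len(selected), size=2, replace=False
                    )
                    sire, dam = selected[pick[0]], selected[pick[1]]
                child = f"{line[0].upper()}{gen}_{j + 1}"
                pop.add_offspring(child, sire, dam, gen, line)
            current = [r[0] for r in pop.records
                       if r[3] == gen and r[4] == line]
    realized = pd.DataFrame(
        rows, columns=["line", "generation", "trait", "S", "V_P"]
    )
    return pop.study(truth_extra={"realized_selection": realized})


def run_random_mating(config: SimulationConfig) -> SimulatedStudy:
    """No-selection control: random parents each generation (drift only)."""
    cfg = replace(config, lines=("control",), design="random-mating")
    return run_artificial_design(cfg)


# ---------------------------------------------------------------------------
# pollinator design


def proportional_offspring_counts(seeds, target: int,
                                  exact_total: bool = True) -> np.ndarray:
    """Offspring sown per parent: target * seeds_j / sum(seeds), with
    fractional counts below 0.5 (but nonzero) rounded up to 1, others
    rounded to nearest.  ``exact_total`` trims/pads deterministically
    (largest counts first) so the cohort size is exactly ``target``."""
    seeds = np.asarray(seeds, dtype=float)
    total = seeds.sum()
    if total <= 0:
        raise ValueError("no seeds in replicate")
    raw = target * seeds / total
    counts = np.where((raw > 0) & (raw < 0.5), 1,
                      np.round(raw).astype(int)).astype(int)
    if exact_total:
        order = np.argsort(-counts, kind="stable")
        k = 0
        while counts.sum() > target:
            j = order[k % len(order)]
            if counts[j] > 1 or (counts[j] > 0 and raw[j] >= 0.5):
                counts[j] -= 1
            k += 1
        k = 0
        while counts.sum() < target:
            j = order[k % len(order)]
            if counts[j] > 0:
                counts[j] += 1
            k += 1
    return counts


def _visitation(n_plants: int, config: SimulationConfig, rng) -> np.ndarray:
    """Visited-plant subsampling: each pollinator visits up to
    ``max_visits`` distinct plants (truncated-Poisson number of plants)."""
    visited = np.zeros(n_plants, dtype=bool)
    for _ in range(config.n_pollinators):
        k = min(1 + rng.poisson(2.0), config.max_visits)
        visited[rng.choice(n_plants, size=k, replace=False)] = True
    return visited


def run_pollinator_design(config: SimulationConfig) -> SimulatedStudy:
    """Pollinator-style fitness selection over replicates.

    Per replicate and generation: traits are standardized within the
    replicate, fitness is w = max(0, 1 + beta_true' z + eps), only
    pollinator-visited plants set seeds (seed set = round(w * baseline)),
    and the next cohort is sown proportionally to seed set.  After the
    selection rounds an inter-replicate random-crossing generation
    (labelled ``n_generations + 2``) is produced when ``final_cross``.
    """
    c = config
    pop = _Population(c)
    rng_fit = c.stream("fitness")
    reps = [f"R{r + 1}" for r in range(c.replicates)]
    cohorts = {}
    for r, rep in enumerate(reps):
        cohorts[rep] = [f"{rep}_G1_{k + 1}"
                        for k in range(c.plants_per_replicate)]
        for ind in cohorts[rep]:
            pop.add_founder(ind, 1, rep)

    fitness_rows = []
    for gen in range(1, c.n_generations + 1):
        for rep in reps:
            ids = cohorts[rep]
            phenos = pop.phenotypes(ids)
            sd = phenos.std(axis=0, ddof=1)
            sd[sd <= 0] = 1.0
            z = (phenos - phenos.mean(axis=0)) / sd
            for _attempt in range(10):
                visited = _visitation(len(ids), c, rng_fit)
                w = np.clip(
                    1.0 + z @ c.beta_true
                    + c.fitness_noise_sd * rng_fit.standard_normal(len(ids)),
                    0.0, None,
                )
                seeds = np.where(
                    visited, np.round(w * c.baseline_seeds), 0.0
                ).astype(int)
                if seeds.sum() > 0:
                    break
            else:
                raise RuntimeError("replicate produced no seeds repeatedly")
            for ind, s in zip(ids, seeds):
                fitness_rows.append((ind, int(s), rep, c.design, gen))
            counts = proportional_offspring_counts(
                seeds, c.plants_per_replicate
            )
            next_ids = []
            visited_ids = [i for i, v in zip(ids, visited) if v and
                           seeds[ids.index(i)] > 0]
            for j, (dam, cnt) in enumerate(zip(ids, counts)):
                for m in range(cnt):
                    child = f"{rep}_G{gen + 1}_{len(next_ids) + 1}"
                    sire_pool = [p for p in visited_ids if p != dam] or \
                        [p for p in ids if p != dam]
                    sire = sire_pool[
                        pop.rng_mating.integers(len(sire_pool))
                    ]
                    pop.add_offspring(child, sire, dam, gen + 1, rep)
                    next_ids.append(child)
            cohorts[rep] = next_ids

    if c.final_cross and c.replicates > 1:
        final_gen = c.n_generations + 2
        all_parents = [(rep, i) for rep in reps for i in cohorts[rep]]
        n_final = c.replicates * c.plants_per_replicate
        for j in range(n_final):
            while True:
                a = all_parents[pop.rng_mating.integers(len(all_parents))]
                b = all_parents[pop.rng_mating.integers(len(all_parents))]
                if a[0] != b[0]:  # parents from different replicates
                    break
            pop.add_offspring(f"X_G{final_gen}_{j + 1}", b[1], a[1],
                              final_gen, "crossed")

    return pop.study(fitness_rows=fitness_rows)
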