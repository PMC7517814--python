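"""Shared fixtures: hand-built pedigrees and cached simulated studies.

Expensive animal-model fits are session-scoped so several tests can share
one chain.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import evoquant as eq
from evoquant.simulate import SimulationConfig, run_random_mating


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def trio_pedigree():
    """Two unrelated founders and their offspring."""
    return eq.Pedigree.from_records([
        ("f1", None, None, 0, "x"),
        ("f2", None, None, 0, "x"),
        ("kid", "f1", "f2", 1, "x"),
    ])


@pytest.fixture
def fullsib_pedigree():
    """Full sibs from unrelated founders, plus their (inbred) offspring."""
    return eq.Pedigree.from_records([
        ("f1", None, None, 0, "x"),
        ("f2", None, None, 0, "x"),
        ("s1", "f1", "f2", 1, "x"),
        ("s2", "f1", "f2", 1, "x"),
        ("inb", "s1", "s2", 2, "x"),
    ])


def random_pedigree(rng, n_max: int = 30):
    """Random valid pedigree: founders plus randomly mated generations."""
    n_founders = int(rng.integers(3, 8))
    records = [(f"P{k}", None, None, 0, "x") for k in range(n_founders)]
    pool = [r[0] for r in records]
    gen = 0
    while len(records) < n_max and rng.random() < 0.9:
        gen += 1
        n_kids = int(rng.integers(1, 6))
        new = []
        for j in range(n_kids):
            if len(records) >= n_max:
                break
            sire, dam = rng.choice(pool, size=2, replace=True)
            if sire == dam and rng.random() < 0.5:
                dam = pool[int(rng.integers(len(pool)))]
            name = f"G{gen}_{j}"
            records.append((name, sire, dam, gen, "x"))
            new.append(name)
        pool = pool + new
    return eq.Pedigree.from_records(records)


def kinship_oracle(pedigree):
    """Independent brute-force coefficient-of-kinship recursion.

    A = 2 * kinship off the diagonal convention folded in:
    A_ij = 2 f_ij for i != j and A_ii = 2 f_ii = 1 + F_i.
    """
    frame = pedigree.frame
    parents = {r.id: (r.sire, r.dam) for r in frame.itertuples(index=False)}
    order = {r.id: k for k, r in enumerate(frame.itertuples(index=False))}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i, j):
        if order[i] > order[j]:
            i, j = j, i
        if i == j:
            s, d = parents[i]
            inb = f(s, d) if s is not None and not _isnan(s) and \
                d is not None and not _isnan(d) else 0.0
            return 0.5 * (1.0 + inb)
        s, d = parents[j]
        val = 0.0
        if s is not None and not _isnan(s):
            val += 0.5 * f(i, s)
        if d is not None and not _isnan(d):
            val += 0.5 * f(i, d)
        return val

    def _isnan(x):
        return isinstance(x, float) and np.isnan(x)

    ids = pedigree.ids
    n = len(ids)
    a = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = 2.0 * f(ids[i], ids[j])
    return a


@pytest.fixture(scope="session")
def sim_study_t2():
    """Random-mating study, t = 2, known G_true (session-cached)."""
    cfg = SimulationConfig(
        t=2, g_true=np.array([[1.0, 0.5], [0.5, 1.0]]),
        d_true=0.1 * np.eye(2), s_true=0.1 * np.eye(2), r_true=np.eye(2),
        n_founders=100, offspring_per_line=100, n_select=40, seed=101,
    )
    return run_random_mating(cfg)


@pytest.fixture(scope="session")
def fitted_t2(sim_study_t2):
    """Animal-model posterior on the t = 2 study (session-cached)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = eq.AnimalModel(sim_study_t2.traits, sim_study_t2.pedigree)
        return model.fit(chain=eq.ChainSettings(6000, 1500, 5), seed=7)
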