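"""Simulator: founder moments, transmission, both experimental designs."""

import numpy as np
import pytest

import evoquant as eq
from evoquant.simulate import (
    SimulationConfig,
    breed,
    proportional_offspring_counts,
    run_artificial_design,
    run_pollinator_design,
    run_random_mating,
    simulate_founders,
)


class TestFounders:
    def test_zero_g_phenotypic_cov_is_residual(self):
        r = np.array([[1.0, 0.3], [0.3, 2.0]])
        cfg = SimulationConfig(t=2, g_true=np.zeros((2, 2)),
                               d_true=np.zeros((2, 2)),
                               s_true=np.zeros((2, 2)), r_true=r, seed=1)
        _, bv, phen = simulate_founders(cfg, n=5000)
        assert np.allclose(bv, 0.0)
        assert np.allclose(np.cov(phen, rowvar=False), r, atol=0.1)

    def test_zero_residual_phenotype_equals_breeding_value(self):
        cfg = SimulationConfig(t=2, r_true=np.zeros((2, 2)),
                               d_true=np.zeros((2, 2)),
                               s_true=np.zeros((2, 2)), seed=2)
        _, bv, phen = simulate_founders(cfg, n=100)
        assert np.allclose(phen, bv + cfg.intercept)

    def test_breeding_value_variance_lln(self):
        cfg = SimulationConfig(t=1, g_true=np.array([[1.0]]), seed=3)
        _, bv, _ = simulate_founders(cfg, n=5000)
        assert bv.var(ddof=1) == pytest.approx(1.0, abs=0.08)


class TestBreed:
    def test_zero_parents_zero_g(self):
        cfg = SimulationConfig(t=2, g_true=np.zeros((2, 2)), seed=0)
        out = breed(cfg, [("s", "d")], {"s": np.zeros(2), "d": np.zeros(2)})
        assert np.allclose(out, 0.0)

    def test_mendelian_variance_noninbred(self):
        cfg = SimulationConfig(t=1, g_true=np.array([[1.0]]), seed=0)
        rng = np.random.default_rng(0)
        out = breed(cfg, [("s", "d")] * 20_000,
                    {"s": np.zeros(1), "d": np.zeros(1)}, rng=rng)
        assert out.var(ddof=1) == pytest.approx(0.5, abs=0.02)

    def test_mendelian_variance_shrinks_with_inbreeding(self):
        cfg = SimulationConfig(t=1, g_true=np.array([[1.0]]), seed=0)
        rng = np.random.default_rng(0)
        out = breed(cfg, [("s", "d")] * 20_000,
                    {"s": np.zeros(1), "d": np.zeros(1)},
                    inbreeding={"s": 1.0, "d": 1.0}, rng=rng)
        assert out.var(ddof=1) == pytest.approx(0.0, abs=1e-12)


class TestArtificialDesign:
    def test_pedigree_validates_and_shape(self):
        cfg = SimulationConfig(t=2, n_founders=60, offspring_per_line=20,
                               seed=4)
        study = run_artificial_design(cfg)
        # construction runs validate_pedigree; invariants hold
        ped = eq.validate_pedigree(study.pedigree)
        assert ped.n == 60 + 3 * 3 * 20
        lines = set(study.pedigree.frame["line"])
        assert {"tall", "short", "control", "parental"} <= lines

    def test_selection_direction(self):
        cfg = SimulationConfig(t=2, seed=5, n_founders=100,
                               offspring_per_line=40)
        study = run_artificial_design(cfg)
        means = study.traits.data.groupby(
            [study.pedigree.frame.set_index("id")["line"],
             study.traits.generation]).mean()
        assert means.loc[("tall", 3), "trait1"] > \
            means.loc[("short", 3), "trait1"]

    def test_realized_differential_logged(self):
        cfg = SimulationConfig(t=2, seed=6, n_founders=60,
                               offspring_per_line=20)
        study = run_artificial_design(cfg)
        log = study.truth["realized_selection"]
        tall1 = log[(log.line == "tall") & (log.generation == 0) &
                    (log.trait == "trait1")]
        assert tall1["S"].iloc[0] > 0
        short1 = log[(log.line == "short") & (log.generation == 0) &
                     (log.trait == "trait1")]
        assert short1["S"].iloc[0] < 0

    def test_zero_heritability_no_response(self):
        """G_true = 0: mean realized response across replicate runs sits in
        a 3-SE band around zero."""
        changes = []
        for seed in range(40):
            cfg = SimulationConfig(
                t=1, g_true=np.zeros((1, 1)), d_true=np.zeros((1, 1)),
                s_true=np.zeros((1, 1)), r_true=np.array([[1.0]]),
                n_founders=60, offspring_per_line=30, lines=("tall",),
                n_generations=1, seed=seed,
            )
            study = run_artificial_design(cfg)
            means = study.traits.generation_means()
            changes.append(means.loc[1, "trait1"] - means.loc[0, "trait1"])
        changes = np.array(changes)
        se = changes.std(ddof=1) / np.sqrt(len(changes))
        assert abs(changes.mean()) < 3 * se + 1e-12

    def test_control_line_martingale(self):
        """With no selection the generation means drift but center on zero
        across replicate runs."""
        changes = []
        for seed in range(40):
            cfg = SimulationConfig(t=1, g_true=np.array([[1.0]]),
                                   n_founders=40, offspring_per_line=40,
                                   n_select=16, n_generations=2, seed=seed,
                                   r_true=np.array([[1.0]]),
                                   d_true=np.zeros((1, 1)),
                                   s_true=np.zeros((1, 1)))
            study = run_random_mating(cfg)
            means = study.traits.generation_means()
            changes.append(means.loc[2, "trait1"] - means.loc[0, "trait1"])
        changes = np.array(changes)
        se = changes.std(ddof=1) / np.sqrt(len(changes))
        assert abs(changes.mean()) < 3 * se

    def test_truth_log_consistency(self):
        cfg = SimulationConfig(t=2, seed=7, n_founders=60,
                               offspring_per_line=20)
        study = run_artificial_design(cfg)
        bv = study.truth["breeding_values"]
        resid = study.traits.data - bv - cfg.intercept
        # non-genetic part has mean ~0 and variance ~ D + S + R
        expected = (cfg.d_true + cfg.s_true + cfg.r_true)[0, 0]
        offspring = study.pedigree.frame["sire"].notna().to_numpy()
        var = resid[offspring].var(ddof=1)["trait1"]
        assert var == pytest.approx(expected, rel=0.35)

    def test_selfing_rate_produces_selfed_offspring(self):
        cfg = SimulationConfig(t=1, seed=8, n_founders=40,
                               offspring_per_line=30, selfing_rate=1.0,
                               lines=("control",), n_generations=1)
        study = run_artificial_design(cfg)
        kids = study.pedigree.frame.dropna(subset=["sire"])
        assert (kids["sire"] == kids["dam"]).all()


class TestPollinatorDesign:
    def test_proportional_counts_hand_example(self):
        # 36 * 10/11 = 32.7 -> 33; 36 * 1/11 = 3.3 -> 3; zero seeds -> 0
        counts = proportional_offspring_counts([10, 1, 0], 36)
        assert list(counts) == [33, 3, 0]

    def test_below_half_rounds_up_to_one(self):
        # 36 * 1/200 = 0.18 < 0.5 -> 1, not 0
        counts = proportional_offspring_counts([199, 1], 36,
                                               exact_total=False)
        assert counts[1] == 1

    def test_exact_total_enforced(self, rng):
        for _ in range(20):
            seeds = rng.poisson(8, 12)
            if seeds.sum() == 0:
                continue
            counts = proportional_offspring_counts(seeds, 36)
            assert counts.sum() == 36

    def test_design_structure(self):
        cfg = SimulationConfig(t=2, design="pollinator", n_generations=3,
                               seed=9)
        study = run_pollinator_design(cfg)
        eq.validate_pedigree(study.pedigree)
        gens = set(study.pedigree.frame["generation"])
        assert gens == {1, 2, 3, 4, 5}  # 3 rounds + final cross (label +2)
        f = study.fitness.frame
        assert set(f["generation"]) == {1, 2, 3}
        cohort = study.pedigree.frame.groupby(["line", "generation"]).size()
        assert (cohort.loc["R1"] == cfg.plants_per_replicate).all()

    def test_final_cross_parents_from_different_replicates(self):
        cfg = SimulationConfig(t=2, design="pollinator", n_generations=2,
                               seed=10)
        study = run_pollinator_design(cfg)
        frame = study.pedigree.frame
        crossed = frame[frame["line"] == "crossed"]
        rep_of = frame.set_index("id")["line"]
        assert len(crossed) == cfg.replicates * cfg.plants_per_replicate
        assert (rep_of[crossed["sire"]].to_numpy() !=
                rep_of[crossed["dam"]].to_numpy()).all()

    def test_null_fitness_no_gradient(self):
        """beta_true = 0: recovered gradients are near zero."""
        import warnings

        from evoquant.traits import transform_traits

        cfg = SimulationConfig(t=2, design="pollinator", n_generations=6,
                               beta_true=np.zeros(2), seed=11)
        study = run_pollinator_design(cfg)
        f = study.fitness.frame
        ids = [i for i in study.traits.ids if i in set(f["id"])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traits = transform_traits(study.traits.restrict(ids), "zscore",
                                      zscore_scope="global")
        res = eq.LandeArnoldModel(traits, study.fitness).fit()
        assert np.all(np.abs(res.beta) < 4 * res.bse + 0.05)

    def test_positive_gradient_produces_correlated_response(self):
        """Selection on trait 1 drags positively covarying traits along
        (qualitative indirect-response structure)."""
        g = np.array([[0.4, 0.25], [0.25, 0.4]])
        changes = []
        for seed in range(6):
            cfg = SimulationConfig(
                t=2, design="pollinator", g_true=g,
                beta_true=np.array([0.5, 0.0]), n_generations=8,
                seed=100 + seed, fitness_noise_sd=0.2,
            )
            study = run_pollinator_design(cfg)
            means = study.traits.generation_means()
            changes.append(means.loc[10] - means.loc[1])
        mean_change = np.mean([c.to_numpy() for c in changes], axis=0)
        assert mean_change[0] > 0
        assert mean_change[1] > 0  # indirect response via covariance


def test_named_substreams_reproducible():
    cfg = SimulationConfig(t=2, seed=42)
    a = cfg.stream("founders").standard_normal(5)
    b = cfg.stream("founders").standard_normal(5)
    c = cfg.stream("mating").standard_normal(5)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_study_save_round_trip(tmp_path):
    cfg = SimulationConfig(t=2, n_founders=30, offspring_per_line=10,
                           n_generations=1, seed=12)
    study = run_artificial_design(cfg)
    study.save(tmp_path)
    ped = eq.read_pedigree(tmp_path / "pedigree.csv")
    traits = eq.read_traits(tmp_path / "phenotypes.csv")
    assert ped.n == study.pedigree.n
    assert np.allclose(traits.values(), study.traits.values())
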