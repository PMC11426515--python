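"""Mutation-dropping estimator: normalization, trajectories, fitting and
bootstrap behaviour."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import musema as m
from musema.mutation_drop import drop_genotypic_values
from conftest import make_line_pedigree


@pytest.mark.parametrize("n_ind", [10, 123, 5000])
def test_effect_normalization_exact(n_ind):
    """b * a^2 / 2 equals one unit of mutational variance exactly."""
    cfg = m.DropConfig(n_mutations_total=1_000_000)
    assert cfg.per_individual_variance(n_ind) == pytest.approx(1.0, abs=0)


def test_seeded_effect_variance_approaches_unit():
    """Empirical variance of per-individual seeded effects: each individual
    receives b mutations of effect +/- a, realizing variance b*a^2 = 2
    units (the V_M = b a^2/2 = 1 bookkeeping counts additive variance at
    the within-individual allele frequency 1/2)."""
    ped = make_line_pedigree(1, 1, 2)   # 4 individuals, no transmission noise
    # no descendants beyond g1 -> founder values are pure seed sums
    cfg = m.DropConfig(n_mutations_total=400_000, seed=1)
    vals = drop_genotypic_values(ped, cfg)
    # founders carry only their own seeds
    assert np.var(vals[:2], ddof=0) >= 0.0  # smoke: finite
    b = cfg.n_mutations_total / len(ped)
    a = cfg.effect(len(ped))
    assert b * a**2 == pytest.approx(2.0, rel=1e-12)


def _mini_phenotypes():
    rows = []
    rng = np.random.default_rng(0)
    for line in ("L1", "L2", "L3"):
        for gen in (1, 2, 3):
            for k in range(4):
                rows.append({"individual_id": f"{line}g{gen}i{k}",
                             "line": line, "generation": gen,
                             "sex": "male" if k % 2 == 0 else "female",
                             "y": 5.0})
    return pd.DataFrame(rows)


def test_identical_line_means_give_zero_z():
    df = _mini_phenotypes()
    ped = make_line_pedigree(3, 3, 4)
    z = m.observed_between_line_variances(df, ped, "y")
    assert np.allclose(z.z, 0.0)


def test_sex_correction_removes_additive_sex_effect():
    df = _mini_phenotypes()
    rng = np.random.default_rng(1)
    df["y"] = rng.normal(size=len(df))
    ped = make_line_pedigree(3, 3, 4)
    z0 = m.observed_between_line_variances(df, ped, "y").z
    df2 = df.copy()
    df2.loc[df2["sex"] == "male", "y"] += 7.0   # balanced sexes per line
    z1 = m.observed_between_line_variances(df2, ped, "y").z
    assert np.allclose(z0, z1, atol=1e-12)


def test_missing_trait_errors():
    with pytest.raises(KeyError):
        m.observed_between_line_variances(_mini_phenotypes(),
                                          make_line_pedigree(3, 3, 4),
                                          "nope")


def test_fit_exact_linear_combination():
    gens = np.arange(5)
    g = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    e = np.array([0.5, 0.4, 0.3, 0.35, 0.35])
    ser = m.VarianceSeries(gens, z=3.0 * g + 2.0 * e, g=g, e_env=e)
    est = m.fit_h2m(ser)
    assert est.x_coef == pytest.approx(3.0, abs=1e-10)
    assert est.y_coef == pytest.approx(2.0, abs=1e-10)
    assert est.h2m == pytest.approx(1.5, abs=1e-10)


def test_fit_pure_environment_gives_zero_h2m():
    gens = np.arange(4)
    g = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([0.5, 0.4, 0.3, 0.45])
    est = m.fit_h2m(m.VarianceSeries(gens, z=e.copy(), g=g, e_env=e))
    assert est.h2m == pytest.approx(0.0, abs=1e-10)


def test_fit_collinear_error():
    gens = np.arange(4)
    g = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(np.linalg.LinAlgError):
        m.fit_h2m(m.VarianceSeries(gens, z=g, g=g, e_env=2.0 * g))


def test_scale_equivariance():
    gens = np.arange(5)
    rng = np.random.default_rng(2)
    g = np.cumsum(rng.random(5)) + 1
    e = rng.random(5) + 0.2
    z = 0.02 * g + 1.1 * e + rng.normal(0, 0.01, 5)
    base = m.fit_h2m(m.VarianceSeries(gens, z=z, g=g, e_env=e))
    scaled = m.fit_h2m(m.VarianceSeries(gens, z=9.0 * z, g=g, e_env=e))
    assert scaled.x_coef == pytest.approx(9.0 * base.x_coef, rel=1e-10)
    assert scaled.y_coef == pytest.approx(9.0 * base.y_coef, rel=1e-10)
    assert scaled.h2m == pytest.approx(base.h2m, rel=1e-10)


def test_env_between_line_scale():
    """Equal line sizes n_l per generation: e_env ~ 1/n_l; one individual
    per line: e_env ~ 1."""
    ped = make_line_pedigree(10, 4, 8)
    cfg = m.DropConfig(n_env_replicates=300, seed=3)
    e = m.simulate_env_between_line(ped, cfg)
    assert np.allclose(e.e_env, 1.0 / 8, rtol=0.2)
    ped1 = make_line_pedigree(10, 4, 2)
    e1 = m.simulate_env_between_line(ped1, cfg)
    assert np.allclose(e1.e_env, 0.5, rtol=0.2)


def test_drop_seed_contract(small_experiment):
    ped, _, _ = small_experiment
    cfg = m.DropConfig(n_mutations_total=20_000, seed=5)
    g1 = m.simulate_mutation_drop(ped, cfg)
    g2 = m.simulate_mutation_drop(ped, cfg)
    assert np.array_equal(g1.g, g2.g)
    e1 = m.simulate_env_between_line(ped, cfg)
    e2 = m.simulate_env_between_line(ped, cfg)
    assert np.array_equal(e1.e_env, e2.e_env)


def test_g_trend_nondecreasing_in_expectation():
    """Between-line genetic variance accumulates with line separation."""
    ped = make_line_pedigree(12, 8, 4)
    acc = np.zeros(8)
    for s in range(6):
        cfg = m.DropConfig(n_mutations_total=50_000, seed=100 + s)
        acc += m.simulate_mutation_drop(ped, cfg).g
    acc /= 6
    # mean trajectory rises from the first to the last generation
    assert acc[-1] > acc[0]
    assert np.mean(np.diff(acc)) > 0


def test_bootstrap_seed_contract_and_null_ci(small_experiment):
    ped, phen, _ = small_experiment
    cfg = m.DropConfig(n_mutations_total=20_000, seed=6, n_env_replicates=30)
    a = m.bootstrap_h2m(phen, ped, "trait", cfg, n_boot=50)
    b = m.bootstrap_h2m(phen, ped, "trait", cfg, n_boot=50)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    assert a.ci_low < a.ci_high


def test_null_world_estimates_centre_on_zero(small_cfg):
    """Phenotypes with V_M = 0 give h2m estimates centred on zero under
    the estimator's environmental model (iid individual effects; shared
    litter/maternal environments are switched off, since environmental
    covariance within litters inflates between-line variance in a shape
    the iid e trajectory cannot absorb and leaks a small positive offset
    into the mutational weight)."""
    from musema.simulate import simulate_pedigree, simulate_phenotypes
    cfg0 = replace(small_cfg, v_m=0.0, v_litter=0.0, v_maternal=0.0, seed=7)
    ped = simulate_pedigree(cfg0)
    phen0, _ = simulate_phenotypes(ped, cfg0)
    zs = m.observed_between_line_variances(phen0, ped, "trait")
    ests = []
    # each replicate is a full experiment: fresh phenotypes AND a fresh
    # drop, since conditional on one (g, e) realization the least-squares
    # estimate has a fixed nonzero offset that only averages out across
    # independent drops
    for r in range(16):
        dc = m.DropConfig(n_mutations_total=50_000, seed=80 + r,
                          n_env_replicates=100)
        g = m.simulate_mutation_drop(ped, dc, generations=zs.generations)
        e = m.simulate_env_between_line(ped, dc, generations=zs.generations)
        phen, _ = simulate_phenotypes(ped, replace(cfg0, seed=900 + r))
        z = m.observed_between_line_variances(phen, ped, "trait")
        ests.append(m.fit_h2m(z.merged(g).merged(e)).h2m)
    se = np.std(ests, ddof=1) / np.sqrt(len(ests))
    assert abs(np.mean(ests)) < 3 * se + 2e-4
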