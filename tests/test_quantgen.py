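"""Relationship matrices (recursive oracle), REML mixed model (GLS and
OLS oracles), HDI arithmetic and quick animal-model sanity checks."""

import numpy as np
import pandas as pd
import pytest

from shoalgen import quantgen as qg
from shoalgen import synthdata as sd
from shoalgen.quantgen.animal import AnimalModelFit, hdi_interval

# ---------------------------------------------------------------------------
# A matrix


def recursive_a(ped):
    """Independent oracle: textbook recursive definition with memoization."""
    sire = dict(zip(ped["id"], ped["sire"]))
    dam = dict(zip(ped["id"], ped["dam"]))
    from functools import lru_cache

    order = {i: k for k, i in enumerate(ped["id"])}

    @lru_cache(maxsize=None)
    def a(i, j):
        if order[i] < order[j]:
            i, j = j, i
        si, di = sire[i], dam[i]
        if i == j:
            if si >= 0 and di >= 0:
                return 1.0 + 0.5 * a(si, di)
            return 1.0
        parts = []
        for p in (si, di):
            parts.append(a(p, j) if p >= 0 else 0.0)
        return 0.5 * sum(parts)

    return a


def test_a_matrix_unrelated_founders_identity():
    ped = pd.DataFrame(
        {
            "id": [0, 1, 2],
            "sire": [-1] * 3,
            "dam": [-1] * 3,
            "sex": ["M", "F", "F"],
            "line": [0] * 3,
            "regime": ["control"] * 3,
            "generation": ["parent"] * 3,
            "family": [0, 1, 2],
        }
    )
    np.testing.assert_allclose(qg.build_A_matrix(ped).to_numpy(), np.eye(3))


def test_a_matrix_textbook_identities(three_gen_pedigree):
    a = qg.build_A_matrix(three_gen_pedigree)
    assert a.loc[0, 3] == pytest.approx(0.5)  # parent-offspring
    assert a.loc[3, 4] == pytest.approx(0.5)  # full sibs
    assert a.loc[3, 5] == pytest.approx(0.25)  # half sibs
    assert a.loc[6, 6] == pytest.approx(1.25)  # full-sib mating: F = 0.25


def test_a_matrix_matches_recursive_oracle(three_gen_pedigree):
    a = qg.build_A_matrix(three_gen_pedigree)
    oracle = recursive_a(three_gen_pedigree)
    for i in three_gen_pedigree["id"]:
        for j in three_gen_pedigree["id"]:
            assert a.loc[i, j] == pytest.approx(oracle(i, j), abs=1e-12)


def test_a_matrix_symmetric_psd_bounded():
    cfg = sd.SimConfig(n_families_total=30, families_per_line=5)
    ped = sd.simulate_pedigree(cfg)
    a = qg.build_A_matrix(ped).to_numpy()
    np.testing.assert_allclose(a, a.T)
    assert np.linalg.eigvalsh(a).min() >= -1e-8
    assert a.min() >= 0 and a.max() <= 2


def test_pedigree_cycle_and_sex_errors(three_gen_pedigree):
    bad = three_gen_pedigree.copy()
    bad.loc[bad["id"] == 0, "sire"] = 7  # male descendant as ancestor: loop
    with pytest.raises(ValueError, match="cycle"):
        qg.build_A_matrix(bad)
    bad2 = three_gen_pedigree.copy()
    bad2.loc[bad2["id"] == 3, "dam"] = 0  # male dam
    with pytest.raises(ValueError, match="dam"):
        qg.build_A_matrix(bad2)


def test_subset_same_sex(three_gen_pedigree):
    a = qg.build_A_matrix(three_gen_pedigree)
    sub, ids = qg.subset_same_sex(three_gen_pedigree, a, "F")
    assert set(ids) == {1, 2, 4, 6}
    # relatedness through males is preserved after subsetting
    assert sub.loc[4, 6] == a.loc[4, 6]
    subm, ids_m = qg.subset_same_sex(three_gen_pedigree, a, "M")
    assert 4 not in ids_m  # sisters absent from the male set
    assert subm.loc[3, 5] == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# LMM


def lmm_data(rng, n_group=60, delta=0.0):
    n = 2 * n_group
    df = pd.DataFrame(
        {
            "regime": ["polarization"] * n_group + ["control"] * n_group,
            "sex": list(np.tile(["F", "M"], n // 2)),
            "generation": "offspring",
            "group_activity": rng.standard_normal(n),
            "line": rng.integers(0, 6, n),
            "family": rng.integers(0, 30, n),
            "group_use": rng.integers(1, 8, n),
        }
    )
    df["phenotype"] = (
        delta * (df["regime"] == "polarization")
        + 0.1 * df["group_activity"]
        + rng.standard_normal(n)
    )
    return df


def test_lmm_zero_variances_matches_ols(rng):
    df = lmm_data(rng, delta=0.4)
    fixed = ["regime", "sex", "regime:sex", "group_activity"]
    res = qg.fit_lmm(
        df,
        "phenotype",
        fixed,
        ["line", "family"],
        fix_variances={"residual": 1.0, "line": 0.0, "family": 0.0},
    )
    from shoalgen.quantgen.lmm import _encode_terms

    x, names = _encode_terms(df, fixed)
    ols = np.linalg.lstsq(x, df["phenotype"].to_numpy(), rcond=None)[0]
    np.testing.assert_allclose(res.coefficients["estimate"], ols, atol=1e-6)


def test_lmm_gls_oracle_fixed_components(rng):
    df = lmm_data(rng, n_group=15, delta=0.3)
    fixed = ["regime", "group_activity"]
    vfix = {"residual": 0.8, "line": 0.3}
    res = qg.fit_lmm(df, "phenotype", fixed, ["line"], fix_variances=vfix)
    from shoalgen.quantgen.lmm import _encode_terms, _z_matrices

    x, _ = _encode_terms(df, fixed)
    z = _z_matrices(df, ["line"])["line"]
    v = 0.8 * np.eye(len(df)) + 0.3 * (z @ z.T)
    vinv = np.linalg.inv(v)
    beta = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ df["phenotype"].to_numpy())
    np.testing.assert_allclose(res.coefficients["estimate"], beta, atol=1e-6)
    cov = np.linalg.inv(x.T @ vinv @ x)
    np.testing.assert_allclose(res.coefficients["se"], np.sqrt(np.diag(cov)), atol=1e-6)


def test_lmm_recovers_planted_effect(rng):
    ests = []
    for s in range(8):
        df = lmm_data(np.random.default_rng(100 + s), n_group=120, delta=0.5)
        res = qg.fit_lmm(df, "phenotype", ["regime", "group_activity"], ["line"])
        ests.append(res.coefficients.loc["regime[polarization]", "estimate"])
    assert np.mean(ests) == pytest.approx(0.5, abs=0.08)


def test_lmm_sex_specific_regime_contrasts():
    cfg = sd.config_for_h2(0.2, 0.2, 0.5, seed=31)
    ped = sd.simulate_pedigree(cfg)
    rng = np.random.default_rng(31)
    truth = sd.simulate_breeding_values(ped, cfg, rng)
    phen = sd.simulate_phenotypes(ped, truth, cfg, rng)  # regime_f=0.2, regime_m=0
    res = qg.fit_lmm(
        phen,
        "phenotype",
        ["regime", "sex", "regime:sex", "generation", "group_activity"],
        ["line", "family", "group_use"],
    )
    con = qg.regime_contrasts_by_sex(res)
    assert con.loc["F", "estimate"] == pytest.approx(0.2, abs=0.25)
    assert abs(con.loc["M", "estimate"]) < 0.25
    assert (con["df"] > 0).all() and (con["se"] > 0).all()


def test_lmm_singular_design_warns(rng):
    df = lmm_data(rng)
    df["dup"] = df["group_activity"]
    with pytest.warns(UserWarning, match="singular"):
        qg.fit_lmm(df, "phenotype", ["group_activity", "dup"], ["line"])


# ---------------------------------------------------------------------------
# HDI / summaries


def test_hdi_matches_bruteforce_search(rng):
    draws = np.concatenate([rng.normal(0, 1, 4000), rng.normal(5, 0.5, 2000)])
    lo, hi = hdi_interval(draws, 0.9)
    x = np.sort(draws)
    m = int(np.ceil(0.9 * len(x)))
    widths = [(x[i + m] - x[i], x[i], x[i + m]) for i in range(len(x) - m)]
    w, lo2, hi2 = min(widths)
    assert (lo, hi) == (pytest.approx(lo2), pytest.approx(hi2))
    inside = ((draws >= lo) & (draws <= hi)).mean()
    assert inside >= 0.9


def test_heritability_summary_arithmetic():
    draws = {
        "va": np.full((1, 100), 2.0),
        "v_res": np.full((1, 100), 2.0),
        "h2": np.full((1, 100), 0.5),
    }
    fit = AnimalModelFit(
        draws=draws,
        diagnostics=pd.DataFrame(),
        converged=True,
        flags=[],
        model="univariate",
        fixed_effect_names=[],
    )
    s = qg.heritability_summary(fit)
    assert s.loc[s.parameter == "h2", "median"].iloc[0] == pytest.approx(0.5)


def test_prior_predictive_h2_spans_unit_interval():
    h2 = qg.prior_predictive_h2(n=4000, seed=1)
    assert h2.min() < 0.05 and h2.max() > 0.95
    assert ((h2 > 0) & (h2 < 1)).all()


# ---------------------------------------------------------------------------
# animal model sanity (small, fast configurations)


SMALL_MCMC = qg.McmcConfig(chains=2, draws=500, warmup=400, seed=3)


def small_dataset(h2f=0.3, h2m=0.3, r=0.6, n_fam=60, seed=5):
    cfg = sd.config_for_h2(h2f, h2m, r, seed=seed)
    cfg = sd.SimConfig(**{**cfg.to_dict(), "n_families_total": n_fam, "families_per_line": 10,
                          "fixed_effects": cfg.fixed_effects})
    ped = sd.simulate_pedigree(cfg)
    rng = np.random.default_rng(seed)
    truth = sd.simulate_breeding_values(ped, cfg, rng)
    phen = sd.simulate_phenotypes(ped, truth, cfg, rng)
    return ped, phen, qg.build_A_matrix(ped)


def test_animal_model_null_heritability_near_zero():
    # no additive or family variance planted; full study size (195 fams)
    cfg = sd.config_for_h2(0.0, 0.0, 0.0, v_family=0.0, seed=11)
    ped = sd.simulate_pedigree(cfg)
    rng = np.random.default_rng(11)
    truth = sd.simulate_breeding_values(ped, cfg, rng)
    phen = sd.simulate_phenotypes(ped, truth, cfg, rng)
    a = qg.build_A_matrix(ped)
    fit = qg.fit_same_sex_model(phen, a, "F", mcmc=SMALL_MCMC)
    assert fit.posterior_median("h2") < 0.1
    lo, hi = fit.hdi("h2")
    assert lo < 0.02


def test_animal_model_rescaling_invariance_of_h2():
    ped, phen, a = small_dataset(seed=13)
    fit1 = qg.fit_same_sex_model(phen, a, "F", mcmc=SMALL_MCMC)
    phen2 = phen.copy()
    phen2["phenotype"] = 2.0 * phen2["phenotype"]
    fit2 = qg.fit_same_sex_model(phen2, a, "F", mcmc=SMALL_MCMC)
    assert fit1.posterior_median("h2") == pytest.approx(
        fit2.posterior_median("h2"), abs=0.06
    )


def test_animal_model_seed_reproducibility():
    ped, phen, a = small_dataset(seed=17)
    f1 = qg.fit_same_sex_model(phen, a, "M", mcmc=SMALL_MCMC)
    f2 = qg.fit_same_sex_model(phen, a, "M", mcmc=SMALL_MCMC)
    np.testing.assert_array_equal(f1.draws["h2"], f2.draws["h2"])


def test_animal_model_nonpsd_a_errors():
    ped, phen, a = small_dataset(seed=19)
    bad = a.copy()
    bad.iloc[0, 1] = bad.iloc[1, 0] = 1.5  # breaks PSD
    with pytest.raises(ValueError, match="positive semi-definite"):
        qg.fit_animal_model(phen, bad, mcmc=SMALL_MCMC)


def test_bivariate_single_sex_flagged():
    ped, phen, a = small_dataset(seed=23)
    females = phen[phen["sex"] == "F"]
    with pytest.warns(UserWarning, match="single-sex"):
        fit = qg.fit_bivariate_animal_model(females, a, mcmc=SMALL_MCMC)
    assert not fit.converged
    assert any("unidentified" in f for f in fit.flags)


def test_bivariate_perfect_correlation_recovers_high_r():
    cfg = sd.config_for_h2(0.4, 0.4, 1.0, seed=29)
    ped = sd.simulate_pedigree(cfg)
    rng = np.random.default_rng(29)
    truth = sd.simulate_breeding_values(ped, cfg, rng)
    phen = sd.simulate_phenotypes(ped, truth, cfg, rng)
    a = qg.build_A_matrix(ped)
    mc = qg.McmcConfig(chains=2, draws=800, warmup=600, seed=5, mh_substeps=4)
    fit = qg.fit_bivariate_animal_model(phen, a, mcmc=mc)
    assert fit.posterior_median("r_fm") > 0.8
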