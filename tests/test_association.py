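import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from fritassoc.association import (
    association_scan,
    encode_genotype,
    fit_mixed_model,
    pilot_models,
    simplify_model,
)
from fritassoc.data import DataError
from fritassoc.simulate import (
    PopulationSpec,
    SnpEffect,
    TraitModel,
    simulate_genotypes,
    simulate_traits,
)

from conftest import make_meta


# -- encodings --------------------------------------------------------------

@pytest.mark.parametrize("scheme, expected", [
    ("additive", [0, 1, 2]),
    ("dominant", [0, 1, 1]),
    ("recessive", [0, 0, 1]),
    ("overdominant", [0, 1, 0]),
])
def test_encoding_definitions(scheme, expected):
    out = encode_genotype([0.0, 1.0, 2.0], scheme)
    assert out.tolist() == expected


def test_encoding_missing_passthrough():
    out = encode_genotype([0.0, np.nan, 2.0], "dominant")
    assert np.isnan(out[1]) and out[0] == 0 and out[2] == 1


def test_unknown_scheme_rejected():
    with pytest.raises(DataError):
        encode_genotype([0.0], "multiplicative")


def test_dominant_recessive_swap_under_allele_flip(rng):
    """Flipping which allele is minor swaps the dominant and recessive roles."""
    counts = rng.integers(0, 3, 200).astype(float)
    flipped = 2.0 - counts
    assert np.array_equal(encode_genotype(flipped, "dominant"),
                          1.0 - encode_genotype(counts, "recessive"))
    assert np.array_equal(encode_genotype(flipped, "recessive"),
                          1.0 - encode_genotype(counts, "dominant"))
    assert np.array_equal(encode_genotype(flipped, "overdominant"),
                          encode_genotype(counts, "overdominant"))


# -- mixed-model fits -------------------------------------------------------

def _design(n_per_pop=40, seed=0, n_pops=4):
    rng = np.random.default_rng(seed)
    samples, pops = [], []
    for p in range(n_pops):
        for i in range(n_per_pop):
            samples.append(f"P{p}_s{i}")
            pops.append(f"P{p}")
    env = {f"P{p}": ("fragmented" if p < n_pops // 2 else "continuous")
           for p in range(n_pops)}
    meta = make_meta(samples, pops, env,
                     sexes=list(rng.choice(["male", "female"], len(samples))))
    code = pd.Series(rng.binomial(2, 0.3, len(samples)).astype(float),
                     index=meta.index)
    return meta, code, rng


def test_noiseless_recovery():
    meta, code, _ = _design()
    response = 1.0 * code
    fit = fit_mixed_model(response, meta, code, include_interaction=False)
    assert fit.terms["genotype"].estimate == pytest.approx(1.0, abs=1e-6)


def test_matches_ols_when_population_variance_estimate_hits_boundary():
    """With no simulated population variance the REML estimate regularly hits
    the zero boundary, and there the fixed effects must equal plain OLS."""
    found = 0
    for seed in range(8):
        meta, code, rng = _design(seed=seed)
        response = pd.Series(
            0.4 * code + 0.3 * (meta["environment"] == "fragmented")
            + rng.standard_normal(len(meta)), index=meta.index)
        fit = fit_mixed_model(response, meta, code, include_sex=False,
                              include_interaction=False)
        if not fit.boundary:
            continue
        found += 1
        df = pd.DataFrame({
            "score": response,
            "env": (meta["environment"] == "fragmented").astype(float),
            "genotype": code,
        })
        ols = smf.ols("score ~ env + genotype", df).fit()
        for term in ("env", "genotype"):
            assert fit.terms[term].estimate == pytest.approx(ols.params[term],
                                                             abs=1e-6)
    assert found >= 1


def test_constant_genotype_rejected():
    meta, code, _ = _design()
    with pytest.raises(DataError, match="constant"):
        fit_mixed_model(pd.Series(np.arange(len(meta), dtype=float),
                                  index=meta.index),
                        meta, pd.Series(1.0, index=meta.index))


def test_zero_variance_response_rejected():
    meta, code, _ = _design()
    with pytest.raises(DataError, match="variance"):
        fit_mixed_model(pd.Series(1.0, index=meta.index), meta, code)


# -- simplification ---------------------------------------------------------

def test_interaction_dropped_when_null():
    meta, code, rng = _design(seed=5)
    response = pd.Series(0.5 * code + rng.standard_normal(len(meta)),
                         index=meta.index)
    full = fit_mixed_model(response, meta, code, include_sex=False)
    final = simplify_model(full, alpha=0.05)
    if full.terms["env_x_genotype"].p >= 0.05:
        assert final.interaction_removed
        assert "env_x_genotype" not in final.terms
    else:  # rare draw with a chance interaction
        assert not final.interaction_removed


def test_interaction_kept_when_strong():
    meta, code, rng = _design(n_per_pop=100, seed=6)
    env = (meta["environment"] == "fragmented").astype(float)
    response = pd.Series(1.5 * code * env + rng.standard_normal(len(meta)),
                         index=meta.index)
    full = fit_mixed_model(response, meta, code, include_sex=False)
    final = simplify_model(full, alpha=0.05)
    assert final.interaction_removed is False
    assert final.interaction_p < 0.05


def test_simplify_requires_interaction_fit():
    meta, code, rng = _design()
    response = pd.Series(rng.standard_normal(len(meta)), index=meta.index)
    fit = fit_mixed_model(response, meta, code, include_interaction=False)
    with pytest.raises(DataError):
        simplify_model(fit)


def test_true_interaction_detected_reliably():
    detected = 0
    reps = 12
    for seed in range(reps):
        meta, code, rng = _design(n_per_pop=100, seed=100 + seed)
        env = (meta["environment"] == "fragmented").astype(float)
        response = pd.Series(1.0 * code * env + rng.standard_normal(len(meta)),
                             index=meta.index)
        full = fit_mixed_model(response, meta, code, include_sex=False)
        final = simplify_model(full, alpha=0.05)
        detected += final.interaction_removed is False
    assert detected >= 0.9 * reps


# -- grid scan --------------------------------------------------------------

def _tiny_scan_inputs(seed=9, n_loci=2):
    specs = [PopulationSpec(p, e, 40, 1, [0.35] * n_loci) for p, e in
             [("AL", "fragmented"), ("UP", "fragmented"),
              ("GO", "continuous"), ("SA", "continuous")]]
    geno, meta, _ = simulate_genotypes(specs, n_loci, seed=seed)
    rng = np.random.default_rng(seed)
    scores = pd.DataFrame({
        "sample_id": list(meta.index) * 2,
        "battery": ["development"] * len(meta) + ["male_adult"] * len(meta),
        "component": ["PC1"] * len(meta) + ["PC1"] * len(meta),
        "score": rng.standard_normal(2 * len(meta)),
    })
    return geno, meta, scores


def test_grid_arithmetic_and_family_size():
    geno, meta, scores = _tiny_scan_inputs()
    table, log = association_scan(scores, geno, meta)
    # 2 loci x 2 components x 4 schemes, minus any degenerate/failed cells
    assert log["tests_fitted"] + log["tests_skipped"] == 16
    assert log["fdr_family_size"] == log["tests_fitted"] == len(table)
    assert (table["p_adj"] >= table["p"] - 1e-12).all()


def test_scan_deterministic():
    geno, meta, scores = _tiny_scan_inputs()
    t1, _ = association_scan(scores, geno, meta)
    t2, _ = association_scan(scores, geno, meta)
    pd.testing.assert_frame_equal(t1, t2)


def test_monomorphic_cell_skipped_and_logged():
    geno, meta, scores = _tiny_scan_inputs()
    # force one locus monomorphic
    geno.df["snp02"] = geno.df["snp02"].iloc[0][0] * 2
    geno._alleles.clear()
    table, log = association_scan(scores, geno, meta)
    reasons = {s["reason"] for s in log["skips"]}
    assert any("constant" in r for r in reasons)
    assert log["tests_fitted"] == len(table)
    assert set(table["locus"]) == {"snp01"}


def test_empty_grid_is_an_error():
    geno, meta, scores = _tiny_scan_inputs()
    geno.df[:] = "NN"
    geno._alleles.clear()
    with pytest.raises(DataError, match="empty"):
        association_scan(scores, geno, meta)


# -- pilot models -----------------------------------------------------------

def _pilot_dataset(family_sd, seed, n_fam=30, sibs=6, beta=0.0):
    specs = [PopulationSpec(p, e, n_fam, sibs, [0.3]) for p, e in
             [("AL", "fragmented"), ("GO", "continuous")]]
    geno, meta, _ = simulate_genotypes(specs, 1, seed=seed)
    model = TraitModel("pupal_weight", family_sd=family_sd, residual_sd=1.0,
                       snp_effects=([SnpEffect("snp01", "dominant", beta)]
                                    if beta else []))
    traits = simulate_traits(geno, meta, [model], seed=seed + 1)
    code = pd.Series(encode_genotype(geno.minor_counts()["snp01"], "dominant"),
                     index=meta.index)
    return traits["pupal_weight"], code, meta


def test_pilot_zero_family_variance_at_boundary():
    trait, code, meta = _pilot_dataset(family_sd=0.0, seed=30)
    fit = pilot_models(trait, code, meta)
    assert fit.family_var == pytest.approx(0.0, abs=0.05)


def test_pilot_family_variance_recovered():
    estimates = []
    for seed in range(5):
        trait, code, meta = _pilot_dataset(family_sd=2.0, seed=40 + seed)
        fit = pilot_models(trait, code, meta)
        estimates.append(fit.family_var)
    mean_var = np.mean(estimates)
    assert abs(mean_var - 4.0) / 4.0 < 0.5


def test_pilot_detects_genotype_effect():
    hits = 0
    reps = 10
    for seed in range(reps):
        trait, code, meta = _pilot_dataset(family_sd=0.5, seed=60 + seed,
                                           beta=1.0)
        fit = pilot_models(trait, code, meta)
        g = fit.terms["genotype"]
        hits += (g.estimate > 0) and (g.p < 0.05)
    assert hits >= 8
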