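import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fritassoc.data import DataError
from fritassoc.qc import (
    GenotypeCounts,
    UndefinedMAFError,
    apply_qc,
    fdr_adjust,
    genotype_counts,
    hwe_chi2_test,
    hwe_exact_test,
    maf,
)
from fritassoc.simulate import PopulationSpec, simulate_genotypes

from conftest import make_geno, make_meta


# -- genotype_counts --------------------------------------------------------

@pytest.mark.parametrize(
    "calls, expected",
    [
        (["AA", "AC", "CC", "NN"], (1, 1, 1, 1)),
        (["CA"], (0, 1, 0, 0)),  # order-insensitive heterozygote
        ([], (0, 0, 0, 0)),
    ],
)
def test_genotype_counts_tally(calls, expected):
    assert genotype_counts(calls, major="A", minor="C") == expected


def test_genotype_counts_rejects_triallelic():
    with pytest.raises(DataError, match="alleles"):
        genotype_counts(["AA", "AC", "AG"])


# -- maf --------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts, expected",
    [
        ((25, 50, 25, 0), 0.5),
        ((90, 10, 0, 0), 0.05),
        ((10, 0, 0, 5), 0.0),  # monomorphic; missing excluded
    ],
)
def test_maf_examples(counts, expected):
    assert maf(GenotypeCounts(*counts)) == pytest.approx(expected)


def test_maf_all_missing_undefined():
    with pytest.raises(UndefinedMAFError):
        maf(GenotypeCounts(0, 0, 0, 7))


# -- HWE exact test ---------------------------------------------------------

def brute_force_hwe(n_mm, n_het, n_nn):
    """Exhaustive conditional-distribution oracle using exact rationals."""
    from fractions import Fraction

    n = n_mm + n_het + n_nn
    n_minor = min(n_het + 2 * n_nn, 2 * n - n_het - 2 * n_nn)
    if n == 0 or n_minor == 0:
        return 1.0
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        rare = (n_minor - h) // 2
        common = n - h - rare
        if common < 0:
            continue
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(rare) * math.factorial(h) * math.factorial(common),
        )
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def test_hwe_perfect_proportions():
    assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)


def test_hwe_extreme_heterozygote_deficit():
    assert hwe_exact_test(50, 0, 50) < 1e-20


@pytest.mark.parametrize("n_mm, n_het, n_nn", [
    (n_mm, n_het, n_nn)
    for n_mm in range(0, 6)
    for n_het in range(0, 6)
    for n_nn in range(0, 6)
    if 0 < n_mm + n_het + n_nn <= 10
])
def test_hwe_matches_enumeration(n_mm, n_het, n_nn):
    assert hwe_exact_test(n_mm, n_het, n_nn) == pytest.approx(
        brute_force_hwe(n_mm, n_het, n_nn), rel=1e-9
    )


def test_hwe_chi2_close_to_exact_at_large_n():
    # asymptotic agreement, not identity
    p_exact = hwe_exact_test(400, 440, 160)
    p_chi2 = hwe_chi2_test(400, 440, 160)
    assert abs(p_exact - p_chi2) < 0.05


# -- BH FDR -----------------------------------------------------------------

def test_fdr_hand_stepup_oracle():
    adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    # 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 -> monotone enforcement -> all 0.04
    assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_fdr_single_and_ties():
    assert fdr_adjust([0.03]) == pytest.approx([0.03])
    assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])


def test_fdr_rejects_out_of_range():
    with pytest.raises(DataError):
        fdr_adjust([0.5, 1.5])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_fdr_properties(pvals):
    adj = fdr_adjust(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    # order of the sorted raw values is preserved in the adjusted values
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


# -- two-tier rule ----------------------------------------------------------

def _four_pop_dataset(bad_pops_l1=(), monomorphic=False):
    """40 samples, 4 populations; L1 optionally spoiled in chosen pops."""
    samples, pops, l1, l2 = [], [], [], []
    for p, pop in enumerate(["P1", "P2", "P3", "P4"]):
        for i in range(10):
            samples.append(f"{pop}_s{i}")
            pops.append(pop)
            if pop in bad_pops_l1:
                l1.append("AA" if monomorphic else ("AA" if i < 5 else "CC"))
            else:
                l1.append(["AA", "AC", "AC", "CC"][i % 4])
            l2.append(["AA", "AC", "AC", "CC"][i % 4])
    geno = make_geno({"L1": l1, "L2": l2}, samples)
    meta = make_meta(samples, pops)
    return geno, meta


def test_locus_failing_in_two_populations_dropped():
    geno, meta = _four_pop_dataset(bad_pops_l1=("P1", "P2"))
    filtered, records = apply_qc(geno, meta)
    rec = {r.locus: r for r in records}
    assert rec["L1"].verdict == "drop"
    assert "L1" not in filtered.loci and "L2" in filtered.loci


def test_locus_failing_in_one_population_masked():
    geno, meta = _four_pop_dataset(bad_pops_l1=("P2",))
    filtered, records = apply_qc(geno, meta)
    rec = {r.locus: r for r in records}
    assert rec["L1"].verdict == "mask"
    assert rec["L1"].masked_populations == ["P2"]
    masked = filtered.df.loc[meta["population"] == "P2", "L1"]
    assert (masked == "NN").all()
    untouched = filtered.df.loc[meta["population"] != "P2", "L1"]
    assert (untouched == geno.df.loc[meta["population"] != "P2", "L1"]).all()


def test_all_pass_retains_matrix_unchanged():
    geno, meta = _four_pop_dataset()
    filtered, records = apply_qc(geno, meta)
    assert all(r.verdict == "retain" for r in records)
    pd.testing.assert_frame_equal(filtered.df, geno.df)


def test_monomorphic_population_counts_as_maf_failure():
    geno, meta = _four_pop_dataset(bad_pops_l1=("P3",), monomorphic=True)
    _, records = apply_qc(geno, meta)
    rec = {r.locus: r for r in records}
    assert rec["L1"].verdict == "mask"
    assert rec["L1"].masked_populations == ["P3"]


def test_apply_qc_idempotent():
    geno, meta = _four_pop_dataset(bad_pops_l1=("P2",))
    once, _ = apply_qc(geno, meta)
    twice, _ = apply_qc(once, meta)
    pd.testing.assert_frame_equal(once.df, twice.df)


def test_qc_masking_never_alters_calls(study_ds):
    filtered, _ = apply_qc(study_ds.genotypes, study_ds.meta)
    orig = study_ds.genotypes.df[filtered.loci]
    changed = (filtered.df != orig) & (filtered.df != "NN")
    assert not changed.any().any()


def test_null_drop_rate_below_fdr_level():
    """HW-conforming loci with comfortable MAF are almost never dropped."""
    drops = 0
    total = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        mafs = list(rng.uniform(0.15, 0.5, 12))
        specs = [PopulationSpec(p, e, 30, 1, mafs) for p, e in
                 [("AL", "fragmented"), ("UP", "fragmented"),
                  ("GO", "continuous"), ("SA", "continuous")]]
        geno, meta, _ = simulate_genotypes(specs, 12, seed=seed)
        _, records = apply_qc(geno, meta)
        drops += sum(r.verdict == "drop" for r in records)
        total += len(records)
    assert drops / total <= 0.05
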