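"""Pairwise Weir–Cockerham FST and standardized FST between populations.

Theta is the variance-components estimator: per locus and allele the
among-population (a), among-individual-within-population (b) and
within-individual (c) components are computed from sample sizes, allele
frequencies and observed heterozygote proportions; the multi-locus estimate
is the ratio of summed a over summed (a + b + c) (ratio of averages, not
average of ratios). Negative estimates are reported as-is.

Standardized FST divides theta by the maximum attainable given the observed
within-population diversity, obtained operationally by recoding each
population's alleles to private labels (keeping genotype counts and
missingness) and recomputing theta on the recoded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING_CALL, DataError, GenotypeMatrix


class FstUndefinedError(DataError):
    """No usable locus, or zero denominator."""


def _locus_components(n: np.ndarray, allele_counts: dict, het_counts: dict):
    """Weir–Cockerham a, b, c for one locus, summed over alleles.

    Parameters: per-population genotyped sample sizes ``n``; per allele, the
    allele-copy counts and heterozygote-carrier counts per population.
    """
    r = len(n)
    if np.any(n < 1):
        return 0.0, 0.0, 0.0
    nbar = n.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0, 0.0
    a_sum = b_sum = c_sum = 0.0
    for allele, counts in allele_counts.items():
        p = counts / (2.0 * n)
        pbar = counts.sum() / (2.0 * n.sum())
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = het_counts[allele].sum() / n.sum()
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _locus_tables(geno: GenotypeMatrix, pop_ids: list[list[str]], locus: str, recode: bool):
    """Per-population allele-count / het-count tables for one locus."""
    r = len(pop_ids)
    n = np.zeros(r)
    allele_counts: dict = {}
    het_counts: dict = {}
    for i, ids in enumerate(pop_ids):
        for call in geno.df.loc[ids, locus]:
            if call == MISSING_CALL:
                continue
            n[i] += 1
            a1, a2 = call[0], call[1]
            if recode:
                a1, a2 = (i, a1), (i, a2)
            for a in (a1, a2):
                if a not in allele_counts:
                    allele_counts[a] = np.zeros(r)
                    het_counts[a] = np.zeros(r)
                allele_counts[a][i] += 1
            if a1 != a2:
                het_counts[a1][i] += 1
                het_counts[a2][i] += 1
    return n, allele_counts, het_counts


def wc_components(
    geno: GenotypeMatrix, meta: pd.DataFrame, populations, locus: str, recode: bool = False
):
    """Weir–Cockerham (a, b, c) for one locus across the given populations."""
    pop_ids = [
        [s for s in meta.index[meta["population"] == p] if s in geno.df.index]
        for p in populations
    ]
    n, ac, hc = _locus_tables(geno, pop_ids, locus, recode)
    return _locus_components(n, ac, hc)


def _multilocus_theta(geno, meta, populations, loci, recode):
    num = den = 0.0
    for locus in loci:
        a, b, c = wc_components(geno, meta, populations, locus, recode=recode)
        num += a
        den += a + b + c
    if den == 0.0:
        raise FstUndefinedError(
            f"theta undefined for populations {tuple(populations)}: "
            "no polymorphic locus with usable samples"
        )
    return num / den


def pairwise_fst(
    geno: GenotypeMatrix, meta: pd.DataFrame, pop_a: str, pop_b: str, loci=None
) -> float:
    """Multi-locus Weir–Cockerham theta between two populations."""
    loci = list(loci) if loci is not None else geno.loci
    return _multilocus_theta(geno, meta, [pop_a, pop_b], loci, recode=False)


def standardized_fst(
    geno: GenotypeMatrix, meta: pd.DataFrame, pop_a: str, pop_b: str, loci=None
) -> float:
    """Theta rescaled by its maximum given observed within-population diversity."""
    loci = list(loci) if loci is not None else geno.loci
    theta = _multilocus_theta(geno, meta, [pop_a, pop_b], loci, recode=False)
    theta_max = _multilocus_theta(geno, meta, [pop_a, pop_b], loci, recode=True)
    if theta_max == 0.0:
        raise FstUndefinedError("maximum theta is zero; standardized FST undefined")
    return theta / theta_max


def _fast_biallelic_theta(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Vectorized two-population bi-allelic theta.

    ``x1``/``x2``: (..., n_i, L) minor-allele counts with NaN for missing.
    Returns theta over the trailing locus axis for each leading index.
    """
    v1 = np.isfinite(x1)
    v2 = np.isfinite(x2)
    n1 = v1.sum(axis=-2).astype(float)
    n2 = v2.sum(axis=-2).astype(float)
    s1 = np.nansum(x1, axis=-2)
    s2 = np.nansum(x2, axis=-2)
    h1 = np.nansum(x1 == 1, axis=-2).astype(float)
    h2 = np.nansum(x2 == 1, axis=-2).astype(float)
    ok = (n1 >= 1) & (n2 >= 1) & ((n1 + n2) > 2)
    n1 = np.where(ok, n1, 2.0)
    n2 = np.where(ok, n2, 2.0)
    nbar = (n1 + n2) / 2.0
    nc = 2 * nbar - (n1**2 + n2**2) / (2 * nbar)
    p1 = s1 / (2 * n1)
    p2 = s2 / (2 * n2)
    pbar = (s1 + s2) / (2 * (n1 + n2))
    s2v = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (h1 + h2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2v - (pbar * (1 - pbar) - s2v / 2.0 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2v / 2.0 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2.0
    # both alleles of a bi-allelic locus contribute symmetrically (factor 2
    # cancels in the ratio)
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    c = np.where(ok, c, 0.0)
    num = a.sum(axis=-1)
    den = (a + b + c).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def fst_significance(
    geno: GenotypeMatrix,
    meta: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    n_perm: int = 10_000,
    seed: int = 0,
    loci=None,
    chunk: int = 500,
) -> float:
    """Permutation p-value for theta > 0 (samples shuffled between the pair).

    Add-one rule: p = (#{theta_perm >= theta_obs} + 1) / (n_perm + 1).
    """
    loci = list(loci) if loci is not None else geno.loci
    ids_a = [s for s in meta.index[meta["population"] == pop_a] if s in geno.df.index]
    ids_b = [s for s in meta.index[meta["population"] == pop_b] if s in geno.df.index]
    x = geno.minor_counts().loc[ids_a + ids_b, loci].to_numpy(dtype=float)
    na = len(ids_a)
    n = x.shape[0]
    theta_obs = _fast_biallelic_theta(x[None, :na, :], x[None, na:, :])[0]
    if not np.isfinite(theta_obs):
        raise FstUndefinedError("theta undefined; cannot test significance")
    rng = np.random.default_rng(seed)
    base = np.arange(n)
    count = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = rng.permuted(np.broadcast_to(base, (b, n)), axis=1)
        xp = x[idx]
        th = _fast_biallelic_theta(xp[:, :na, :], xp[:, na:, :])
        count += int(np.sum(th >= theta_obs - 1e-12))
        done += b
    return (count + 1) / (n_perm + 1)


@dataclass
class FstPair:
    pop_a: str
    pop_b: str
    theta: float
    standardized: float | None
    p: float | None
    n_loci: int


def fst_matrix(
    geno: GenotypeMatrix,
    meta: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    loci=None,
) -> list[FstPair]:
    """All pairwise theta / standardized theta / permutation p."""
    loci = list(loci) if loci is not None else geno.loci
    pops = sorted(meta["population"].unique())
    ss = np.random.SeedSequence(seed)
    pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(pairs))]
    out = []
    for (a, b), sd in zip(pairs, seeds):
        theta = pairwise_fst(geno, meta, a, b, loci=loci)
        try:
            std = standardized_fst(geno, meta, a, b, loci=loci)
        except FstUndefinedError:
            std = None
        p = fst_significance(geno, meta, a, b, n_perm=n_perm, seed=sd, loci=loci) if n_perm else None
        out.append(FstPair(a, b, theta, std, p, len(loci)))
    return out


def fst_frame(pairs: list[FstPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pop_a": p.pop_a,
                "pop_b": p.pop_b,
                "theta": p.theta,
                "standardized_theta": np.nan if p.standardized is None else p.standardized,
                "p": np.nan if p.p is None else p.p,
                "n_loci": p.n_loci,
            }
            for p in pairs
        ]
    )
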