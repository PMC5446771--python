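"""Per-population SNP quality control.

Each locus is screened within every population for Hardy–Weinberg
disequilibrium (exact conditional test, Benjamini–Hochberg adjusted across
loci within the population) and for low minor-allele frequency. A locus
failing either screen in two or more populations is dropped outright; a locus
failing in exactly one population is kept but that population's calls are
masked to missing; otherwise the locus is retained untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import MISSING_CALL, DataError, GenotypeMatrix


class GenotypeCounts(NamedTuple):
    hom_major: int
    het: int
    hom_minor: int
    missing: int


class UndefinedMAFError(DataError):
    """MAF requested for an all-missing genotype column."""


def genotype_counts(calls, major: str | None = None, minor: str | None = None) -> GenotypeCounts:
    """Tally genotype classes in a column of unordered allele-pair calls.

    Major/minor labels are inferred from the column when not supplied
    (ties broken alphabetically). Calls are order-insensitive: "CA" and
    "AC" are the same heterozygote.
    """
    calls = [c for c in calls]
    if major is None or minor is None:
        tally: dict[str, int] = {}
        for call in calls:
            if call == MISSING_CALL:
                continue
            for a in call:
                tally[a] = tally.get(a, 0) + 1
        if len(tally) > 2:
            raise DataError(f">2 distinct alleles observed: {sorted(tally)}")
        ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        if major is None:
            major = ranked[0][0] if ranked else "?"
        if minor is None:
            minor = ranked[1][0] if len(ranked) > 1 else None
    n_mm = n_het = n_nn = n_miss = 0
    for call in calls:
        if call == MISSING_CALL:
            n_miss += 1
            continue
        k = call.count(minor) if minor is not None else 0
        if k == 0:
            n_mm += 1
        elif k == 1:
            n_het += 1
        else:
            n_nn += 1
    return GenotypeCounts(n_mm, n_het, n_nn, n_miss)


def maf(counts: GenotypeCounts) -> float:
    """Folded minor-allele frequency from a genotype-count quadruple."""
    n = counts.hom_major + counts.het + counts.hom_minor
    if n == 0:
        raise UndefinedMAFError("all calls missing; MAF undefined")
    f = (counts.het + 2 * counts.hom_minor) / (2 * n)
    return min(f, 1.0 - f)


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional test for Hardy–Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one (mid-p
    off). Monomorphic columns return 1.
    """
    n = n_hom_major + n_het + n_hom_minor
    n_minor = n_het + 2 * n_hom_minor
    n_minor = min(n_minor, 2 * n - n_minor)
    if n == 0 or n_minor == 0:
        return 1.0
    lgam = math.lgamma

    def logprob(h: int) -> float:
        # P(het = h | n, n_minor) = n! 2^h / (nmm! h! nMM!) * nminor! nmajor! / (2n)!
        rare_hom = (n_minor - h) // 2
        common_hom = n - h - rare_hom
        return (
            lgam(n + 1)
            - lgam(rare_hom + 1)
            - lgam(h + 1)
            - lgam(common_hom + 1)
            + h * math.log(2.0)
            + lgam(n_minor + 1)
            + lgam(2 * n - n_minor + 1)
            - lgam(2 * n + 1)
        )

    hets = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    logs = np.array([logprob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = list(hets).index(n_het)
    p = probs[probs <= probs[obs] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_chi2_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """1-df chi-square goodness-of-fit alternative to the exact test."""
    from scipy.stats import chi2

    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    p_minor = (n_het + 2 * n_hom_minor) / (2 * n)
    if p_minor in (0.0, 1.0):
        return 1.0
    q = 1.0 - p_minor
    exp = np.array([q * q * n, 2 * p_minor * q * n, p_minor * p_minor * n])
    obs = np.array([n_hom_major, n_het, n_hom_minor])
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, 1))


def hwe_test(counts: GenotypeCounts, method: str = "exact") -> float:
    if method == "exact":
        return hwe_exact_test(counts.hom_major, counts.het, counts.hom_minor)
    if method == "chi2":
        return hwe_chi2_test(counts.hom_major, counts.het, counts.hom_minor)
    raise ValueError(f"unknown HWE method {method!r}")


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PopulationQC:
    counts: GenotypeCounts
    maf: float | None
    hwe_p: float
    hwe_p_adj: float = np.nan
    fail: bool = False


@dataclass
class LocusQCRecord:
    locus: str
    populations: dict[str, PopulationQC] = field(default_factory=dict)
    verdict: str = "retain"  # retain | mask | drop
    masked_populations: list[str] = field(default_factory=list)

    @property
    def failing_populations(self) -> list[str]:
        return [p for p, q in self.populations.items() if q.fail]


def apply_qc(
    geno: GenotypeMatrix,
    meta: pd.DataFrame,
    hwe_alpha: float = 0.05,
    maf_min: float = 0.05,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, list[LocusQCRecord]]:
    """Run the two-tier SNP-removal / population-masking rule.

    Per population and locus, failure = (BH-adjusted HWE p < hwe_alpha) OR
    (MAF < maf_min). All-missing or monomorphic population columns count as
    MAF failures (no usable information). FDR adjustment is applied per
    population across loci.
    """
    pops = sorted(meta["population"].unique())
    pop_samples = {p: meta.index[meta["population"] == p] for p in pops}
    for p in pops:
        if len(pop_samples[p]) == 0:
            raise DataError(f"population {p!r} has zero samples")

    records = {locus: LocusQCRecord(locus=locus) for locus in geno.loci}
    for pop in pops:
        sub = geno.df.loc[geno.df.index.intersection(pop_samples[pop])]
        raw_p = []
        for locus in geno.loci:
            al = geno.alleles(locus)
            counts = genotype_counts(sub[locus], major=al.major, minor=al.minor)
            try:
                f = maf(counts)
            except UndefinedMAFError:
                f = None
            pv = hwe_test(counts, method=hwe_method)
            records[locus].populations[pop] = PopulationQC(counts, f, pv)
            raw_p.append(pv)
        adj = fdr_adjust(raw_p)
        for locus, a in zip(geno.loci, adj):
            q = records[locus].populations[pop]
            q.hwe_p_adj = float(a)
            q.fail = (q.hwe_p_adj < hwe_alpha) or (q.maf is None) or (q.maf < maf_min)

    filtered = geno
    dropped = []
    for locus in geno.loci:
        rec = records[locus]
        failing = rec.failing_populations
        if len(failing) >= 2:
            rec.verdict = "drop"
            dropped.append(locus)
        elif len(failing) == 1:
            rec.verdict = "mask"
            rec.masked_populations = failing
            filtered = filtered.mask(locus, pop_samples[failing[0]])
        else:
            rec.verdict = "retain"
    if dropped:
        filtered = filtered.drop_loci(dropped)
    return filtered, [records[locus] for locus in geno.loci]


def qc_report_frame(records: list[LocusQCRecord]) -> pd.DataFrame:
    """Flatten QC records into the per-locus report table."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"locus": rec.locus, "verdict": rec.verdict,
                                  "masked_populations": ";".join(rec.masked_populations)}
        for pop, q in rec.populations.items():
            row[f"maf_{pop}"] = np.nan if q.maf is None else q.maf
            row[f"hwe_p_{pop}"] = q.hwe_p
            row[f"hwe_p_adj_{pop}"] = q.hwe_p_adj
            row[f"fail_{pop}"] = q.fail
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus")
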