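"""Directed permutation test for environment-consistent allele-frequency shifts.

Populations are organised into two fragmented-environment groups and two
continuous-environment groups. For each locus the statistic is the 4-vector
of group MAF differences (f1-c1, f1-c2, f2-c1, f2-c2), where frequencies are
allele-count proportions of the *globally* designated minor allele (not
refolded per group, so signs are coherent). Only loci whose four differences
strictly share a sign are tested: sample group labels are permuted uniformly
(preserving group sizes) and a permutation counts as extreme when every
element of its difference vector, signed in the observed direction, reaches
the corresponding observed element. The nominal p uses the add-one rule
(count + 1) / (n_perm + 1); family-wise control is Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataError, GenotypeMatrix

_EPS = 1e-12


class GroupingError(DataError):
    """Population-to-group assignment cannot be inferred."""


def default_groups(meta: pd.DataFrame) -> tuple[tuple[tuple[str, ...], ...], tuple[tuple[str, ...], ...]]:
    """Build the 2+2 group structure from the environment column.

    Requires exactly two fragmented and two continuous groups. The five
    study populations are special-cased: GO and OL are pooled into a single
    continuous group alongside SA.
    """
    frag = sorted(meta.loc[meta["environment"] == "fragmented", "population"].unique())
    cont = sorted(meta.loc[meta["environment"] == "continuous", "population"].unique())
    if len(frag) != 2:
        raise GroupingError(f"need exactly 2 fragmented populations, got {frag}")
    if len(cont) == 2:
        cont_groups = ((cont[0],), (cont[1],))
    elif set(cont) == {"GO", "OL", "SA"}:
        cont_groups = (("GO", "OL"), ("SA",))
    else:
        raise GroupingError(
            f"cannot infer 2 continuous groups from {cont}; pass groups explicitly"
        )
    return ((frag[0],), (frag[1],)), cont_groups


@dataclass
class EnvDiffResult:
    locus: str
    freqs: tuple[float, float, float, float]  # f1, f2 (fragmented), c1, c2 (continuous)
    differences: tuple[float, float, float, float]
    consistent: bool
    direction: int  # +1 fragmented higher, -1 lower, 0 inconsistent
    nominal_p: float | None = None
    n_perm: int = 0
    bonferroni_significant: bool | None = None
    note: str = ""
    masked: bool = False


def maf_mle(geno: GenotypeMatrix, meta: pd.DataFrame, population: str, locus: str) -> float:
    """Allele-count proportion of the global minor allele in one population.

    Maximum-likelihood estimate under binomial sampling of 2n alleles; may
    exceed 0.5 because the minor designation is global, keeping differences
    between populations signed coherently.
    """
    ids = meta.index[meta["population"] == population]
    counts = geno.minor_counts().loc[geno.df.index.intersection(ids), locus]
    n = counts.notna().sum()
    if n == 0:
        raise DataError(f"no non-missing calls for {population} at {locus}")
    return float(counts.sum() / (2 * n))


def directed_statistic(p11: float, p12: float, p21: float, p22: float):
    """Difference vector, consistency flag, and direction.

    Consistent iff all four differences are strictly positive or strictly
    negative; zeros break consistency.
    """
    diffs = (p11 - p21, p11 - p22, p12 - p21, p12 - p22)
    if all(d > 0 for d in diffs):
        return diffs, True, +1
    if all(d < 0 for d in diffs):
        return diffs, True, -1
    return diffs, False, 0


def _group_freqs(counts_sum, valid_sum):
    with np.errstate(invalid="ignore", divide="ignore"):
        return counts_sum / (2.0 * valid_sum)


def directed_permutation_test(
    geno: GenotypeMatrix,
    meta: pd.DataFrame,
    locus: str,
    n_perm: int = 1_000_000,
    seed: int = 0,
    groups=None,
    statistic: str = "elementwise",
    chunk: int = 20_000,
) -> EnvDiffResult:
    """Permutation p-value for one locus' environment-directed MAF shift.

    ``statistic="elementwise"`` requires every signed difference of a
    permutation to reach the observed one; ``"min"`` compares only the
    smallest signed difference (sensitivity variant).
    """
    if statistic not in ("elementwise", "min"):
        raise ValueError("statistic must be 'elementwise' or 'min'")
    frag_groups, cont_groups = groups if groups is not None else default_groups(meta)
    group_pops = list(frag_groups) + list(cont_groups)

    counts_all = geno.minor_counts()[locus]
    sample_ids: list[str] = []
    sizes: list[int] = []
    for pops in group_pops:
        ids = [s for s in meta.index[meta["population"].isin(pops)] if s in counts_all.index]
        sample_ids.extend(ids)
        sizes.append(len(ids))
    x = counts_all.loc[sample_ids].to_numpy(dtype=float)
    valid = np.isfinite(x)
    xz = np.where(valid, x, 0.0)
    bounds = np.concatenate([[0], np.cumsum(sizes)])

    obs_f = []
    for g in range(4):
        sl = slice(bounds[g], bounds[g + 1])
        nv = valid[sl].sum()
        if nv == 0:
            return EnvDiffResult(locus, (np.nan,) * 4, (np.nan,) * 4, False, 0,
                                 note=f"group {g} all-missing; locus excluded")
        obs_f.append(xz[sl].sum() / (2.0 * nv))
    f1, f2, c1, c2 = obs_f
    diffs, consistent, direction = directed_statistic(f1, f2, c1, c2)
    res = EnvDiffResult(locus, (f1, f2, c1, c2), diffs, consistent, direction)
    if not consistent:
        res.note = "inconsistent difference signs; no test"
        return res

    s = float(direction)
    obs_signed = np.array([s * d for d in diffs])
    obs_min = obs_signed.min()
    rng = np.random.default_rng(seed)
    n = x.size
    count = 0
    done = 0
    base = np.arange(n)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = rng.permuted(np.broadcast_to(base, (b, n)), axis=1)
        xp = xz[idx]
        vp = valid[idx]
        freqs = []
        for g in range(4):
            sl = slice(bounds[g], bounds[g + 1])
            freqs.append(_group_freqs(xp[:, sl].sum(axis=1), vp[:, sl].sum(axis=1)))
        pf1, pf2, pc1, pc2 = freqs
        d = np.stack([pf1 - pc1, pf1 - pc2, pf2 - pc1, pf2 - pc2]) * s
        if statistic == "elementwise":
            hits = np.all(d >= obs_signed[:, None] - _EPS, axis=0)
        else:
            hits = np.nanmin(d, axis=0) >= obs_min - _EPS
        count += int(np.nansum(hits))
        done += b
    res.nominal_p = (count + 1) / (n_perm + 1)
    res.n_perm = n_perm
    return res


def scan_loci(
    geno: GenotypeMatrix,
    meta: pd.DataFrame,
    n_perm: int = 1_000_000,
    seed: int = 0,
    groups=None,
    family_alpha: float = 0.01,
    family_size: int | None = None,
    loci=None,
) -> list[EnvDiffResult]:
    """Directed permutation test over loci with Bonferroni verdicts.

    The Bonferroni family size defaults to the number of loci scanned (all
    QC-retained loci), not only the sign-consistent ones.
    """
    loci = list(loci) if loci is not None else geno.loci
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(loci))]
    results = []
    for locus, sd in zip(loci, seeds):
        results.append(
            directed_permutation_test(geno, meta, locus, n_perm=n_perm, seed=sd, groups=groups)
        )
    return bonferroni_verdicts(results, family_alpha=family_alpha,
                               family_size=family_size or len(loci))


def bonferroni_verdicts(
    results: list[EnvDiffResult], family_alpha: float = 0.01, family_size: int | None = None
) -> list[EnvDiffResult]:
    """Flag results significant at the Bonferroni-corrected level (strict <)."""
    tested = [r for r in results if r.nominal_p is not None]
    m = family_size if family_size is not None else len(results)
    if m < len(tested):
        raise ValueError("family_size smaller than the number of tested loci")
    thr = family_alpha / m
    for r in results:
        r.bonferroni_significant = (r.nominal_p < thr) if r.nominal_p is not None else False
    return results


def results_frame(results: list[EnvDiffResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "locus": r.locus,
            "maf_frag1": r.freqs[0], "maf_frag2": r.freqs[1],
            "maf_cont1": r.freqs[2], "maf_cont2": r.freqs[3],
            "consistent": r.consistent, "direction": r.direction,
            "nominal_p": np.nan if r.nominal_p is None else r.nominal_p,
            "n_perm": r.n_perm,
            "bonferroni_significant": bool(r.bonferroni_significant),
            "note": r.note,
        })
    return pd.DataFrame(rows).set_index("locus")
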