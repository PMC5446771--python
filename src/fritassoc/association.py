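"""SNP-trait association scans with linear mixed models.

Every QC-retained locus is tested against every retained principal-component
score under four genotype encodings (additive, dominant, recessive,
over-dominant). The model has sex (development components only), environment
type, genotype and environment-by-genotype fixed effects, with a random
intercept for population nested in environment; the interaction is dropped
when non-significant (minimal adequate model). Raw genotype p-values are
Benjamini–Hochberg corrected across the whole fitted grid. The pilot variant
adds a family random intercept nested in population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .data import DataError, GenotypeMatrix
from .qc import fdr_adjust

SCHEMES = ("additive", "dominant", "recessive", "overdominant")


def encode_genotype(minor_counts, scheme: str):
    """Numeric genotype codes from minor-allele counts (NaN passes through).

    additive: 0/1/2 copies; dominant: carrier of >=1 minor allele;
    recessive: minor homozygote; overdominant: heterozygote indicator.
    """
    if scheme not in SCHEMES:
        raise DataError(f"unknown inheritance scheme {scheme!r}")
    x = np.asarray(minor_counts, dtype=float)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    if scheme == "additive":
        out[ok] = x[ok]
    elif scheme == "dominant":
        out[ok] = (x[ok] >= 1).astype(float)
    elif scheme == "recessive":
        out[ok] = (x[ok] == 2).astype(float)
    else:
        out[ok] = (x[ok] == 1).astype(float)
    return out


@dataclass
class Term:
    estimate: float
    se: float
    p: float


@dataclass
class FitSummary:
    terms: dict[str, Term]
    n: int
    converged: bool
    boundary: bool  # population variance at the zero boundary
    population_var: float
    family_var: float | None = None
    interaction_removed: bool | None = None
    interaction_p: float | None = None
    method: str = "reml-wald"
    error: str | None = None
    _frame: pd.DataFrame | None = field(default=None, repr=False)
    _spec: dict = field(default_factory=dict, repr=False)

    @property
    def ok(self) -> bool:
        return self.error is None


def _assemble(response: pd.Series, meta: pd.DataFrame, genotype_code: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame({"score": response})
    df = df.join(meta[["population", "environment", "sex", "family"]], how="inner")
    df["genotype"] = genotype_code.reindex(df.index)
    df["env"] = (df["environment"] == "fragmented").astype(float)
    df["sexf"] = (df["sex"] == "female").astype(float)
    df = df.dropna(subset=["score", "genotype"])
    return df


def _fit(df: pd.DataFrame, include_sex: bool, include_interaction: bool,
         family_re: bool, reml: bool = True) -> FitSummary:
    rhs = ["env", "genotype"]
    if include_sex:
        rhs.insert(0, "sexf")
    if include_interaction:
        df = df.assign(env_x_genotype=df["env"] * df["genotype"])
        rhs.append("env_x_genotype")
    formula = "score ~ " + " + ".join(rhs)
    if df["score"].std(ddof=0) == 0:
        raise DataError("response has zero variance")
    if df["population"].nunique() < 2:
        raise DataError("need >= 2 populations")
    vc = {"family": "0 + C(family)"} if family_re else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["population"],
                            re_formula="1", vc_formula=vc)
        fit = None
        last_err: Exception | None = None
        # gradient-based first; derivative-free fallbacks ride out boundary
        # variance estimates that make the REML score singular. Variance-
        # component fits additionally cross-check optimizers by restricted
        # likelihood, since lbfgs can report convergence at a poor optimum.
        def _trustworthy(res) -> bool:
            if not (res.converged and np.isfinite(res.llf)):
                return False
            # a fully collapsed random-effect covariance is the signature of
            # lbfgs stalling at a spurious optimum with corrupt fixed effects
            return not (res.cov_re.size and float(res.cov_re.iloc[0, 0]) < 1e-12)

        candidates = []
        for method in ("lbfgs", "powell", "nm"):
            try:
                res = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_err = exc
                continue
            candidates.append(res)
            if not family_re and _trustworthy(res):
                break
        if candidates:
            sound = [r for r in candidates if r.converged and np.isfinite(r.llf)]
            pool = sound or candidates
            fit = max(pool, key=lambda r: (r.llf if np.isfinite(r.llf) else -np.inf))
        if fit is None:
            return FitSummary(terms={}, n=len(df), converged=False, boundary=False,
                              population_var=np.nan, error=str(last_err),
                              _frame=df, _spec=dict(include_sex=include_sex,
                                                    include_interaction=include_interaction,
                                                    family_re=family_re, reml=reml))
    terms = {}
    for name in fit.params.index:
        if name == "Group Var" or name.endswith(" Var"):
            continue
        terms[name] = Term(float(fit.params[name]), float(fit.bse[name]),
                           float(fit.pvalues[name]))
    pop_var = float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0
    fam_var = None
    if family_re and fit.vcomp.size:
        fam_var = float(fit.vcomp[0])
    return FitSummary(
        terms=terms, n=len(df), converged=bool(fit.converged),
        boundary=pop_var < 1e-6, population_var=pop_var, family_var=fam_var,
        _frame=df,
        _spec=dict(include_sex=include_sex, include_interaction=include_interaction,
                   family_re=family_re, reml=reml),
    )


def fit_mixed_model(
    response: pd.Series,
    meta: pd.DataFrame,
    genotype_code: pd.Series,
    include_sex: bool = True,
    include_interaction: bool = True,
    family_re: bool = False,
    reml: bool = True,
) -> FitSummary:
    """Fit one mixed model: fixed sex/environment/genotype(/interaction),
    random intercept for population (plus family when ``family_re``)."""
    df = _assemble(response, meta, genotype_code)
    if df["genotype"].nunique() < 2:
        raise DataError("genotype column is constant; nothing to test")
    return _fit(df, include_sex, include_interaction, family_re, reml)


def simplify_model(fit: FitSummary, alpha: float = 0.05) -> FitSummary:
    """Drop a non-significant environment-by-genotype interaction and refit.

    If the interaction's Wald p >= alpha the model is refit without it and
    the reduced fit is returned (decision recorded on the result); otherwise
    the full model is kept.
    """
    if not fit.ok:
        return fit
    if "env_x_genotype" not in fit.terms:
        raise DataError("initial fit did not include the interaction")
    p_int = fit.terms["env_x_genotype"].p
    if p_int < alpha:
        fit.interaction_removed = False
        fit.interaction_p = p_int
        return fit
    reduced = _fit(fit._frame, fit._spec["include_sex"], False,
                   fit._spec["family_re"], fit._spec["reml"])
    reduced.interaction_removed = True
    reduced.interaction_p = p_int
    return reduced


def pilot_models(
    trait: pd.Series, genotype_code: pd.Series, meta: pd.DataFrame,
    include_sex: bool = True,
) -> FitSummary:
    """Single-SNP pilot model on a raw trait with family and population
    random intercepts (no interaction term)."""
    df = _assemble(trait, meta, genotype_code)
    if df["genotype"].nunique() < 2:
        raise DataError("genotype column is constant; nothing to test")
    return _fit(df, include_sex, False, family_re=True)


@dataclass
class ScanRecord:
    locus: str
    battery: str
    component: str
    scheme: str
    estimate: float
    p: float
    p_adj: float
    interaction_removed: bool | None
    interaction_p: float | None
    n: int
    boundary: bool
    converged: bool


def association_scan(
    pc_scores: dict[str, pd.DataFrame] | pd.DataFrame,
    geno: GenotypeMatrix,
    meta: pd.DataFrame,
    schemes=SCHEMES,
    interaction_alpha: float = 0.05,
    sex_batteries: tuple[str, ...] = ("development",),
) -> tuple[pd.DataFrame, dict]:
    """Fit the full locus x component x scheme grid and FDR-correct it.

    ``pc_scores``: long-format frame (sample_id, battery, component, score)
    or mapping battery -> wide score frame. Returns the result table plus a
    log dict (tests fitted, skips with reasons, FDR family size).
    """
    if isinstance(pc_scores, pd.DataFrame):
        long = pc_scores
        responses = {
            (b, c): g.set_index("sample_id")["score"]
            for (b, c), g in long.groupby(["battery", "component"], sort=True)
        }
    else:
        responses = {
            (b, comp): frame[comp]
            for b, frame in pc_scores.items()
            for comp in frame.columns
        }
    minor = geno.minor_counts()
    records: list[ScanRecord] = []
    skips: list[dict] = []
    for (battery, component), response in sorted(responses.items()):
        include_sex = battery in sex_batteries
        for locus in geno.loci:
            counts = minor[locus]
            for scheme in schemes:
                code = pd.Series(encode_genotype(counts, scheme), index=counts.index)
                aligned = code.reindex(response.index).dropna()
                if aligned.nunique() < 2:
                    skips.append({"locus": locus, "battery": battery,
                                  "component": component, "scheme": scheme,
                                  "reason": "constant genotype encoding"})
                    continue
                fit = fit_mixed_model(response, meta, code,
                                      include_sex=include_sex,
                                      include_interaction=True)
                fit = simplify_model(fit, alpha=interaction_alpha)
                if not fit.ok or "genotype" not in fit.terms:
                    skips.append({"locus": locus, "battery": battery,
                                  "component": component, "scheme": scheme,
                                  "reason": f"fit failed: {fit.error}"})
                    continue
                g = fit.terms["genotype"]
                if not np.isfinite(g.p):
                    skips.append({"locus": locus, "battery": battery,
                                  "component": component, "scheme": scheme,
                                  "reason": "singular fit: non-finite genotype p"})
                    continue
                records.append(ScanRecord(
                    locus=locus, battery=battery, component=component,
                    scheme=scheme, estimate=g.estimate, p=g.p, p_adj=np.nan,
                    interaction_removed=fit.interaction_removed,
                    interaction_p=fit.interaction_p, n=fit.n,
                    boundary=fit.boundary, converged=fit.converged,
                ))
    if not records:
        raise DataError("empty association grid: nothing was fitted")
    table = pd.DataFrame([r.__dict__ for r in records])
    table["p_adj"] = fdr_adjust(table["p"].to_numpy())
    log = {
        "tests_fitted": len(records),
        "tests_skipped": len(skips),
        "skips": skips,
        "fdr_family_size": len(records),
    }
    return table, log
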