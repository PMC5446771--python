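"""Life-history trait reduction: per-battery PCA with Kaiser-style retention.

The 21-trait battery is split into three groups (development traits of both
sexes, male adult traits, female adult traits). Proportion-valued traits are
arcsine-square-root transformed, each battery is restricted to complete
cases, and a correlation-matrix PCA reduces it to the components with
eigenvalue > 1 and proportion of variance > 0.1. Retained component scores
are screened for normality with Shapiro–Wilk tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError

BATTERY_NAMES = ("development", "male_adult", "female_adult")


def arcsine_transform(p):
    """arcsin(sqrt(p)) for proportions in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((arr[np.isfinite(arr)] < 0) | (arr[np.isfinite(arr)] > 1)):
            raise DataError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    if np.isscalar(p):
        return float(out)
    return out


@dataclass
class TraitBattery:
    """One trait group, transformed and restricted to complete cases."""

    name: str
    data: pd.DataFrame  # complete cases only, proportions already transformed
    proportion_traits: list[str] = field(default_factory=list)

    @classmethod
    def build(cls, traits: pd.DataFrame, name: str, columns: list[str],
              proportion_traits: list[str] | None = None) -> "TraitBattery":
        proportion_traits = proportion_traits or []
        missing = [c for c in columns if c not in traits.columns]
        if missing:
            raise DataError(f"battery {name!r}: unknown traits {missing}")
        sub = traits[columns].copy()
        for c in proportion_traits:
            sub[c] = arcsine_transform(sub[c].to_numpy())
        sub = sub.dropna(axis=0, how="any")
        return cls(name=name, data=sub, proportion_traits=list(proportion_traits))


def correlation_screen(battery: TraitBattery, n_tests: int | None = None, alpha: float = 0.05):
    """Pairwise Pearson correlations with Bonferroni significance flags.

    Returns (r matrix, p matrix, significant-flag matrix). Zero-variance
    traits yield NaN entries. ``n_tests`` defaults to the number of distinct
    pairs.
    """
    cols = list(battery.data.columns)
    k = len(cols)
    if n_tests is None:
        n_tests = k * (k - 1) // 2
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            x = battery.data[cols[i]]
            y = battery.data[cols[j]]
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0 or len(x) < 3:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    threshold = alpha / n_tests
    sig = p < threshold
    np.fill_diagonal(sig.values, False)
    return r, p, sig


@dataclass
class PCResult:
    battery: str
    eigenvalues: np.ndarray
    proportions: np.ndarray
    loadings: pd.DataFrame  # traits x components
    scores: pd.DataFrame  # samples x components
    retained: np.ndarray  # bool per component
    shapiro_p: dict[str, float] = field(default_factory=dict)

    @property
    def retained_components(self) -> list[str]:
        return [c for c, keep in zip(self.scores.columns, self.retained) if keep]


def retention_rule(eigenvalues, proportions) -> np.ndarray:
    """Keep a component iff eigenvalue > 1 AND proportion of variance > 0.1."""
    ev = np.asarray(eigenvalues, dtype=float)
    pr = np.asarray(proportions, dtype=float)
    return (ev > 1.0) & (pr > 0.1)


def run_pca(battery: TraitBattery) -> PCResult:
    """Correlation-matrix PCA of a standardized trait battery.

    Eigen-decomposition of the Pearson correlation matrix; scores are the
    standardized data projected on the eigenvectors (centered, variance equal
    to the eigenvalue). Each component's sign is fixed by making its
    largest-magnitude loading positive.
    """
    X = battery.data.to_numpy(dtype=float)
    n, k = X.shape
    if n < k:
        raise DataError(
            f"battery {battery.name!r}: {n} complete cases < {k} traits"
        )
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        zero = [c for c, s in zip(battery.data.columns, sd) if s == 0]
        raise DataError(f"zero-variance traits in PCA: {zero}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(k):
        i_max = np.argmax(np.abs(evecs[:, j]))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    comp_names = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(evecs, index=battery.data.columns, columns=comp_names)
    scores = pd.DataFrame(Z @ evecs, index=battery.data.index, columns=comp_names)
    proportions = evals / evals.sum()
    return PCResult(
        battery=battery.name,
        eigenvalues=evals,
        proportions=proportions,
        loadings=loadings,
        scores=scores,
        retained=retention_rule(evals, proportions),
    )


def normality_check(result: PCResult, alpha: float = 0.01) -> dict[str, tuple[float, bool]]:
    """Shapiro–Wilk p per retained component; flag = significant departure.

    Also records the p-values on the result object.
    """
    out = {}
    for comp in result.retained_components:
        s = result.scores[comp].to_numpy()
        if len(s) < 3:
            raise DataError("Shapiro-Wilk needs >= 3 scores")
        if np.ptp(s) == 0:
            raise DataError(f"constant scores for {comp}; normality test undefined")
        p = float(stats.shapiro(s).pvalue)
        result.shapiro_p[comp] = p
        out[comp] = (p, p < alpha)
    return out


def reduce_batteries(
    traits: pd.DataFrame, battery_config: dict, shapiro_alpha: float = 0.01
) -> dict[str, PCResult]:
    """Run the full three-battery reduction from a battery configuration.

    ``battery_config`` maps battery name -> {"traits": [...],
    "proportions": [...]} (proportions optional).
    """
    results = {}
    for name, spec in battery_config.items():
        battery = TraitBattery.build(
            traits, name, spec["traits"], spec.get("proportions", [])
        )
        res = run_pca(battery)
        normality_check(res, alpha=shapiro_alpha)
        results[name] = res
    return results


def scores_frame(results: dict[str, PCResult], retained_only: bool = True) -> pd.DataFrame:
    """Long-format score table (sample_id, battery, component, score)."""
    rows = []
    for name, res in results.items():
        comps = res.retained_components if retained_only else list(res.scores.columns)
        for comp in comps:
            for sid, val in res.scores[comp].items():
                rows.append({"sample_id": sid, "battery": name,
                             "component": comp, "score": val})
    return pd.DataFrame(rows)


def summary_frame(results: dict[str, PCResult]) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        for j, comp in enumerate(res.scores.columns):
            rows.append({
                "battery": name, "component": comp,
                "eigenvalue": res.eigenvalues[j],
                "proportion": res.proportions[j],
                "retained": bool(res.retained[j]),
                "shapiro_p": res.shapiro_p.get(comp, math.nan),
            })
    return pd.DataFrame(rows)
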