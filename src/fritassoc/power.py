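"""QTL-association power and required-sample-size calculations.

The setting is indirect association: a genotyped marker in linkage
disequilibrium (LD) with an unobserved causal variant that explains a given
fraction of trait variance. Power derives from the trait variance the marker
itself captures after LD attenuation.

Model
-----
Let ``r`` be the allele-frequency correlation between marker and causal
locus, computed from the LD coefficient (D' scale by default) and the two
allele frequencies: ``D = D' * Dmax``, ``r = D / sqrt(p_m q_m p_c q_c)``.
Under an additive causal architecture the marker's additive regressor
captures ``r^2`` of the QTL variance and the test has 1 df. Under the
dominant model the causal locus acts with complete dominance; its variance
splits into additive and dominance components (Va, Vd), the marker captures
``r^2 * Va + r^4 * Vd``, and the genotypic test has 2 df.

The test's noncentrality at sample size N is the likelihood-ratio form
``lambda = N * ln(1 / (1 - E))`` where E is the marker-explained variance
fraction; power comes from the noncentral chi-square distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import chi2, ncx2

MODELS = ("additive", "dominant")


class PowerError(ValueError):
    """Invalid power request or unreachable target."""


@dataclass(frozen=True)
class PowerRequest:
    """Inputs of one power / sample-size calculation.

    Parameters
    ----------
    maf_marker, maf_causal : frequency of the minor (increaser) allele at
        the genotyped marker and the causal locus, in (0, 0.5].
    ld : LD between marker and causal locus; D' scale unless
        ``ld_scale="r2"``.
    qtl_variance : fraction of trait variance explained by the causal locus.
    model : "additive" or "dominant" (complete dominance at the causal
        locus, 2-df genotypic test at the marker).
    alpha : type-I error of the marker test.
    target_power : power sought by :func:`required_n`.
    """

    maf_marker: float
    maf_causal: float
    ld: float
    qtl_variance: float
    model: str = "additive"
    alpha: float = 0.05
    target_power: float = 0.80
    ld_scale: str = "dprime"

    def __post_init__(self) -> None:
        for name in ("maf_marker", "maf_causal"):
            v = getattr(self, name)
            if not 0.0 < v <= 0.5:
                raise PowerError(f"{name} must be in (0, 0.5], got {v}")
        if not 0.0 <= self.ld <= 1.0:
            raise PowerError(f"ld must be in [0, 1], got {self.ld}")
        if not 0.0 < self.qtl_variance < 1.0:
            raise PowerError("qtl_variance must be in (0, 1)")
        if self.model not in MODELS:
            raise PowerError(f"model must be one of {MODELS}")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.target_power < 1.0:
            raise PowerError("alpha and target_power must be in (0, 1)")
        if self.ld_scale not in ("dprime", "r2"):
            raise PowerError("ld_scale must be 'dprime' or 'r2'")

    @property
    def test_df(self) -> int:
        return 1 if self.model == "additive" else 2


def _allele_r2(req: PowerRequest) -> float:
    """Squared allele-frequency correlation between marker and causal locus."""
    if req.ld_scale == "r2":
        return req.ld
    pm, pc = req.maf_marker, req.maf_causal
    qm, qc_ = 1.0 - pm, 1.0 - pc
    dmax = min(pm * qc_, qm * pc)
    if dmax == 0.0:
        raise PowerError("Dmax = 0: a locus is monomorphic")
    d = req.ld * dmax
    r = d / math.sqrt(pm * qm * pc * qc_)
    return r * r


def _dominance_partition(p: float) -> tuple[float, float]:
    """(additive, dominance) variance fractions of a completely dominant QTL.

    Genotypic values -a / +a / +a for 0/1/2 copies of the increaser allele at
    frequency *p*; returns Va and Vd as fractions of the QTL's total variance.
    """
    q = 1.0 - p
    va = 2.0 * p * q * (1.0 + (q - p)) ** 2
    vd = (2.0 * p * q) ** 2
    tot = va + vd
    return va / tot, vd / tot


def marker_variance_explained(req: PowerRequest) -> float:
    """Trait-variance fraction captured by the marker after LD attenuation."""
    r2 = _allele_r2(req)
    if req.model == "additive":
        return r2 * req.qtl_variance
    va_frac, vd_frac = _dominance_partition(req.maf_causal)
    return (r2 * va_frac + r2 * r2 * vd_frac) * req.qtl_variance


def power_at_n(req: PowerRequest, n: int | None = None) -> float:
    """Power of the marker test at sample size *n* (default: a required field).

    Noncentrality ``n * ln(1/(1 - E))``; noncentral chi-square with 1 df
    (additive) or 2 df (dominant genotypic test).
    """
    if n is None:
        raise PowerError("sample size n must be given")
    if n < 1:
        raise PowerError("n must be >= 1")
    e = marker_variance_explained(req)
    if e >= 1.0:
        raise PowerError("marker-explained variance fraction >= 1")
    if e == 0.0:
        return req.alpha
    lam = n * math.log(1.0 / (1.0 - e))
    crit = chi2.ppf(1.0 - req.alpha, req.test_df)
    return float(ncx2.sf(crit, req.test_df, lam))


def required_n(req: PowerRequest) -> int:
    """Smallest integer sample size reaching the requested power."""
    if req.target_power <= req.alpha:
        raise PowerError("target_power must exceed alpha")
    e = marker_variance_explained(req)
    if e <= 0.0:
        raise PowerError("marker explains no variance; power target unreachable")
    # continuous solution, then resolve the integer boundary exactly
    lam_unit = math.log(1.0 / (1.0 - e))
    crit = chi2.ppf(1.0 - req.alpha, req.test_df)
    lam_star = brentq(
        lambda lam: ncx2.sf(crit, req.test_df, lam) - req.target_power, 1e-9, 1e6
    )
    n = max(1, math.floor(lam_star / lam_unit))
    while power_at_n(req, n) < req.target_power:
        n += 1
    return n


def power_curve(req: PowerRequest, n_values) -> list[tuple[int, float]]:
    return [(int(n), power_at_n(req, int(n))) for n in n_values]
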