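"""Design-based regional density estimation across replicate arrays.

Given per-array counts n_j and effective sampling areas â_j (with
delta-method variances), the regional density over J independent replicate
arrays can be estimated either as the total count over the total area,

    D̂_region = Σ n_j / Σ â_j                       (area-weighted),

or as the unweighted mean of array-specific densities,

    D̂_region = (1/J) Σ n_j / â_j                   (mean of densities).

The area-weighted form gives more weight to arrays with higher detectability
and is biased when detection parameters differ among arrays, so the mean of
densities is the default.  Two variance estimators are provided, both of the
form D̂² [ var(n)/n² + Σ var(â_j)/Â² ] with Â = Σ â_j:

* Poisson: var(n) = n, appropriate when activity centres follow a
  homogeneous Poisson process across the region;
* empirical: var(n) = J/(J−1) Σ (n_j − n/J)², treating arrays as
  independent equal random samples and making no assumption about the
  spatial distribution of density.

Confidence intervals are lognormal:  (D/C, D·C) with
C = exp(z · sqrt(log(1 + var/D²))), the standard back-transformed form for
positive abundance estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core import density_per_100km2

__all__ = [
    "ArrayComponent",
    "RegionalEstimate",
    "components_from_fits",
    "dhat_region_eq2",
    "dhat_region_eq3",
    "var_n_empirical",
    "var_region_poisson",
    "var_region_empirical",
    "lognormal_ci",
    "regional_estimate",
]


@dataclass(frozen=True)
class ArrayComponent:
    """Per-array ingredients of the regional estimators."""

    array_id: str
    n: int
    a_hat: float  # km²
    var_a_hat: float  # km⁴

    @property
    def d_hat(self) -> float:
        """Array-local density per 100 km²."""
        return density_per_100km2(self.n, self.a_hat)


@dataclass(frozen=True)
class RegionalEstimate:
    """Regional density with Poisson and empirical variances and CIs."""

    J: int
    estimator: str  # "eq3_mean" or "eq2_pooled_area"
    D_region: float  # per 100 km²
    var_poisson: float
    var_empirical: float | None
    ci95_poisson: tuple[float, float]
    ci95_empirical: tuple[float, float] | None
    components: tuple[ArrayComponent, ...]
    note: str = ""

    @property
    def rse_poisson(self) -> float:
        return math.sqrt(self.var_poisson) / self.D_region

    @property
    def rse_empirical(self) -> float | None:
        if self.var_empirical is None:
            return None
        return math.sqrt(self.var_empirical) / self.D_region


def components_from_fits(fits) -> list[ArrayComponent]:
    """Extract per-array components from converged independent fits.

    Raises if any fit failed: the caller must drop failed arrays explicitly
    (reducing J) so that exclusions are a visible, logged decision.
    """
    comps = []
    for f in fits:
        if not f.converged:
            raise ValueError(
                f"cannot combine a failed fit ({f.message}); drop it explicitly"
            )
        for aid, a in f.a_by_array.items():
            comps.append(
                ArrayComponent(
                    array_id=aid, n=f.n, a_hat=a, var_a_hat=f.var_a_by_array[aid]
                )
            )
    return comps


def dhat_region_eq3(components) -> float:
    """Mean of array-specific densities, per 100 km²."""
    comps = list(components)
    if not comps:
        raise ValueError("need at least one component")
    return float(np.mean([c.d_hat for c in comps]))


def dhat_region_eq2(components) -> float:
    """Total count over total effective area, per 100 km².

    Weights arrays by â_j, so it is biased when detectability (hence â_j)
    varies among arrays; prefer :func:`dhat_region_eq3`.
    """
    comps = list(components)
    if not comps:
        raise ValueError("need at least one component")
    n = sum(c.n for c in comps)
    A = sum(c.a_hat for c in comps)
    return density_per_100km2(n, A)


def var_n_empirical(n_list) -> float:
    """Across-array empirical variance of the total count.

    ``J/(J−1) · Σ (n_j − n̄)²`` with n̄ = n/J; requires J ≥ 2.
    """
    n_arr = np.asarray(list(n_list), dtype=float)
    J = len(n_arr)
    if J < 2:
        raise ValueError("empirical variance requires at least 2 arrays")
    return float(J / (J - 1) * np.sum((n_arr - n_arr.mean()) ** 2))


def _var_sum_terms(components) -> tuple[float, float, float]:
    n = sum(c.n for c in components)
    A = sum(c.a_hat for c in components)
    var_A = sum(c.var_a_hat for c in components)
    return n, A, var_A


def var_region_poisson(D_region: float, components) -> float:
    """Variance assuming homogeneous Poisson density: var(n) = n."""
    comps = list(components)
    n, A, var_A = _var_sum_terms(comps)
    if n <= 0:
        raise ValueError("no animals detected")
    return D_region**2 * (n / n**2 + var_A / A**2)


def var_region_empirical(D_region: float, components) -> float:
    """Variance with the across-array empirical estimate of var(n)."""
    comps = list(components)
    n, A, var_A = _var_sum_terms(comps)
    if n <= 0:
        raise ValueError("no animals detected")
    vn = var_n_empirical([c.n for c in comps])
    return D_region**2 * (vn / n**2 + var_A / A**2)


def lognormal_ci(D: float, var: float, level: float = 0.95) -> tuple[float, float]:
    """Back-transformed lognormal confidence interval for a density.

    ``C = exp(z · sqrt(log(1 + var/D²)))`` and the interval is
    ``(D/C, D·C)``, multiplicatively symmetric about D.
    """
    if D <= 0:
        raise ValueError("lognormal CI requires a positive estimate")
    if var < 0:
        raise ValueError("variance must be non-negative")
    if var == 0:
        return (D, D)
    z = norm.ppf(0.5 + level / 2.0)
    C = math.exp(z * math.sqrt(math.log1p(var / D**2)))
    return (D / C, D * C)


def regional_estimate(
    components,
    estimator: str = "eq3_mean",
    level: float = 0.95,
) -> RegionalEstimate:
    """Full regional estimate with both variance estimators and CIs.

    The empirical variance is reported only when J ≥ 2.  The
    ``eq2_pooled_area`` estimator carries a bias caveat in ``note``.
    """
    comps = tuple(components)
    J = len(comps)
    if estimator == "eq3_mean":
        D = dhat_region_eq3(comps)
        note = ""
    elif estimator == "eq2_pooled_area":
        D = dhat_region_eq2(comps)
        note = (
            "area-weighted estimator: biased when detectability varies among arrays"
        )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    var_p = var_region_poisson(D, comps)
    var_e = var_region_empirical(D, comps) if J >= 2 else None
    return RegionalEstimate(
        J=J,
        estimator=estimator,
        D_region=D,
        var_poisson=var_p,
        var_empirical=var_e,
        ci95_poisson=lognormal_ci(D, var_p, level),
        ci95_empirical=lognormal_ci(D, var_e, level) if var_e is not None else None,
        components=comps,
        note=note,
    )
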