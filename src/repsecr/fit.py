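"""Conditional-likelihood fitting of half-normal SECR models.

For binary proximity-detector data the likelihood conditions on the number of
detected animals ``n``, so density drops out and only the detection
parameters θ = (g0, σ) are estimated.  The per-animal contribution is

    Pr(ω_i) = ∫ Pr(ω_i | x) dx / a(θ),

where the integral runs over the habitat mask and
``a(θ) = ∫ p·(x) dx`` is the effective sampling area — the spatial integral
of the probability of being detected at least once.  Density follows from
the Horvitz–Thompson-like estimator ``D̂ = n / â``, with variance

    var(D̂) = D̂² [ var(n)/n² + var(â)/â² ],   var(n) = n  (Poisson),

and var(â) by the delta method on the link scale (logit g0, log σ).

Because detection probabilities are constant over occasions, a capture
history enters the likelihood only through its per-detector detection
counts, which the implementation exploits for vectorisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .combine import lognormal_ci
from .core import (
    CaptureData,
    DetectionParams,
    DetectorArray,
    HabitatMask,
    build_mask,
    density_per_100km2,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "history_prob",
    "effective_area",
    "conditional_nll",
    "fit_array",
    "fit_pooled",
    "rpsv",
]

SHARINGS = ("independent", "pooled_constant", "pooled_additive", "pooled_interactive")

# Link-scale box: g0 in (1e-6, 1-1e-6), sigma in (1 m, 1e7 m).
_G0_LINK_BOUND = 13.815509
_LSIG_BOUNDS = (0.0, math.log(1e7))
_FD_STEP = 1e-4  # central-difference step on the link scale


@dataclass(frozen=True)
class ModelSpec:
    """Fitting options: parameter sharing across arrays and mask controls.

    ``sharing`` is one of ``independent`` (one array), ``pooled_constant``
    (one θ for all arrays), ``pooled_additive`` (common θ plus per-array
    additive offsets on the link scale), or ``pooled_interactive`` (a
    separate θ per array, jointly maximised).  ``buffer_m``/``cell_side_m``
    override the default data-driven mask (buffer 4σ, cell σ/2).
    """

    sharing: str = "independent"
    buffer_m: float | None = None
    cell_side_m: float | None = None
    min_n: int = 5
    min_spatial_recaptures: int = 1

    def __post_init__(self) -> None:
        if self.sharing not in SHARINGS:
            raise ValueError(f"unknown sharing {self.sharing!r}")


@dataclass(frozen=True)
class FitResult:
    """Detection-parameter MLEs with effective areas and local density.

    ``a_by_array`` maps array id to â_j in km²; ``a_total`` is Â = Σ â_j.
    ``D_local`` is 100·n/Â (animals per 100 km²) with its Poisson-model
    variance and lognormal 95% CI.  ``vcov_link`` is the covariance of all
    link-scale parameters (inverse finite-difference Hessian).
    """

    converged: bool
    message: str
    sharing: str
    n: int
    n_recaptures: int
    theta: dict[str, DetectionParams] = field(default_factory=dict)
    params_link: np.ndarray | None = None
    vcov_link: np.ndarray | None = None
    a_by_array: dict[str, float] = field(default_factory=dict)
    var_a_by_array: dict[str, float] = field(default_factory=dict)
    a_total: float = math.nan
    var_a_total: float = math.nan
    D_local: float = math.nan
    var_D_local: float = math.nan
    ci95: tuple[float, float] = (math.nan, math.nan)
    loglik: float = math.nan
    n_params: int = 0
    aicc: float = math.nan
    n_evaluations: int = 0
    masks: dict[str, HabitatMask] = field(default_factory=dict)

    @property
    def se_D(self) -> float:
        return math.sqrt(self.var_D_local)

    @property
    def rse_D(self) -> float:
        return self.se_D / self.D_local


def history_prob(x, omega_i: np.ndarray, array: DetectorArray, params: DetectionParams) -> float:
    """Probability of one capture history given activity centre ``x``.

    ``omega_i`` is the (S × K) binary matrix for one animal; the history
    must contain at least one detection (all-zero histories carry no
    conditional-likelihood term).
    """
    om = np.asarray(omega_i)
    if om.sum() == 0:
        raise ValueError("all-zero history has no conditional-likelihood term")
    if om.shape != (array.n_occasions, array.n_detectors):
        raise ValueError("omega_i must be (n_occasions, n_detectors)")
    x = np.asarray(x, dtype=float)
    d2 = np.sum((array.coords - x[None, :]) ** 2, axis=1)
    z = -d2 / (2.0 * params.sigma**2)
    logp = math.log(params.g0) + z  # stable even when p underflows
    log1mp = np.log1p(-params.g0 * np.exp(z))
    counts = om.sum(axis=0)  # detections per detector
    logpr = float(np.sum(counts * logp + (array.n_occasions - counts) * log1mp))
    return math.exp(logpr)


class _ArrayLikelihood:
    """Pre-computed distance geometry for one (array, mask) pair."""

    def __init__(self, array: DetectorArray, mask: HabitatMask, data: CaptureData | None):
        self.array = array
        self.mask = mask
        self.S = array.n_occasions
        diff = mask.cell_centers[:, None, :] - array.coords[None, :, :]
        self.d2 = np.sum(diff**2, axis=-1)  # (n_cells, K)
        self.counts = data.detector_counts().astype(float) if data is not None else None
        self.n = data.n if data is not None else 0
        self.log_cell = math.log(mask.cell_area)

    def _logp(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g0 = 1.0 / (1.0 + math.exp(-theta[0]))
        sigma = math.exp(theta[1])
        z = -self.d2 / (2.0 * sigma * sigma)
        logp = math.log(g0) + z
        log1mp = np.log1p(-g0 * np.exp(z))
        return logp, log1mp

    def area(self, theta: np.ndarray) -> float:
        """Effective sampling area a(θ) in km² by mask quadrature."""
        _, log1mp = self._logp(theta)
        pdot = -np.expm1(self.S * log1mp.sum(axis=1))
        return float(pdot.sum() * self.mask.cell_area)

    def nll(self, theta: np.ndarray) -> float:
        """Negative conditional log likelihood for this array's animals."""
        logp, log1mp = self._logp(theta)
        pdot = -np.expm1(self.S * log1mp.sum(axis=1))
        a = pdot.sum() * self.mask.cell_area
        if not (a > 0):
            return 1e10
        # log Pr(omega_i | x) for every animal x cell, via detection counts
        logpr = self.counts @ logp.T + (self.S - self.counts) @ log1mp.T
        log_int = logsumexp(logpr, axis=1) + self.log_cell
        val = self.n * math.log(a) - float(log_int.sum())
        return val if math.isfinite(val) else 1e10


def effective_area(
    params: DetectionParams, array: DetectorArray, mask: HabitatMask
) -> tuple[float, np.ndarray]:
    """Effective sampling area â (km²) and its link-scale gradient.

    The gradient (w.r.t. logit g0 and log σ) is computed by central finite
    differences and feeds the delta-method variance of â.
    """
    lik = _ArrayLikelihood(array, mask, None)
    theta = params.to_link()
    a = lik.area(theta)
    grad = np.empty(2)
    for i in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += _FD_STEP
        tm[i] -= _FD_STEP
        grad[i] = (lik.area(tp) - lik.area(tm)) / (2.0 * _FD_STEP)
    return a, grad


def conditional_nll(
    params_link: np.ndarray, data: CaptureData, array: DetectorArray, mask: HabitatMask
) -> float:
    """Negative log conditional likelihood at link-scale parameters."""
    params_link = np.asarray(params_link, dtype=float)
    if not np.all(np.isfinite(params_link)):
        raise ValueError("parameters must be finite")
    if data.n < 1:
        raise ValueError("conditional likelihood needs at least one animal")
    return _ArrayLikelihood(array, mask, data).nll(params_link)


def rpsv(data: CaptureData, array: DetectorArray) -> float | None:
    """Root pooled spatial variance of detection locations, metres.

    Pools squared deviations of each animal's detection coordinates about
    its own centroid; animals with a single detection contribute nothing.
    Returns None when no animal has ≥2 detections.  Under half-normal
    detection this is a rough data-driven guess at σ used only to seed the
    optimiser and size the mask.
    """
    xy = array.coords
    ss = 0.0
    df = 0
    for i in range(data.n):
        occ, det = np.nonzero(data.omega[i])
        if len(det) < 2:
            continue
        pts = xy[det]
        ss += float(np.sum((pts - pts.mean(axis=0)) ** 2))
        df += len(det) - 1
    if df == 0:
        return None
    return math.sqrt(ss / (2.0 * df))


def _sigma_start(data: CaptureData, array: DetectorArray) -> float:
    s = rpsv(data, array)
    if s is None or not math.isfinite(s) or s <= 0:
        s = array.spacing() / 2.0
    # keep the start well inside the array's resolvable scales
    return float(np.clip(s, array.spacing() / 4.0, 20.0 * array.spacing()))


def _default_mask(array: DetectorArray, sigma: float, spec: ModelSpec) -> HabitatMask:
    buffer_m = spec.buffer_m if spec.buffer_m is not None else 4.0 * sigma
    cell = (
        spec.cell_side_m
        if spec.cell_side_m is not None
        else min(sigma / 2.0, array.spacing() / 2.0)
    )
    return build_mask(array, buffer_m=buffer_m, cell_side_m=cell)


def _check_data(data: CaptureData, spec: ModelSpec) -> str | None:
    if data.n < spec.min_n:
        return f"insufficient data: n={data.n} < {spec.min_n}"
    if data.n_spatial_recaptures < spec.min_spatial_recaptures:
        return (
            f"insufficient data: {data.n_spatial_recaptures} spatial recaptures "
            f"< {spec.min_spatial_recaptures}"
        )
    return None


def _theta_bounds(n_params: int, sharing: str = "independent") -> list[tuple[float, float]]:
    """Link-scale box constraints for the joint parameter vector."""
    if sharing == "pooled_additive":
        base = [(-_G0_LINK_BOUND, _G0_LINK_BOUND), _LSIG_BOUNDS]
        return base + [(-20.0, 20.0)] * (n_params - 2)
    return [
        (-_G0_LINK_BOUND, _G0_LINK_BOUND) if i % 2 == 0 else _LSIG_BOUNDS
        for i in range(n_params)
    ]


def _minimize(fun, x0: np.ndarray, bounds: list | None = None) -> tuple:
    """Quasi-Newton minimisation with one perturbed restart on failure."""
    if bounds is None:
        bounds = _theta_bounds(len(x0))
    opts = dict(ftol=1e-12, gtol=1e-7, maxiter=500)
    res = minimize(fun, x0, method="L-BFGS-B", bounds=bounds, options=opts)
    nfev = res.nfev
    if not res.success:
        res2 = minimize(
            fun, x0 + 0.3, method="L-BFGS-B", bounds=bounds, options=opts
        )
        nfev += res2.nfev
        if res2.success or res2.fun < res.fun:
            res = res2
    at_bound = any(
        math.isclose(v, b[0], abs_tol=1e-6) or math.isclose(v, b[1], abs_tol=1e-6)
        for v, b in zip(res.x, bounds)
    )
    return res, nfev, at_bound


def _hessian(fun, x: np.ndarray, h: float = _FD_STEP) -> np.ndarray:
    """Central-difference Hessian."""
    k = len(x)
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h**2)
    return H


def _aicc(loglik: float, p: int, n: int) -> float:
    if n - p - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def _failure(message: str, sharing: str, n: int, recaps: int) -> FitResult:
    return FitResult(
        converged=False, message=message, sharing=sharing, n=n, n_recaptures=recaps
    )


def fit_array(
    data: CaptureData, array: DetectorArray, spec: ModelSpec | None = None
) -> FitResult:
    """Fit the constant-parameter half-normal model to one array's data.

    Maximises the conditional likelihood on the link scale from a
    data-driven start (g0 = 0.2, σ from :func:`rpsv`).  The mask defaults
    to buffer 4σ_start / cell σ_start/2 and is rebuilt once as 4σ̂ when the
    estimate exceeds the start (two-pass, guarding against truncation of
    the integration region).  Data below the minimum-data rule, optimiser
    failure, a boundary solution, or a non-positive-definite Hessian yield
    a non-converged result rather than numbers.
    """
    spec = spec or ModelSpec()
    if spec.sharing != "independent":
        raise ValueError("fit_array requires sharing='independent'")
    if data.array_id != array.array_id:
        raise ValueError("data/array mismatch")
    reason = _check_data(data, spec)
    if reason is not None:
        return _failure(reason, spec.sharing, data.n, data.n_recaptures)

    sigma0 = _sigma_start(data, array)
    theta0 = DetectionParams(g0=0.2, sigma=sigma0).to_link()
    mask = _default_mask(array, sigma0, spec)
    lik = _ArrayLikelihood(array, mask, data)
    res, nfev, at_bound = _minimize(lik.nll, theta0)
    sigma_hat = math.exp(res.x[1])
    if spec.buffer_m is None and sigma_hat > sigma0:
        # second pass with a mask sized to the estimate
        mask = _default_mask(array, sigma_hat, spec)
        lik = _ArrayLikelihood(array, mask, data)
        res, nfev2, at_bound = _minimize(lik.nll, res.x)
        nfev += nfev2
    if not res.success or at_bound:
        return _failure(
        f"optimizer failed: {res.message}" if not res.success else "boundary solution",
            spec.sharing,
            data.n,
            data.n_recaptures,
        )

    H = _hessian(lik.nll, res.x)
    evals = np.linalg.eigvalsh(H)
    if evals.min() <= 0:
        return _failure(
            "non-positive-definite Hessian", spec.sharing, data.n, data.n_recaptures
        )
    vcov = np.linalg.inv(H)
    theta_hat = DetectionParams.from_link(res.x)
    a_hat, grad = effective_area(theta_hat, array, mask)
    var_a = float(grad @ vcov @ grad)
    n = data.n
    D = density_per_100km2(n, a_hat)
    var_D = D * D * (1.0 / n + var_a / a_hat**2)
    loglik = -res.fun
    p = 2
    return FitResult(
        converged=True,
        message="ok",
        sharing=spec.sharing,
        n=n,
        n_recaptures=data.n_recaptures,
        theta={array.array_id: theta_hat},
        params_link=res.x.copy(),
        vcov_link=vcov,
        a_by_array={array.array_id: a_hat},
        var_a_by_array={array.array_id: var_a},
        a_total=a_hat,
        var_a_total=var_a,
        D_local=D,
        var_D_local=var_D,
        ci95=lognormal_ci(D, var_D),
        loglik=loglik,
        n_params=p,
        aicc=_aicc(loglik, p, n),
        n_evaluations=nfev,
        masks={array.array_id: mask},
    )


def _theta_blocks(x: np.ndarray, sharing: str, J: int) -> list[np.ndarray]:
    """Map the joint link-scale vector to per-array (2,) parameter blocks."""
    if sharing == "pooled_constant":
        return [x[:2]] * J
    if sharing == "pooled_interactive":
        return [x[2 * j : 2 * j + 2] for j in range(J)]
    if sharing == "pooled_additive":
        base = x[:2]
        blocks = [base]
        for j in range(1, J):
            off = np.array([x[2 + (j - 1)], x[2 + (J - 1) + (j - 1)]])
            blocks.append(base + off)
        return blocks
    raise ValueError(sharing)


def fit_pooled(
    datasets: list[CaptureData],
    arrays: list[DetectorArray],
    spec: ModelSpec | None = None,
) -> FitResult:
    """Jointly fit ≥2 arrays with shared detection parameters.

    The joint conditional likelihood is the sum of per-array conditional
    likelihoods with parameters tied per ``spec.sharing``.  The pooled
    density estimate applies the Horvitz–Thompson form to the pooled data:
    ``D̂ = 100 Σ n_j / Σ â_j``, with the delta-method variance of
    Â = Σ â_j propagated through the shared parameters.  With
    ``pooled_interactive`` sharing the joint problem separates by array and
    reproduces independent per-array fits.
    """
    spec = spec or ModelSpec(sharing="pooled_constant")
    if spec.sharing == "independent":
        raise ValueError("fit_pooled requires a pooled sharing mode")
    if len(arrays) < 2:
        raise ValueError("pooled modes require at least 2 arrays")
    if len(datasets) != len(arrays):
        raise ValueError("one dataset per array required")
    by_id = {d.array_id: d for d in datasets}
    datasets = [by_id[a.array_id] for a in arrays]
    J = len(arrays)
    n_total = sum(d.n for d in datasets)
    recaps = sum(d.n_recaptures for d in datasets)
    total_sr = sum(d.n_spatial_recaptures for d in datasets)
    if n_total < spec.min_n or total_sr < spec.min_spatial_recaptures:
        return _failure("insufficient pooled data", spec.sharing, n_total, recaps)

    # start sigma from the pooled RPSV across arrays
    ss, df = 0.0, 0
    for d, a in zip(datasets, arrays):
        s = rpsv(d, a)
        if s is not None:
            xy = a.coords
            for i in range(d.n):
                _, det = np.nonzero(d.omega[i])
                if len(det) < 2:
                    continue
                pts = xy[det]
                ss += float(np.sum((pts - pts.mean(axis=0)) ** 2))
                df += len(det) - 1
    sigma0 = math.sqrt(ss / (2.0 * df)) if df > 0 else arrays[0].spacing() / 2.0
    sigma0 = float(
        np.clip(sigma0, arrays[0].spacing() / 4.0, 20.0 * arrays[0].spacing())
    )

    if spec.sharing == "pooled_constant":
        n_params = 2
        x0 = DetectionParams(0.2, sigma0).to_link()
        sig_starts = [sigma0] * J
    elif spec.sharing == "pooled_interactive":
        n_params = 2 * J
        sig_starts = [_sigma_start(d, a) for d, a in zip(datasets, arrays)]
        x0 = np.concatenate(
            [DetectionParams(0.2, s).to_link() for s in sig_starts]
        )
    else:  # pooled_additive
        n_params = 2 + 2 * (J - 1)
        x0 = np.concatenate([DetectionParams(0.2, sigma0).to_link(), np.zeros(2 * (J - 1))])
        sig_starts = [sigma0] * J

    def build_liks(sigmas: list[float]) -> list[_ArrayLikelihood]:
        return [
            _ArrayLikelihood(a, _default_mask(a, s, spec), d)
            for a, s, d in zip(arrays, sigmas, datasets)
        ]

    liks = build_liks(sig_starts)

    def joint_nll(x: np.ndarray) -> float:
        return sum(
            lik.nll(blk) for lik, blk in zip(liks, _theta_blocks(x, spec.sharing, J))
        )

    bounds = _theta_bounds(n_params, spec.sharing)
    res, nfev, at_bound = _minimize(
        _bounded_joint(joint_nll, spec.sharing, J), x0, bounds
    )
    sig_hat = [math.exp(b[1]) for b in _theta_blocks(res.x, spec.sharing, J)]
    if spec.buffer_m is None and any(s > s0 for s, s0 in zip(sig_hat, sig_starts)):
        liks = build_liks([max(s, s0) for s, s0 in zip(sig_hat, sig_starts)])
        res, nfev2, at_bound = _minimize(
            _bounded_joint(joint_nll, spec.sharing, J), res.x, bounds
        )
        nfev += nfev2
    if not res.success or at_bound:
        return _failure(
            f"optimizer failed: {res.message}" if not res.success else "boundary solution",
            spec.sharing,
            n_total,
            recaps,
        )

    fun = _bounded_joint(joint_nll, spec.sharing, J)
    H = _hessian(fun, res.x)
    evals = np.linalg.eigvalsh(H)
    if evals.min() <= 0:
        return _failure("non-positive-definite Hessian", spec.sharing, n_total, recaps)
    vcov = np.linalg.inv(H)

    blocks = _theta_blocks(res.x, spec.sharing, J)
    theta = {
        a.array_id: DetectionParams.from_link(b) for a, b in zip(arrays, blocks)
    }
    # per-array areas and the gradient of each a_j w.r.t. the joint vector
    a_by, var_a_by = {}, {}
    grad_total = np.zeros(len(res.x))
    a_total = 0.0
    for j, (a, lik) in enumerate(zip(arrays, liks)):
        def area_j(x: np.ndarray, _lik=lik, _j=j) -> float:
            return _lik.area(_theta_blocks(x, spec.sharing, J)[_j])

        aj = area_j(res.x)
        gj = np.empty(len(res.x))
        for i in range(len(res.x)):
            xp, xm = res.x.copy(), res.x.copy()
            xp[i] += _FD_STEP
            xm[i] -= _FD_STEP
            gj[i] = (area_j(xp) - area_j(xm)) / (2.0 * _FD_STEP)
        a_by[a.array_id] = aj
        var_a_by[a.array_id] = float(gj @ vcov @ gj)
        grad_total += gj
        a_total += aj
    var_a_total = float(grad_total @ vcov @ grad_total)

    D = density_per_100km2(n_total, a_total)
    var_D = D * D * (1.0 / n_total + var_a_total / a_total**2)
    loglik = -res.fun
    return FitResult(
        converged=True,
        message="ok",
        sharing=spec.sharing,
        n=n_total,
        n_recaptures=recaps,
        theta=theta,
        params_link=res.x.copy(),
        vcov_link=vcov,
        a_by_array=a_by,
        var_a_by_array=var_a_by,
        a_total=a_total,
        var_a_total=var_a_total,
        D_local=D,
        var_D_local=var_D,
        ci95=lognormal_ci(D, var_D),
        loglik=loglik,
        n_params=n_params,
        aicc=_aicc(loglik, n_params, n_total),
        n_evaluations=nfev,
        masks={a.array_id: lik.mask for a, lik in zip(arrays, liks)},
    )


def _bounded_joint(fun, sharing: str, J: int):
    """Wrap a joint nll so every per-array block respects the link box."""

    def wrapped(x: np.ndarray) -> float:
        for blk in _theta_blocks(x, sharing, J):
            if abs(blk[0]) > _G0_LINK_BOUND or not (
                _LSIG_BOUNDS[0] <= blk[1] <= _LSIG_BOUNDS[1]
            ):
                return 1e10
        return fun(x)

    return wrapped
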