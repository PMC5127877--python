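"""Voxel-wise parameter estimation for multi-b-value DWI.

Two estimators share the same bounded model surface:

* ``nlls`` — deterministic trust-region-reflective least squares
  (:func:`scipy.optimize.least_squares`) with model-specific staged
  initialization (log-linear ADC seed; for IVIM a high-b mono fit for D,
  intercept ratio for f, then a 1-D grid seed for D*).
* ``mcmc`` — adaptive Metropolis–Hastings under a Gaussian likelihood and
  uniform-on-bounds priors, used as a robust least-squares estimator.  The
  chain is initialized at the NLLS solution with proposal scales taken from
  the Gauss–Newton covariance, adapted during burn-in toward ~30% acceptance.
  The point estimate is the per-parameter posterior median by default.

Estimates always respect the configured bounds; estimates pinned at a bound
are flagged rather than silently accepted.  Voxels with insufficient usable
data yield a non-converged :class:`FitResult` with NaN parameters, never an
exception, so whole-ROI fitting is robust to pathological voxels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .signal_models import AcquisitionProtocol, ModelDefinition, get_model

__all__ = [
    "FitConfig",
    "FitResult",
    "ParameterMap",
    "fit_voxel_nlls",
    "fit_voxel_mcmc",
    "fit_voxel",
    "fit_roi",
]

_BOUND_TOL = 1e-9  # relative closeness to a bound that counts as "clipped"


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings for one model.

    ``bounds`` overrides the registry defaults per parameter.  ``min_b``
    restricts the fit to b >= min_b (the registry already sets 100 for
    ``adc100``); ``None`` defers to the model definition.  MCMC settings:
    ``chain_length`` total iterations, ``burn_in`` discarded iterations
    (adaptation happens here), ``proposal_scales`` optional per-parameter
    Gaussian proposal sd (default: Gauss-Newton scales from the NLLS fit),
    ``sigma_noise`` fixes the likelihood noise sd (default: estimated from
    the NLLS residuals).
    """

    model_id: str = "mono"
    bounds: Optional[Dict[str, Tuple[float, float]]] = None
    estimator: str = "nlls"
    chain_length: int = 5000
    burn_in: int = 1000
    proposal_scales: Optional[Dict[str, float]] = None
    seed: int = 0
    point_estimate: str = "posterior_median"
    min_b: Optional[float] = None
    kurtosis_form: str = "as_printed"
    sigma_noise: Optional[float] = None

    def __post_init__(self):
        if self.estimator not in ("nlls", "mcmc"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.point_estimate not in ("posterior_median", "posterior_mean", "map"):
            raise ValueError(f"unknown point estimate rule {self.point_estimate!r}")
        if not (self.chain_length > self.burn_in >= 0):
            raise ValueError("require chain_length > burn_in >= 0")
        if self.bounds is not None:
            for name, (lo, hi) in self.bounds.items():
                if not lo < hi:
                    raise ValueError(f"bounds for {name!r} must satisfy low < high")

    @property
    def model(self) -> ModelDefinition:
        return get_model(self.model_id, kurtosis_form=self.kurtosis_form)

    def resolve_bounds(self, model: ModelDefinition, max_signal: float) -> np.ndarray:
        """(2, n_free) bound array; S0's open upper bound becomes 10x max signal."""
        out = np.empty((2, model.n_free))
        for j, name in enumerate(model.free_params):
            lo, hi = model.default_bounds[name]
            if self.bounds and name in self.bounds:
                lo, hi = self.bounds[name]
            if name == "S0" and not np.isfinite(hi):
                hi = 10.0 * max(max_signal, 1e-12)
            out[0, j], out[1, j] = lo, hi
        return out

    def effective_min_b(self, model: ModelDefinition) -> Optional[float]:
        return self.min_b if self.min_b is not None else model.min_b

    def digest(self) -> str:
        payload = {
            k: (sorted(v.items()) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class FitResult:
    """Outcome of one voxel fit: named parameter values (including derived
    ones), residual sum of squares, convergence flag and diagnostics."""

    model_id: str
    theta: Dict[str, float]
    residual_sum_squares: float
    converged: bool
    n_points_used: int
    diagnostics: Dict[str, object] = field(default_factory=dict)

    @property
    def params(self):
        """Validated parameter dataclass (None for failed fits)."""
        if not self.converged and any(np.isnan(v) for v in self.theta.values()):
            return None
        model = get_model(self.model_id, kurtosis_form=self.diagnostics.get("form", "as_printed"))
        return model.make_params(self.theta)


@dataclass
class ParameterMap:
    """Voxel grid of one fitted parameter: values inside the mask, NaN outside."""

    model_id: str
    parameter: str
    values: np.ndarray
    mask: np.ndarray
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask geometry differ")


# ---------------------------------------------------------------------------
# Initialization


def _loglin_adc(b: np.ndarray, s: np.ndarray) -> Tuple[float, float]:
    """Log-linear (S0, ADC) seed; requires positive signals."""
    if len(b) < 2 or np.ptp(b) == 0:
        return float(np.mean(s)), 0.0
    slope, intercept = np.polyfit(b, np.log(s), 1)
    return float(np.exp(intercept)), float(-slope)


def _initial_theta(model: ModelDefinition, b: np.ndarray, s: np.ndarray,
                   bounds: np.ndarray) -> np.ndarray:
    lo, hi = bounds
    s0_guess, adc_guess = _loglin_adc(b, s)

    def clipb(j: int, v: float) -> float:
        span = hi[j] - lo[j]
        return float(np.clip(v, lo[j] + 1e-12 * max(span, 1.0), hi[j] - 1e-12 * max(span, 1.0)))

    mid = model.model_id
    if mid in ("mono", "adc100"):
        return np.array([clipb(0, s0_guess), clipb(1, adc_guess)])
    if mid == "stretched":
        return np.array([clipb(0, s0_guess), clipb(1, adc_guess), clipb(2, 0.9)])
    if mid == "kurtosis":
        low = b <= 300
        s0g, ddcg = (_loglin_adc(b[low], s[low]) if low.sum() >= 2 else (s0_guess, adc_guess))
        k0 = 1e-3 if model.form == "as_printed" else 0.5
        return np.array([clipb(0, s0g), clipb(1, ddcg), clipb(2, k0)])
    if mid == "ivim":
        # stage 1: tissue diffusion from the high-b tail
        high = b >= 300
        if high.sum() >= 2:
            a_int, d0 = _loglin_adc(b[high], s[high])
        else:
            a_int, d0 = s0_guess, adc_guess
        s0_0 = float(s[np.argmin(b)])
        f0 = float(np.clip(1.0 - a_int / max(s0_0, 1e-12), 0.01, 0.6))
        theta = np.array([clipb(0, max(s0_0, a_int)), clipb(1, f0), clipb(2, d0), 0.0])
        # stage 2: 1-D grid seed for D* with the rest held fixed
        grid = np.geomspace(max(lo[3], 1e-4), hi[3], 25)
        cand = np.tile(theta, (grid.size, 1))
        cand[:, 3] = grid
        rss = ((model.signal(cand, b) - s) ** 2).sum(axis=1)
        theta[3] = clipb(3, grid[int(np.argmin(rss))])
        return theta
    raise KeyError(mid)


def _prepare(signal, protocol: AcquisitionProtocol, config: FitConfig):
    """Apply the b-subset, drop non-positive signals, resolve bounds."""
    model = config.model
    s = np.asarray(signal, dtype=float)
    b = protocol.b_array
    if s.shape != b.shape:
        raise ValueError(f"signal has {s.shape} values but protocol has {b.shape} b-values")
    keep = protocol.subset_mask(config.effective_min_b(model))
    positive = s > 0
    n_dropped = int((keep & ~positive).sum())
    keep &= positive
    return model, b[keep], s[keep], n_dropped


def _failed(model: ModelDefinition, config: FitConfig, n_used: int, n_dropped: int,
            reason: str) -> FitResult:
    theta = {name: float("nan") for name in model.free_params}
    for name in model.derived:
        theta[name] = float("nan")
    return FitResult(
        model_id=model.model_id,
        theta=theta,
        residual_sum_squares=float("nan"),
        converged=False,
        n_points_used=n_used,
        diagnostics={"failure": reason, "n_dropped_nonpositive": n_dropped,
                     "form": model.form},
    )


def _finalize_theta(model: ModelDefinition, x: np.ndarray, bounds: np.ndarray,
                    diagnostics: Dict[str, object]) -> Dict[str, float]:
    lo, hi = bounds
    clipped = []
    for j, name in enumerate(model.free_params):
        span = max(hi[j] - lo[j], 1e-300)
        if np.isfinite(lo[j]) and (x[j] - lo[j]) <= _BOUND_TOL * span:
            clipped.append(name)
        elif np.isfinite(hi[j]) and (hi[j] - x[j]) <= _BOUND_TOL * span:
            clipped.append(name)
    theta = {name: float(v) for name, v in zip(model.free_params, x)}
    if model.model_id == "ivim" and theta["Dstar"] < theta["D"]:
        # fast component must stay above the slow one; rare with default bounds
        theta["Dstar"] = theta["D"]
        diagnostics["dstar_clipped_to_d"] = True
    for name, fn in model.derived.items():
        theta[name] = float(fn(theta))
    diagnostics["clipped_params"] = clipped
    return theta


def fit_voxel_nlls(signal, protocol: AcquisitionProtocol, config: FitConfig) -> FitResult:
    """Bounded nonlinear least squares for one voxel's decay curve."""
    model, b, s, n_dropped = _prepare(signal, protocol, config)
    if len(s) < model.n_free + 1:
        return _failed(model, config, len(s), n_dropped, "too few usable signals")
    bounds = config.resolve_bounds(model, float(s.max()))
    x0 = _initial_theta(model, b, s, bounds)
    scale = np.maximum(np.abs(x0), 1e-3 * np.maximum(np.abs(bounds[1]), 1e-12))

    def resid(x: np.ndarray) -> np.ndarray:
        return model.signal(x, b) - s

    def jac(x: np.ndarray) -> np.ndarray:
        return model.jac(x, b)

    res = least_squares(
        resid, x0, jac=jac, bounds=(bounds[0], bounds[1]), method="trf",
        x_scale=scale, xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=600,
    )
    diagnostics: Dict[str, object] = {
        "n_dropped_nonpositive": n_dropped,
        "nfev": int(res.nfev),
        "form": model.form,
    }
    theta = _finalize_theta(model, res.x, bounds, diagnostics)
    return FitResult(
        model_id=model.model_id,
        theta=theta,
        residual_sum_squares=float(res.fun @ res.fun),
        converged=bool(res.success),
        n_points_used=len(s),
        diagnostics=diagnostics,
    )


def _gauss_newton_scales(model: ModelDefinition, x: np.ndarray, b: np.ndarray,
                         sigma: float, bounds: np.ndarray) -> np.ndarray:
    """Proposal sd per parameter from the local Gauss-Newton covariance."""
    jac = model.jac(x, b)
    jtj = jac.T @ jac
    try:
        cov = sigma**2 * np.linalg.inv(jtj + 1e-12 * np.eye(len(x)) * np.trace(jtj))
        scales = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - singular designs
        scales = np.zeros(len(x))
    span = bounds[1] - bounds[0]
    fallback = 0.01 * np.where(np.isfinite(span), span, np.abs(x) + 1e-12)
    scales = np.where(scales > 0, scales, np.maximum(fallback, 1e-12))
    return scales


def fit_voxel_mcmc(signal, protocol: AcquisitionProtocol, config: FitConfig) -> FitResult:
    """Adaptive Metropolis-Hastings fit for one voxel.

    Posterior: Gaussian likelihood exp(-RSS / (2 sigma^2)) on the usable
    signals, uniform priors on the bounds.  Identical (signal, config, seed)
    gives an identical result.
    """
    nlls = fit_voxel_nlls(signal, protocol, config)
    if not nlls.converged and any(np.isnan(v) for v in nlls.theta.values()):
        return nlls
    model, b, s, n_dropped = _prepare(signal, protocol, config)
    bounds = config.resolve_bounds(model, float(s.max()))
    x = np.array([nlls.theta[name] for name in model.free_params])
    x = np.clip(x, bounds[0], bounds[1])

    dof = max(len(s) - model.n_free, 1)
    sigma = config.sigma_noise
    if sigma is None:
        sigma = float(np.sqrt(max(nlls.residual_sum_squares, 1e-30) / dof))
    sigma = max(sigma, 1e-12 * float(s.max()))

    if config.proposal_scales is not None:
        scales = np.array([config.proposal_scales[name] for name in model.free_params])
    else:
        scales = _gauss_newton_scales(model, x, b, sigma, bounds)

    rng = np.random.default_rng(config.seed)
    inv2s2 = 1.0 / (2.0 * sigma**2)

    def neg_loglike(theta: np.ndarray) -> float:
        r = model.signal(theta, b) - s
        return float(r @ r) * inv2s2

    cur_nll = neg_loglike(x)
    n_keep = config.chain_length - config.burn_in
    samples = np.empty((n_keep, model.n_free))
    accepted = 0
    block_acc = 0
    block = max(50, config.burn_in // 10) if config.burn_in else 50
    for it in range(config.chain_length):
        prop = x + scales * rng.standard_normal(model.n_free)
        if np.all(prop >= bounds[0]) and np.all(prop <= bounds[1]):
            prop_nll = neg_loglike(prop)
            if prop_nll <= cur_nll or rng.random() < np.exp(cur_nll - prop_nll):
                x, cur_nll = prop, prop_nll
                accepted += 1
                block_acc += 1
        if it < config.burn_in and (it + 1) % block == 0:
            # Robbins-Monro-style scale adaptation toward ~0.3 acceptance
            rate = block_acc / block
            scales *= np.exp(np.clip(rate - 0.3, -0.9, 0.9))
            block_acc = 0
        if it >= config.burn_in:
            samples[it - config.burn_in] = x

    rate = accepted / config.chain_length
    if config.point_estimate == "posterior_median":
        est = np.median(samples, axis=0)
    elif config.point_estimate == "posterior_mean":
        est = samples.mean(axis=0)
    else:  # map: lowest-RSS sample visited post burn-in
        rss_chain = np.array([neg_loglike(row) for row in samples[:: max(1, n_keep // 512)]])
        est = samples[:: max(1, n_keep // 512)][int(np.argmin(rss_chain))]
    est = np.clip(est, bounds[0], bounds[1])

    diagnostics: Dict[str, object] = {
        "n_dropped_nonpositive": n_dropped,
        "acceptance_rate": rate,
        "acceptance_warning": not (0.05 <= rate <= 0.8),
        "sigma_noise": sigma,
        "form": model.form,
    }
    theta = _finalize_theta(model, est, bounds, diagnostics)
    r = model.signal(est, b) - s
    return FitResult(
        model_id=model.model_id,
        theta=theta,
        residual_sum_squares=float(r @ r),
        converged=True,
        n_points_used=len(s),
        diagnostics=diagnostics,
    )


def fit_voxel(signal, protocol: AcquisitionProtocol, config: FitConfig) -> FitResult:
    if config.estimator == "mcmc":
        return fit_voxel_mcmc(signal, protocol, config)
    return fit_voxel_nlls(signal, protocol, config)


def fit_roi(volumes: np.ndarray, mask: np.ndarray, protocol: AcquisitionProtocol,
            config: FitConfig) -> Dict[str, ParameterMap]:
    """Fit every in-mask voxel of a (nx, ny, nz, n_b) stack.

    Returns one :class:`ParameterMap` per model parameter, including derived
    ones (f*D* for IVIM).  Voxel-level failures are counted in the map
    provenance, not raised.  MCMC seeds derive from (config.seed, flat voxel
    index) so results do not depend on iteration order.
    """
    volumes = np.asarray(volumes, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volumes.shape[:3] != mask.shape:
        raise ValueError("volume and mask geometry differ")
    if volumes.shape[3] != len(protocol.b_values):
        raise ValueError("b axis length does not match the protocol")
    if not mask.any():
        raise ValueError("mask is empty")
    model = config.model

    names = list(model.free_params) + list(model.derived)
    maps = {name: np.full(mask.shape, np.nan) for name in names}
    n_failed = 0
    n_clipped = 0
    flat = volumes.reshape(-1, volumes.shape[3])
    idx = np.flatnonzero(mask.ravel())
    for i in idx:
        cfg = config
        if config.estimator == "mcmc":
            seed = int(np.random.SeedSequence(entropy=(config.seed, int(i))).generate_state(1)[0]) % (2**31)
            cfg = replace(config, seed=seed)
        result = fit_voxel(flat[i], protocol, cfg)
        if not result.converged:
            n_failed += 1
        if result.diagnostics.get("clipped_params"):
            n_clipped += 1
        for name in names:
            maps[name].ravel()[i] = result.theta[name]

    provenance = {
        "model_id": config.model_id,
        "estimator": config.estimator,
        "config_hash": config.digest(),
        "seed": config.seed,
        "form": model.form,
        "min_b": config.effective_min_b(model),
        "n_voxels": int(idx.size),
        "n_failed": n_failed,
        "n_clipped": n_clipped,
    }
    return {
        name: ParameterMap(config.model_id, name, maps[name], mask, dict(provenance))
        for name in names
    }
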