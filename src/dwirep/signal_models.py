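"""Forward signal models for multi-b-value diffusion-weighted MRI.

Four voxel-level signal equations are provided, each mapping a diffusion
weighting *b* (mm^-2 s) to a magnitude signal (arbitrary units):

``mono``        S_b = S0 * exp(-b * ADC)
``ivim``        S_b = S0 * [f * exp(-b * D*) + (1 - f) * exp(-b * D)]
``stretched``   S_b = S0 * exp(-(b * DDC_alpha)^alpha)
``kurtosis``    S_b = S0 * exp(-b * DDC_K + (1/6) * K^2 * b^2)   ("as_printed")
                S_b = S0 * exp(-b * DDC_K + (1/6) * K * b^2 * DDC_K^2)  ("standard")

Units follow the clinical convention throughout: b in mm^-2 s and diffusion
coefficients in mm^2 s^-1, so b*D is dimensionless.  The kurtosis model's
default exponent uses the K-squared form; the conventional diffusion-kurtosis
expansion is available via ``form="standard"`` and the chosen form is carried
into all provenance records.

The ``adc100`` registry entry is the monoexponential model restricted at fit
time to b >= 100 mm^-2 s, the usual device for suppressing perfusion
contamination of the apparent diffusion coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Tuple

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "MonoParams",
    "IvimParams",
    "StretchedParams",
    "KurtosisParams",
    "ModelDefinition",
    "mono_signal",
    "ivim_signal",
    "stretched_signal",
    "kurtosis_signal",
    "get_model",
    "list_models",
    "DEFAULT_B_VALUES",
]

#: Six-b clinical scheme (mm^-2 s) used as the package default.
DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 300.0, 600.0, 1000.0)


def _check_b(b) -> np.ndarray:
    arr = np.asarray(b, dtype=float)
    if np.any(arr < 0):
        raise ValueError("b-values must be non-negative (mm^-2 s)")
    return arr


def _scalar_or_array(values: np.ndarray, scalar_in: bool):
    return float(values) if scalar_in else values


@dataclass(frozen=True)
class AcquisitionProtocol:
    """The b-value scheme plus free-form acquisition metadata.

    b-values are strictly increasing, non-negative, and at least four
    distinct weightings are required — the minimum for the 4-parameter IVIM
    fit to be identifiable.  Simulation requires b=0 as the S0 anchor;
    fitting subsets (e.g. ADC100) may exclude it.
    """

    b_values: Tuple[float, ...] = DEFAULT_B_VALUES
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        b = tuple(float(v) for v in self.b_values)
        if len(b) < 4:
            raise ValueError("protocol needs at least 4 b-values")
        if any(v < 0 for v in b):
            raise ValueError("b-values must be non-negative")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "b_values", b)

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def has_b0(self) -> bool:
        return self.b_values[0] == 0.0

    def require_b0(self) -> None:
        if not self.has_b0:
            raise ValueError("protocol must contain b = 0 (S0 anchor)")

    def subset_mask(self, min_b: float | None) -> np.ndarray:
        """Boolean selector for b >= min_b (all True when min_b is None)."""
        if min_b is None:
            return np.ones(len(self.b_values), dtype=bool)
        return self.b_array >= float(min_b)


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class MonoParams:
    """Monoexponential decay: S0 (a.u.) and apparent diffusion coefficient
    ADC (mm^2 s^-1)."""

    S0: float
    ADC: float

    def __post_init__(self):
        if not self.S0 > 0:
            raise ValueError("S0 must be positive")
        if self.ADC < 0:
            raise ValueError("ADC must be non-negative")


@dataclass(frozen=True)
class IvimParams:
    """Bi-exponential intravoxel-incoherent-motion parameters.

    ``f`` is the pseudo-diffusion (perfusion) fraction, ``D`` the slow tissue
    diffusion coefficient, ``Dstar`` the fast capillary pseudo-diffusion
    coefficient (all diffusion units mm^2 s^-1).  The compound parameter
    f*D* is exposed as the derived property ``fDstar``.
    """

    S0: float
    f: float
    D: float
    Dstar: float

    def __post_init__(self):
        if not self.S0 > 0:
            raise ValueError("S0 must be positive")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("pseudo-diffusion fraction f must lie in [0, 1]")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.Dstar < self.D:
            raise ValueError("Dstar must be >= D (fast component)")

    @property
    def fDstar(self) -> float:
        return self.f * self.Dstar


@dataclass(frozen=True)
class StretchedParams:
    """Stretched-exponential parameters: distributed diffusion coefficient
    DDC_alpha (mm^2 s^-1) and stretching exponent alpha in (0, 1]."""

    S0: float
    DDC_alpha: float
    alpha: float

    def __post_init__(self):
        if not self.S0 > 0:
            raise ValueError("S0 must be positive")
        if self.DDC_alpha < 0:
            raise ValueError("DDC_alpha must be non-negative")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class KurtosisParams:
    """Kurtosis-model parameters: diffusion coefficient DDC_K (mm^2 s^-1) and
    kurtosis parameter K.

    ``form`` selects the exponent convention: ``as_printed`` uses
    (1/6)*K^2*b^2, ``standard`` the conventional (1/6)*K*b^2*DDC_K^2.
    """

    S0: float
    DDC_K: float
    K: float
    form: str = "as_printed"

    def __post_init__(self):
        if not self.S0 > 0:
            raise ValueError("S0 must be positive")
        if self.DDC_K < 0:
            raise ValueError("DDC_K must be non-negative")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.form not in ("as_printed", "standard"):
            raise ValueError(f"unknown kurtosis form: {self.form!r}")


# ---------------------------------------------------------------------------
# Signal equations (scalar in -> scalar out; sequence in -> array out)


def mono_signal(p: MonoParams, b):
    """S0 * exp(-b * ADC); strictly positive, non-increasing in b."""
    scalar = np.isscalar(b)
    barr = _check_b(b)
    return _scalar_or_array(p.S0 * np.exp(-barr * p.ADC), scalar)


def ivim_signal(p: IvimParams, b):
    """S0 * [f * exp(-b * D*) + (1 - f) * exp(-b * D)]."""
    scalar = np.isscalar(b)
    barr = _check_b(b)
    sig = p.S0 * (p.f * np.exp(-barr * p.Dstar) + (1.0 - p.f) * np.exp(-barr * p.D))
    return _scalar_or_array(sig, scalar)


def stretched_signal(p: StretchedParams, b):
    """S0 * exp(-(b * DDC_alpha)^alpha); 0^alpha := 0 so the b=0 anchor is S0."""
    scalar = np.isscalar(b)
    barr = _check_b(b)
    sig = p.S0 * np.exp(-np.power(barr * p.DDC_alpha, p.alpha))
    return _scalar_or_array(sig, scalar)


def kurtosis_signal(p: KurtosisParams, b):
    """Kurtosis decay in the form selected by ``p.form``.

    The as-printed exponent need not be monotone: its derivative changes sign
    at b = 3*DDC_K/K^2, beyond which the modelled signal turns upward.
    """
    scalar = np.isscalar(b)
    barr = _check_b(b)
    if p.form == "as_printed":
        expo = -barr * p.DDC_K + (p.K**2) * (barr**2) / 6.0
    else:
        expo = -barr * p.DDC_K + p.K * (barr**2) * (p.DDC_K**2) / 6.0
    return _scalar_or_array(p.S0 * np.exp(expo), scalar)


# ---------------------------------------------------------------------------
# Flat-vector signal functions used by the fitting and simulation machinery.
# theta has the model's free parameters along the last axis; b is 1-D.
# A (n_voxel, n_param) theta yields an (n_voxel, n_b) signal matrix.


def _col(theta: np.ndarray, j: int) -> np.ndarray:
    return theta[..., j : j + 1] if theta.ndim > 1 else theta[j]


def _sig_mono(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    return _col(theta, 0) * np.exp(-b * _col(theta, 1))


def _sig_ivim(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, f, d, dstar = (_col(theta, j) for j in range(4))
    return s0 * (f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-b * d))


def _sig_stretched(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, ddc, alpha = (_col(theta, j) for j in range(3))
    return s0 * np.exp(-np.power(b * ddc, alpha))


def _sig_kurtosis_printed(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, ddc, k = (_col(theta, j) for j in range(3))
    return s0 * np.exp(-b * ddc + (k**2) * (b**2) / 6.0)


def _sig_kurtosis_standard(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, ddc, k = (_col(theta, j) for j in range(3))
    return s0 * np.exp(-b * ddc + k * (b**2) * (ddc**2) / 6.0)


# Analytic Jacobians (n_b, n_free) for 1-D theta; used by the NLLS estimator.


def _jac_mono(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, adc = theta
    decay = np.exp(-b * adc)
    return np.column_stack([decay, -b * s0 * decay])


def _jac_ivim(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, f, d, dstar = theta
    ef, ed = np.exp(-b * dstar), np.exp(-b * d)
    return np.column_stack([
        f * ef + (1.0 - f) * ed,
        s0 * (ef - ed),
        -s0 * (1.0 - f) * b * ed,
        -s0 * f * b * ef,
    ])


def _jac_stretched(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, ddc, alpha = theta
    x = b * ddc
    u = np.power(x, alpha)
    s = s0 * np.exp(-u)
    with np.errstate(divide="ignore"):
        logx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), 0.0)
    d_ddc = -s * alpha * u / np.where(ddc > 0, ddc, 1.0)
    d_alpha = -s * u * logx
    return np.column_stack([np.exp(-u), d_ddc, d_alpha])


def _jac_kurtosis_printed(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, ddc, k = theta
    s = s0 * np.exp(-b * ddc + (k**2) * (b**2) / 6.0)
    return np.column_stack([s / s0, -b * s, (k * b**2 / 3.0) * s])


def _jac_kurtosis_standard(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, ddc, k = theta
    s = s0 * np.exp(-b * ddc + k * (b**2) * (ddc**2) / 6.0)
    return np.column_stack([
        s / s0,
        (-b + k * (b**2) * ddc / 3.0) * s,
        ((b**2) * (ddc**2) / 6.0) * s,
    ])


# ---------------------------------------------------------------------------
# Model registry


@dataclass(frozen=True)
class ModelDefinition:
    """Everything the fitting/simulation layers need to know about a model."""

    model_id: str
    free_params: Tuple[str, ...]  # includes S0, ordered as in theta
    report_params: Tuple[str, ...]  # parameters reported in tables (incl. derived)
    signal: Callable[[np.ndarray, np.ndarray], np.ndarray]
    jac: Callable[[np.ndarray, np.ndarray], np.ndarray]
    default_bounds: Dict[str, Tuple[float, float]]
    min_b: float | None = None  # fit-time b restriction, None = use all
    derived: Dict[str, Callable[[Dict[str, float]], float]] = field(default_factory=dict)
    form: str | None = None  # kurtosis exponent convention, if applicable

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def make_params(self, theta: Dict[str, float]):
        """Build the validated parameter dataclass from a named theta dict."""
        if self.model_id in ("mono", "adc100"):
            adc_name = self.free_params[1]
            return MonoParams(S0=theta["S0"], ADC=theta[adc_name])
        if self.model_id == "ivim":
            return IvimParams(S0=theta["S0"], f=theta["f"], D=theta["D"], Dstar=theta["Dstar"])
        if self.model_id == "stretched":
            return StretchedParams(
                S0=theta["S0"], DDC_alpha=theta["DDC_alpha"], alpha=theta["alpha"]
            )
        if self.model_id == "kurtosis":
            return KurtosisParams(
                S0=theta["S0"], DDC_K=theta["DDC_K"], K=theta["K"], form=self.form
            )
        raise KeyError(self.model_id)


# Default bounds: diffusion coefficients span the physiological range, D* is
# forced above the slow-diffusion band, f and alpha live on their natural
# supports.  S0's upper bound is data-driven (10x max signal) and resolved at
# fit time; np.inf here is the placeholder.
_DIFF_BOUNDS = (1e-6, 1e-2)
_S0_BOUNDS = (1e-12, np.inf)

_REGISTRY: Dict[str, ModelDefinition] = {}


def _register(defn: ModelDefinition) -> None:
    _REGISTRY[defn.model_id] = defn


_register(
    ModelDefinition(
        model_id="mono",
        free_params=("S0", "ADC"),
        report_params=("ADC",),
        signal=_sig_mono,
        jac=_jac_mono,
        default_bounds={"S0": _S0_BOUNDS, "ADC": _DIFF_BOUNDS},
    )
)
_register(
    ModelDefinition(
        model_id="adc100",
        free_params=("S0", "ADC100"),
        report_params=("ADC100",),
        signal=_sig_mono,
        jac=_jac_mono,
        default_bounds={"S0": _S0_BOUNDS, "ADC100": _DIFF_BOUNDS},
        min_b=100.0,
    )
)
_register(
    ModelDefinition(
        model_id="ivim",
        free_params=("S0", "f", "D", "Dstar"),
        report_params=("f", "D", "Dstar", "fDstar"),
        signal=_sig_ivim,
        jac=_jac_ivim,
        default_bounds={
            "S0": _S0_BOUNDS,
            "f": (0.0, 1.0),
            "D": _DIFF_BOUNDS,
            "Dstar": (3e-3, 5e-1),
        },
        derived={"fDstar": lambda th: th["f"] * th["Dstar"]},
    )
)
_register(
    ModelDefinition(
        model_id="stretched",
        free_params=("S0", "DDC_alpha", "alpha"),
        report_params=("DDC_alpha", "alpha"),
        signal=_sig_stretched,
        jac=_jac_stretched,
        default_bounds={"S0": _S0_BOUNDS, "DDC_alpha": _DIFF_BOUNDS, "alpha": (1e-2, 1.0)},
    )
)
_register(
    ModelDefinition(
        model_id="kurtosis",
        free_params=("S0", "DDC_K", "K"),
        report_params=("DDC_K", "K"),
        signal=_sig_kurtosis_printed,
        jac=_jac_kurtosis_printed,
        default_bounds={"S0": _S0_BOUNDS, "DDC_K": _DIFF_BOUNDS, "K": (0.0, 5e-3)},
        form="as_printed",
    )
)

_KURTOSIS_STANDARD = ModelDefinition(
    model_id="kurtosis",
    free_params=("S0", "DDC_K", "K"),
    report_params=("DDC_K", "K"),
    signal=_sig_kurtosis_standard,
        jac=_jac_kurtosis_standard,
    default_bounds={"S0": _S0_BOUNDS, "DDC_K": _DIFF_BOUNDS, "K": (0.0, 3.0)},
    form="standard",
)


def get_model(model_id: str, kurtosis_form: str = "as_printed") -> ModelDefinition:
    """Look up a model by its string id: mono, adc100, ivim, stretched, kurtosis."""
    if model_id == "kurtosis" and kurtosis_form == "standard":
        return _KURTOSIS_STANDARD
    if model_id == "kurtosis" and kurtosis_form not in ("as_printed", "standard"):
        raise ValueError(f"unknown kurtosis form: {kurtosis_form!r}")
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id!r}; known: {sorted(_REGISTRY)}"
        ) from None


def list_models() -> Tuple[str, ...]:
    return tuple(sorted(_REGISTRY))
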