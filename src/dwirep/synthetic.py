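"""Paired-visit digital DWI phantoms with known ground truth.

The generator emulates a test-retest cohort: each synthetic subject carries a
tumour-like elliptical ROI over a few contiguous slices, voxel-wise model
parameters drawn from heterogeneous distributions, and two "visits" whose
parameters differ by a multiplicative log-normal perturbation.  Magnitude
images receive Rician noise at a configurable SNR (S0 / sigma at b=0).

Perturbation convention: each visit's parameters are scaled independently by
exp(eps) with eps ~ Normal(0, retest_log_sd^2).  The log-difference between
visits then has variance 2*retest_log_sd^2, so the injected repeated-measures
coefficient of variation is, in closed form,

    CV_expected = 100 * sqrt(exp(retest_log_sd^2) - 1)  [percent]

which is how the repeatability statistics are validated against ground truth.

Everything is reproducible: equal (spec, protocol, seed) gives bit-identical
studies; per-subject RNG streams are spawned from the spec seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .signal_models import AcquisitionProtocol, ModelDefinition, get_model

__all__ = [
    "ParamDistribution",
    "PhantomSpec",
    "SubjectStudy",
    "PairedStudy",
    "default_distributions",
    "generate_phantom",
    "add_noise",
    "write_study",
]

#: Affine for all phantom volumes: 1.7 mm in-plane, 5 mm slices.
PHANTOM_AFFINE = np.diag([1.7, 1.7, 5.0, 1.0])


@dataclass(frozen=True)
class ParamDistribution:
    """Distribution of one model parameter across ROI voxels.

    family:
      constant   — every voxel equals ``loc``
      lognormal  — median ``loc``, log-sd ``scale``
      normal     — mean ``loc``, sd ``scale``
      uniform    — on [loc, scale]
    Samples are clipped to [clip_low, clip_high] when given, which keeps
    bounded parameters (f, alpha, K) on their model support.
    """

    family: str
    loc: float
    scale: float = 0.0
    clip_low: Optional[float] = None
    clip_high: Optional[float] = None

    def __post_init__(self):
        if self.family not in ("constant", "lognormal", "normal", "uniform"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "lognormal" and self.loc <= 0:
            raise ValueError("lognormal location (median) must be positive")
        if self.family == "uniform" and self.scale < self.loc:
            raise ValueError("uniform requires scale (high) >= loc (low)")

    def sample(self, rng: np.random.Generator, n: int, factor: float = 1.0) -> np.ndarray:
        """Draw n voxel values; ``factor`` scales the location multiplicatively
        (used for subject-level and visit-level effects)."""
        if self.family == "constant":
            out = np.full(n, self.loc * factor)
        elif self.family == "lognormal":
            out = self.loc * factor * np.exp(rng.normal(0.0, self.scale, n))
        elif self.family == "normal":
            out = rng.normal(self.loc * factor, self.scale, n)
        else:  # uniform
            out = rng.uniform(self.loc, self.scale, n) * factor
        return self.clip(out)

    def clip(self, values: np.ndarray) -> np.ndarray:
        if self.clip_low is not None or self.clip_high is not None:
            return np.clip(values, self.clip_low, self.clip_high)
        return values

    def quantile(self, q: np.ndarray) -> np.ndarray:
        """Population quantiles (unclipped); for convergence checks."""
        from scipy import stats

        q = np.asarray(q, dtype=float)
        if self.family == "constant":
            return np.full_like(q, self.loc)
        if self.family == "lognormal":
            return self.loc * np.exp(self.scale * stats.norm.ppf(q))
        if self.family == "normal":
            return stats.norm.ppf(q, loc=self.loc, scale=self.scale)
        return self.loc + q * (self.scale - self.loc)

    @property
    def support(self) -> Tuple[float, float]:
        lo, hi = -np.inf, np.inf
        if self.family == "constant":
            lo = hi = self.loc
        elif self.family == "lognormal":
            lo = 0.0
        elif self.family == "uniform":
            lo, hi = self.loc, self.scale
        if self.clip_low is not None:
            lo = max(lo, self.clip_low)
        if self.clip_high is not None:
            hi = min(hi, self.clip_high)
        return lo, hi


def default_distributions(model_id: str) -> Dict[str, ParamDistribution]:
    """Per-parameter voxel distributions at solid-tumour scale.

    Diffusion coefficients are log-normal with ~25% heterogeneity across the
    ROI; bounded parameters are clipped to their model support.
    """
    ln = ParamDistribution

    def diff_coef(median: float) -> ParamDistribution:
        # clips are the model bounds; at ~25% log-sd they are never active
        return ln("lognormal", median, 0.25, clip_low=1e-6, clip_high=1e-2)

    table: Dict[str, Dict[str, ParamDistribution]] = {
        "mono": {
            "S0": ln("constant", 1000.0),
            "ADC": diff_coef(1.35e-3),
        },
        "ivim": {
            "S0": ln("constant", 1000.0),
            "f": ln("lognormal", 0.09, 0.30, clip_high=0.6),
            "D": diff_coef(1.35e-3),
            "Dstar": ln("lognormal", 1.3e-2, 0.30, clip_low=3.5e-3, clip_high=0.4),
        },
        "stretched": {
            "S0": ln("constant", 1000.0),
            "DDC_alpha": diff_coef(1.5e-3),
            "alpha": ln("normal", 0.9, 0.05, clip_low=0.3, clip_high=1.0),
        },
        "kurtosis": {
            "S0": ln("constant", 1000.0),
            "DDC_K": diff_coef(1.78e-3),
            "K": ln("lognormal", 1.3e-3, 0.30, clip_high=4.5e-3),
        },
    }
    table["adc100"] = {"S0": table["mono"]["S0"], "ADC100": table["mono"]["ADC"]}
    try:
        return dict(table[model_id])
    except KeyError:
        raise KeyError(f"no default distributions for model {model_id!r}") from None


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic paired-visit cohort.

    ``snr`` is S0 / noise-sigma at b=0; ``None`` (or inf) disables noise.
    ``retest_log_sd`` is the per-visit multiplicative log-normal sd applied to
    every parameter except S0; ``subject_log_sd`` scatters each subject's
    parameter locations to mimic between-patient spread.  ``retest_scope``
    draws the visit perturbation once per subject-parameter ("subject",
    default) or per voxel ("voxel").
    """

    grid_shape: Tuple[int, int, int] = (24, 24, 5)
    roi_slices: int = 3
    model_id: str = "mono"
    param_distributions: Optional[Dict[str, ParamDistribution]] = None
    snr: Optional[float] = 50.0
    noise_model: str = "rician"
    retest_log_sd: float = 0.025
    subject_log_sd: float = 0.35
    retest_scope: str = "subject"
    n_subjects: int = 15
    roi_radius_frac: float = 0.35
    kurtosis_form: str = "as_printed"
    seed: int = 0

    def __post_init__(self):
        if self.snr is not None and not self.snr > 0:
            raise ValueError("snr must be positive (or None for noise-free)")
        if self.retest_log_sd < 0:
            raise ValueError("retest_log_sd must be non-negative")
        if self.subject_log_sd < 0:
            raise ValueError("subject_log_sd must be non-negative")
        if self.roi_slices < 1:
            raise ValueError("roi_slices must be >= 1")
        if self.roi_slices > self.grid_shape[2]:
            raise ValueError("roi_slices exceeds grid depth")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.retest_scope not in ("subject", "voxel"):
            raise ValueError(f"unknown retest scope {self.retest_scope!r}")

    @property
    def model(self) -> ModelDefinition:
        return get_model(self.model_id, kurtosis_form=self.kurtosis_form)

    def distributions(self) -> Dict[str, ParamDistribution]:
        dists = (
            dict(self.param_distributions)
            if self.param_distributions is not None
            else default_distributions(self.model_id)
        )
        model = self.model
        missing = [p for p in model.free_params if p not in dists]
        if missing:
            raise ValueError(f"missing distributions for parameters: {missing}")
        for name in model.free_params:
            lo, hi = model.default_bounds[name]
            slo, shi = dists[name].support
            if slo < lo - 1e-15 or shi > hi + 1e-15:
                raise ValueError(
                    f"distribution for parameter {name!r} (support [{slo:g}, {shi:g}]) "
                    f"violates model bounds [{lo:g}, {hi:g}]"
                )
        return dists

    def validate(self) -> None:
        self.distributions()

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.param_distributions is not None:
            d["param_distributions"] = {
                k: dataclasses.asdict(v) for k, v in self.param_distributions.items()
            }
        return d


@dataclass
class SubjectStudy:
    """One subject's paired acquisition: per-visit 4-D signal stacks
    (x, y, z, b), the shared ROI mask, and per-visit ground-truth maps."""

    subject_id: str
    visits: Dict[int, np.ndarray]  # visit -> (nx, ny, nz, n_b) signal
    mask: np.ndarray  # boolean (nx, ny, nz)
    truth: Dict[int, Dict[str, np.ndarray]]  # visit -> param -> 3-D map (NaN outside)
    seed: int


@dataclass
class PairedStudy:
    """A full synthetic cohort plus the protocol and spec that produced it."""

    subjects: List[SubjectStudy]
    protocol: AcquisitionProtocol
    spec: PhantomSpec

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def add_noise(signal, sigma: float, noise_model: str = "rician", rng=None):
    """Corrupt a signal with magnitude (Rician) or additive Gaussian noise.

    Rician: sqrt((S + n1)^2 + n2^2) with n1, n2 ~ Normal(0, sigma^2) — the
    magnitude of a complex signal with independent channel noise.  sigma=0
    returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(rng)
    n1 = rng.normal(0.0, sigma, signal.shape)
    if noise_model == "gaussian":
        return signal + n1
    if noise_model == "rician":
        n2 = rng.normal(0.0, sigma, signal.shape)
        return np.sqrt((signal + n1) ** 2 + n2**2)
    raise ValueError(f"unknown noise model {noise_model!r}")


def _roi_mask(spec: PhantomSpec) -> np.ndarray:
    """Elliptical in-plane ROI on the central ``roi_slices`` slices."""
    nx, ny, nz = spec.grid_shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rx = max(spec.roi_radius_frac * nx, 1.5)
    ry = max(spec.roi_radius_frac * ny * 0.8, 1.5)
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    inplane = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    z0 = (nz - spec.roi_slices) // 2
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for z in range(z0, z0 + spec.roi_slices):
        mask[:, :, z] = inplane
    return mask


def generate_phantom(spec: PhantomSpec, protocol: AcquisitionProtocol) -> PairedStudy:
    """Generate the paired-visit cohort described by ``spec``.

    For every ROI voxel, parameters are drawn from the spec distributions
    (subject-level location scatter applied first), each visit's parameters
    are perturbed by an independent multiplicative log-normal factor, the
    generating model is evaluated at all protocol b-values, and noise is
    added.  Ground-truth per-visit parameter maps (including derived ones,
    e.g. f*D*) are stored losslessly.
    """
    protocol.require_b0()
    dists = spec.distributions()
    model = spec.model
    b = protocol.b_array
    mask = _roi_mask(spec)
    flat_idx = np.where(mask.ravel())[0]
    n_vox = flat_idx.size

    root = np.random.SeedSequence(spec.seed)
    child_seqs = root.spawn(spec.n_subjects)
    sigma = 0.0
    if spec.snr is not None and np.isfinite(spec.snr):
        sigma = dists["S0"].loc / spec.snr

    perturbed = [p for p in model.free_params if p != "S0"]
    subjects: List[SubjectStudy] = []
    for i, seq in enumerate(child_seqs):
        rng = np.random.default_rng(seq)
        sub_seed = int(seq.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        # subject-level multiplicative scatter of parameter locations
        factors = {
            name: float(np.exp(rng.normal(0.0, spec.subject_log_sd))) for name in perturbed
        }
        base = {
            name: dists[name].sample(rng, n_vox, factors.get(name, 1.0))
            for name in model.free_params
        }
        visits: Dict[int, np.ndarray] = {}
        truth: Dict[int, Dict[str, np.ndarray]] = {}
        for visit in (1, 2):
            vox_params: Dict[str, np.ndarray] = {"S0": base["S0"]}
            for name in perturbed:
                if spec.retest_scope == "subject":
                    eps = rng.normal(0.0, spec.retest_log_sd)
                else:
                    eps = rng.normal(0.0, spec.retest_log_sd, n_vox)
                vox_params[name] = dists[name].clip(base[name] * np.exp(eps))
            theta = np.column_stack([vox_params[name] for name in model.free_params])
            signal = model.signal(theta, b)  # (n_vox, n_b)
            vol = np.zeros(spec.grid_shape + (len(b),), dtype=float)
            vol.reshape(-1, len(b))[flat_idx] = signal
            if sigma > 0:
                vol = add_noise(vol, sigma, spec.noise_model, rng)
            visits[visit] = vol
            maps: Dict[str, np.ndarray] = {}
            named = dict(vox_params)
            for dname, fn in model.derived.items():
                named[dname] = fn(named)
            for name, values in named.items():
                m = np.full(spec.grid_shape, np.nan)
                m.ravel()[flat_idx] = values
                maps[name] = m
            truth[visit] = maps
        subjects.append(
            SubjectStudy(
                subject_id=f"sub-{i + 1:02d}",
                visits=visits,
                mask=mask.copy(),
                truth=truth,
                seed=sub_seed,
            )
        )
    return PairedStudy(subjects=subjects, protocol=protocol, spec=spec)


def write_study(study: PairedStudy, directory) -> dict:
    """Write a PairedStudy to NIfTI volumes plus a JSON manifest.

    Layout: one volume per b-value per visit per subject
    (``sub-01_visit-1_b50.nii.gz``), one mask per subject, ground-truth maps
    as ``..._truth-<param>.nii.gz``, and ``manifest.json`` recording the
    protocol, spec, seed and every file-to-(subject, visit, b) association.
    """
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    b_values = list(study.protocol.b_values)

    def save(arr: np.ndarray, name: str) -> str:
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), PHANTOM_AFFINE)
        try:
            img.to_filename(str(directory / name))
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"failed writing {directory / name}: {exc}") from exc
        return name

    manifest: dict = {
        "protocol": {"b_values": b_values, "metadata": study.protocol.metadata},
        "spec": study.spec.to_jsonable(),
        "seed": study.spec.seed,
        "subjects": [],
    }
    for sub in study.subjects:
        entry: dict = {
            "subject_id": sub.subject_id,
            "seed": sub.seed,
            "mask": save(sub.mask.astype(np.float64), f"{sub.subject_id}_mask.nii.gz"),
            "volumes": [],
            "truth": [],
        }
        for visit, vol in sorted(sub.visits.items()):
            for j, bv in enumerate(b_values):
                name = f"{sub.subject_id}_visit-{visit}_b{int(round(bv))}.nii.gz"
                entry["volumes"].append(
                    {"file": save(vol[..., j], name), "visit": visit, "b": bv}
                )
        for visit, maps in sorted(sub.truth.items()):
            for pname, arr in sorted(maps.items()):
                name = f"{sub.subject_id}_visit-{visit}_truth-{pname}.nii.gz"
                entry["truth"].append(
                    {"file": save(arr, name), "visit": visit, "parameter": pname}
                )
        manifest["subjects"].append(entry)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
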