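"""End-to-end orchestration: simulate/read -> fit -> centiles -> repeatability.

A :class:`PipelineConfig` describes one run: the acquisition protocol, the
models to fit (default: adc100, ivim, stretched, kurtosis — the nine-parameter
reporting set ADC100, f, D, D*, fD*, DDC_alpha, alpha, DDC_K, K), either a
phantom spec (simulation mode) or an input directory (data mode), and a global
seed.  :func:`run_pipeline` produces per-subject centile tables, the CV-by-
centile profiles with confidence intervals, the median-comparison t-tests,
the correlation matrix of visit-averaged medians, and a JSON run manifest
recording config hash, seed, package versions and warning counts.

Reruns with the same config and seed are bit-identical for the deterministic
NLLS estimator, and reproducible given the seed for MCMC.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitConfig, fit_roi
from .histograms import CENTILES, CentileTable, centile_table, pool_roi
from .repeatability import (
    PairedCohort,
    compare_medians,
    cv_by_centile,
    cv_repeated,
    parameter_correlations,
)
from .signal_models import AcquisitionProtocol, get_model
from .synthetic import (
    PairedStudy,
    ParamDistribution,
    PhantomSpec,
    SubjectStudy,
    generate_phantom,
    write_study,
)

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "DEFAULT_MODELS",
    "run_pipeline",
    "read_dwi_study",
    "cohort_from_study",
    "cohort_to_centile_frame",
    "cohort_from_centile_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_MODELS: Tuple[str, ...] = ("adc100", "ivim", "stretched", "kurtosis")


@dataclass
class PipelineConfig:
    """One pipeline run: where data come from, what to fit, where output goes."""

    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    models: Tuple[str, ...] = DEFAULT_MODELS
    fit_configs: Dict[str, FitConfig] = field(default_factory=dict)
    phantom: Optional[PhantomSpec] = None
    input_dir: Optional[str] = None
    outdir: str = "dwirep_out"
    seed: int = 0
    estimator: str = "nlls"
    max_slices: int = 3
    variance_convention: str = "mean_subtracted"
    write_maps: bool = False
    write_volumes: bool = False

    def __post_init__(self):
        if self.phantom is None and self.input_dir is None:
            raise ValueError("config needs either a phantom spec or an input directory")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValueError(f"input directory does not exist: {self.input_dir}")
        for mid in self.models:
            get_model(mid)  # raises for unknown ids

    def fit_config(self, model_id: str) -> FitConfig:
        cfg = self.fit_configs.get(model_id)
        if cfg is None:
            cfg = FitConfig(model_id=model_id, estimator=self.estimator, seed=self.seed)
        return cfg

    def digest(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, outdir: Optional[str] = None,
                  seed: Optional[int] = None) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, outdir=outdir, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, outdir: Optional[str] = None,
                  seed: Optional[int] = None) -> "PipelineConfig":
        kwargs: dict = {}
        if "protocol" in raw:
            p = raw["protocol"]
            kwargs["protocol"] = AcquisitionProtocol(
                tuple(p["b_values"]), p.get("metadata", {})
            )
        if "models" in raw:
            kwargs["models"] = tuple(raw["models"])
        if "fit_configs" in raw:
            kwargs["fit_configs"] = {
                mid: FitConfig(model_id=mid, **cfg) for mid, cfg in raw["fit_configs"].items()
            }
        if "phantom" in raw and raw["phantom"] is not None:
            kwargs["phantom"] = phantom_spec_from_dict(raw["phantom"])
        for key in ("input_dir", "outdir", "seed", "estimator", "max_slices",
                    "variance_convention", "write_maps", "write_volumes"):
            if key in raw:
                kwargs[key] = raw[key]
        if outdir is not None:
            kwargs["outdir"] = outdir
        if seed is not None:
            kwargs["seed"] = seed
            if kwargs.get("phantom") is not None:
                kwargs["phantom"] = dataclasses.replace(kwargs["phantom"], seed=seed)
        return cls(**kwargs)


def phantom_spec_from_dict(raw: dict) -> PhantomSpec:
    raw = dict(raw)
    if raw.get("param_distributions"):
        raw["param_distributions"] = {
            name: ParamDistribution(**d) for name, d in raw["param_distributions"].items()
        }
    if "grid_shape" in raw:
        raw["grid_shape"] = tuple(raw["grid_shape"])
    return PhantomSpec(**raw)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class ReportBundle:
    """Everything one pipeline run produces, in memory plus on disk."""

    cohort: PairedCohort
    centiles: pd.DataFrame
    cv_by_centile: pd.DataFrame
    cv_median_table: pd.DataFrame
    median_ttests: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict
    outdir: Path


# ---------------------------------------------------------------------------
# Reading studies from disk


def _read_nifti(path: Path) -> np.ndarray:
    import nibabel as nib

    try:
        return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    except Exception as exc:
        raise OSError(f"failed reading NIfTI {path}: {exc}") from exc


def _binarize_mask(arr: np.ndarray, path: Path) -> np.ndarray:
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(
            f"mask {path} has non-binary values {uniq[:5]}; expected 0/1"
        )
    return arr > 0.5


def read_dwi_study(directory, protocol: Optional[AcquisitionProtocol] = None) -> PairedStudy:
    """Read a paired-visit study written by :func:`dwirep.synthetic.write_study`.

    The JSON manifest is authoritative for the b-value/file association; when
    absent, filenames matching ``*_visit-<v>_b<value>.nii*`` are used.  File
    listing order never matters.  Geometry mismatches, missing b-values and
    non-binary masks raise descriptive errors.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if protocol is None:
            protocol = AcquisitionProtocol(
                tuple(manifest["protocol"]["b_values"]),
                manifest["protocol"].get("metadata", {}),
            )
        subject_entries = manifest["subjects"]
    else:
        manifest = None
        if protocol is None:
            raise ValueError(f"no manifest.json in {directory}: a protocol is required")
        subject_entries = _entries_from_filenames(directory)

    b_values = protocol.b_values
    subjects: List[SubjectStudy] = []
    for entry in subject_entries:
        sid = entry["subject_id"]
        mask_arr = _read_nifti(directory / entry["mask"])
        mask = _binarize_mask(mask_arr, directory / entry["mask"])
        by_key: Dict[Tuple[int, float], Path] = {}
        for vol in entry["volumes"]:
            key = (int(vol["visit"]), float(vol["b"]))
            if key in by_key:
                raise ValueError(
                    f"ambiguous b-value association for subject {sid}: "
                    f"visit {key[0]}, b={key[1]:g} appears twice"
                )
            by_key[key] = directory / vol["file"]
        visits: Dict[int, np.ndarray] = {}
        for visit in (1, 2):
            stack = []
            for bv in b_values:
                path = by_key.get((visit, float(bv)))
                if path is None:
                    raise ValueError(
                        f"subject {sid}, visit {visit}: missing volume for b={bv:g}"
                    )
                arr = _read_nifti(path)
                if arr.shape != mask.shape:
                    raise ValueError(
                        f"geometry mismatch: {path} has shape {arr.shape}, "
                        f"mask has {mask.shape}"
                    )
                stack.append(arr)
            visits[visit] = np.stack(stack, axis=-1)
        truth: Dict[int, Dict[str, np.ndarray]] = {}
        for t in entry.get("truth", []):
            truth.setdefault(int(t["visit"]), {})[t["parameter"]] = _read_nifti(
                directory / t["file"]
            )
        subjects.append(SubjectStudy(sid, visits, mask, truth, int(entry.get("seed", 0))))

    spec = None
    if manifest is not None and "spec" in manifest:
        try:
            spec = phantom_spec_from_dict(manifest["spec"])
        except (TypeError, ValueError):  # foreign manifests need not carry a spec
            spec = None
    if spec is None:
        spec = PhantomSpec(grid_shape=subjects[0].mask.shape, n_subjects=len(subjects))
    return PairedStudy(subjects=subjects, protocol=protocol, spec=spec)


def _entries_from_filenames(directory: Path) -> List[dict]:
    """Fallback ``sub-XX_visit-V_b<value>`` filename convention."""
    import re

    pattern = re.compile(r"^(?P<sub>.+)_visit-(?P<visit>\d+)_b(?P<b>[0-9.]+)\.nii(\.gz)?$")
    volumes: Dict[str, List[dict]] = {}
    masks: Dict[str, str] = {}
    for path in sorted(directory.iterdir()):
        m = pattern.match(path.name)
        if m:
            volumes.setdefault(m.group("sub"), []).append(
                {"file": path.name, "visit": int(m.group("visit")), "b": float(m.group("b"))}
            )
        elif path.name.endswith(("_mask.nii.gz", "_mask.nii")):
            masks[path.name.split("_mask.nii")[0]] = path.name
    entries = []
    for sub in sorted(volumes):
        if sub not in masks:
            raise ValueError(f"no mask file found for subject {sub!r}")
        entries.append(
            {"subject_id": sub, "mask": masks[sub], "volumes": volumes[sub], "truth": []}
        )
    if not entries:
        raise ValueError(f"no DWI volumes found in {directory}")
    return entries


# ---------------------------------------------------------------------------
# Fitting a whole study into a cohort


def cohort_from_study(study: PairedStudy, config: PipelineConfig,
                      maps_out: Optional[Path] = None) -> Tuple[PairedCohort, dict]:
    """Fit every subject/visit/model and build the paired centile cohort.

    Returns the cohort plus a counters dict (failed fits, clipped fits, NaN
    voxels dropped from pooling).
    """
    tables: List[CentileTable] = []
    counters = {"n_failed_fits": 0, "n_clipped_fits": 0}
    for sub in study.subjects:
        for visit, vol in sorted(sub.visits.items()):
            for mid in config.models:
                base = config.fit_config(mid)
                # per-(subject, model) seed keeps MCMC streams independent
                mid_tag = int.from_bytes(hashlib.sha256(mid.encode()).digest()[:4], "big")
                fit_seed = int(
                    np.random.SeedSequence(
                        entropy=(config.seed, sub.seed, visit, mid_tag)
                    ).generate_state(1)[0]
                ) % (2**31)
                cfg = dataclasses.replace(base, seed=fit_seed)
                maps = fit_roi(vol, sub.mask, study.protocol, cfg)
                prov = next(iter(maps.values())).provenance
                counters["n_failed_fits"] += int(prov["n_failed"])
                counters["n_clipped_fits"] += int(prov["n_clipped"])
                model = cfg.model
                if maps_out is not None:
                    _write_maps(maps, maps_out, sub.subject_id, visit)
                for pname in model.report_params:
                    sample = pool_roi(
                        maps[pname], max_slices=config.max_slices,
                        subject_id=sub.subject_id, visit=visit,
                    )
                    tables.append(centile_table(sample))
    cohort = PairedCohort.from_tables(tables)
    return cohort, counters


def _write_maps(maps, outdir: Path, subject_id: str, visit: int) -> None:
    import nibabel as nib

    from .synthetic import PHANTOM_AFFINE

    outdir.mkdir(parents=True, exist_ok=True)
    for name, pmap in maps.items():
        img = nib.Nifti1Image(pmap.values, PHANTOM_AFFINE)
        img.header.extensions.append(
            nib.nifti1.Nifti1Extension("comment", json.dumps(_jsonable(pmap.provenance)).encode())
        )
        img.to_filename(str(outdir / f"{subject_id}_visit-{visit}_{pmap.model_id}_{name}.nii.gz"))
        sidecar = outdir / f"{subject_id}_visit-{visit}_{pmap.model_id}_{name}.json"
        sidecar.write_text(json.dumps(_jsonable(pmap.provenance), indent=2))


# ---------------------------------------------------------------------------
# Tables


def cohort_to_centile_frame(cohort: PairedCohort) -> pd.DataFrame:
    """Wide table: one row per subject-visit-parameter, columns p0..p100."""
    rows = []
    for (sub, par, visit), table in sorted(cohort.tables.items()):
        row = {"subject_id": sub, "parameter": par, "visit": visit,
               "n_voxels": table.n_voxels}
        row.update({f"p{p}": table.centiles[p] for p in CENTILES})
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_centile_frame(frame: pd.DataFrame,
                              subgroups: Optional[Dict[str, str]] = None) -> PairedCohort:
    tables = []
    pcols = [f"p{p}" for p in CENTILES]
    for _, row in frame.iterrows():
        tables.append(
            CentileTable(
                parameter=row["parameter"],
                centiles=row[pcols].to_numpy(dtype=float),
                subject_id=str(row["subject_id"]),
                visit=int(row["visit"]),
                n_voxels=int(row.get("n_voxels", 0)),
            )
        )
    return PairedCohort.from_tables(tables, subgroups)


def cv_centile_frame(cohort: PairedCohort, convention: str) -> pd.DataFrame:
    rows = []
    for par in cohort.parameters:
        for res in cv_by_centile(cohort, par, convention=convention):
            rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def cv_median_frame(cohort: PairedCohort, convention: str) -> pd.DataFrame:
    """Median-CV table: one row per parameter (and per subgroup when labelled)."""
    groups: List[Tuple[str, PairedCohort]] = [("full", cohort)]
    labels = sorted(set(cohort.subgroups.values()))
    if len(labels) > 1:
        groups += [(lab, cohort.filter(lab)) for lab in labels]
    rows = []
    for label, grp in groups:
        for par in grp.parameters:
            v1, v2 = grp.medians(par)
            res = cv_repeated(v1, v2, parameter=par, centile=50, convention=convention)
            rows.append(
                {"parameter": par, "subgroup": label, "cv_percent": res.cv_percent,
                 "ci_low": res.ci_low, "ci_high": res.ci_high, "n_pairs": res.n_pairs}
            )
    return pd.DataFrame(rows)


def ttest_frame(cohort: PairedCohort) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(compare_medians(cohort, par)) for par in cohort.parameters]
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run simulate/read -> fit -> centiles -> repeatability and write reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.phantom is not None:
        logger.info("simulation mode: generating %d-subject phantom cohort",
                    config.phantom.n_subjects)
        study = generate_phantom(config.phantom, config.protocol)
        if config.write_volumes:
            write_study(study, outdir / "study")
    else:
        logger.info("data mode: reading study from %s", config.input_dir)
        study = read_dwi_study(config.input_dir, config.protocol)

    maps_out = outdir / "maps" if config.write_maps else None
    cohort, counters = cohort_from_study(study, config, maps_out=maps_out)

    centiles = cohort_to_centile_frame(cohort)
    cv_centiles = cv_centile_frame(cohort, config.variance_convention)
    cv_medians = cv_median_frame(cohort, config.variance_convention)
    ttests = ttest_frame(cohort)
    corr = parameter_correlations(cohort).to_dataframe()

    centiles.to_csv(outdir / "centiles.csv", index=False)
    cv_centiles.to_csv(outdir / "cv_by_centile.csv", index=False)
    cv_medians.to_csv(outdir / "cv_median_table.csv", index=False)
    ttests.to_csv(outdir / "median_ttests.csv", index=False)
    corr.to_csv(outdir / "correlations.csv")

    n_expected = 101 * len(cohort.parameters)
    manifest = {
        "dwirep_version": __version__,
        "numpy_version": np.__version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_subjects": cohort.n_subjects,
        "parameters": list(cohort.parameters),
        "estimator": config.estimator,
        "variance_convention": config.variance_convention,
        "warnings": {
            **counters,
            "n_skipped_centiles": int(n_expected - len(cv_centiles)),
        },
        "outputs": ["centiles.csv", "cv_by_centile.csv", "cv_median_table.csv",
                    "median_ttests.csv", "correlations.csv"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ReportBundle(
        cohort=cohort,
        centiles=centiles,
        cv_by_centile=cv_centiles,
        cv_median_table=cv_medians,
        median_ttests=ttests,
        correlations=corr,
        manifest=manifest,
        outdir=outdir,
    )
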