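"""Test-retest repeatability statistics.

The central quantity is the repeated-measures coefficient of variation on the
log scale: with paired measurements (v1_i, v2_i) over subjects i, the
log-differences d_i = ln(v2_i) - ln(v1_i) have variance sigma^2 and

    CV = 100% * sqrt(exp(sigma^2 / 2) - 1).

``sigma^2`` is by default the mean-subtracted sample variance of the d_i
(n-1 denominator); a zero-mean convention (sum d_i^2 / n) is available, under
which a systematic multiplicative shift between visits inflates the CV rather
than vanishing into the mean.  Confidence intervals come from the chi-square
pivot for a normal-theory variance, mapped through the CV formula (a
percentile bootstrap is available as an alternative).

Also here: the paired t-test comparing visit medians, the per-centile CV
profile across the 0th-100th histogram grid, and the Pearson correlation
matrix of visit-averaged medians across parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .histograms import CENTILES, CentileTable

__all__ = [
    "CVResult",
    "MedianComparison",
    "CorrelationMatrix",
    "PairedCohort",
    "cv_from_sigma2",
    "cv_repeated",
    "cv_confidence_interval",
    "cv_by_centile",
    "compare_medians",
    "parameter_correlations",
]

logger = logging.getLogger(__name__)


def cv_from_sigma2(sigma2: float) -> float:
    """Map a log-difference variance to a percent CV: 100*sqrt(exp(s2/2)-1)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if sigma2 > 1400.0:  # expm1 overflows float64; the CV is effectively infinite
        return float("inf")
    return 100.0 * float(np.sqrt(np.expm1(sigma2 / 2.0)))


@dataclass
class CVResult:
    """Repeated-measures CV for one parameter at one centile."""

    parameter: str
    centile: Optional[int]
    sigma2: float
    cv_percent: float
    ci_low: float
    ci_high: float
    n_pairs: int
    convention: str = "mean_subtracted"


@dataclass
class MedianComparison:
    """Paired t-test on per-subject medians between the two visits."""

    parameter: str
    t: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass
class CorrelationMatrix:
    """Pearson correlations of visit-averaged medians across parameters."""

    parameters: Tuple[str, ...]
    rho: np.ndarray

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        k = len(self.parameters)
        if self.rho.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")

    def get(self, a: str, b: str) -> float:
        i, j = self.parameters.index(a), self.parameters.index(b)
        return float(self.rho[i, j])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=self.parameters, columns=self.parameters)


def _log_differences(visit1, visit2, parameter: str = "") -> np.ndarray:
    v1 = np.asarray(visit1, dtype=float)
    v2 = np.asarray(visit2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("paired visits differ in length")
    if v1.size < 2:
        raise ValueError("need at least 2 pairs")
    for label, v in (("visit 1", v1), ("visit 2", v2)):
        bad = np.flatnonzero(~(v > 0))
        if bad.size:
            raise ValueError(
                f"non-positive value for {parameter or 'parameter'} in {label} "
                f"(pair index {bad[0]}); log-transform undefined"
            )
    return np.log(v2) - np.log(v1)


def _sigma2(d: np.ndarray, convention: str) -> float:
    if convention == "mean_subtracted":
        return float(np.var(d, ddof=1))
    if convention == "zero_mean":
        return float(np.mean(d**2))
    raise ValueError(f"unknown variance convention {convention!r}")


def cv_confidence_interval(sigma2: float, n_pairs: int, level: float = 0.95,
                           convention: str = "mean_subtracted") -> Tuple[float, float]:
    """Chi-square CI for the CV, in percent.

    The pivot (df * s^2 / sigma^2) ~ chi-square(df) gives the interval
    [df*s^2/chi2_hi, df*s^2/chi2_lo] for sigma^2, mapped through the CV
    formula.  df = n-1 for the mean-subtracted convention, n for zero-mean.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    df = n_pairs - 1 if convention == "mean_subtracted" else n_pairs
    alpha = 1.0 - level
    chi_lo = stats.chi2.ppf(alpha / 2.0, df)
    chi_hi = stats.chi2.ppf(1.0 - alpha / 2.0, df)
    s2_low = df * sigma2 / chi_hi
    s2_high = df * sigma2 / chi_lo
    return cv_from_sigma2(s2_low), cv_from_sigma2(s2_high)


def _bootstrap_ci(d: np.ndarray, convention: str, level: float, n_boot: int,
                  seed: int) -> Tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = d.size
    cvs = np.empty(n_boot)
    for k in range(n_boot):
        cvs[k] = cv_from_sigma2(_sigma2(d[rng.integers(0, n, n)], convention))
    lo, hi = np.percentile(cvs, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def cv_repeated(visit1, visit2, parameter: str = "", centile: Optional[int] = None,
                convention: str = "mean_subtracted", level: float = 0.95,
                ci_method: str = "chi2", n_boot: int = 2000, seed: int = 0) -> CVResult:
    """Repeated-measures CV (percent) with its confidence interval.

    ``visit1``/``visit2`` are per-subject paired values (all positive).
    """
    d = _log_differences(visit1, visit2, parameter)
    sigma2 = _sigma2(d, convention)
    cv = cv_from_sigma2(sigma2)
    if ci_method == "chi2":
        ci_low, ci_high = cv_confidence_interval(sigma2, d.size, level, convention)
    elif ci_method == "bootstrap":
        ci_low, ci_high = _bootstrap_ci(d, convention, level, n_boot, seed)
        ci_low, ci_high = min(ci_low, cv), max(ci_high, cv)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return CVResult(
        parameter=parameter,
        centile=centile,
        sigma2=sigma2,
        cv_percent=cv,
        ci_low=ci_low,
        ci_high=ci_high,
        n_pairs=int(d.size),
        convention=convention,
    )


@dataclass
class PairedCohort:
    """Centile tables for both visits of every subject and parameter.

    ``tables[(subject_id, parameter, visit)]`` -> :class:`CentileTable`.
    Optional ``subgroups`` maps subject ids to labels (e.g. anatomical site)
    for subgroup analyses via :meth:`filter`.
    """

    tables: Dict[Tuple[str, str, int], CentileTable]
    subjects: Tuple[str, ...]
    parameters: Tuple[str, ...]
    subgroups: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.subjects) < 2:
            raise ValueError("cohort needs at least 2 subjects")
        for sub in self.subjects:
            for par in self.parameters:
                for visit in (1, 2):
                    if (sub, par, visit) not in self.tables:
                        raise ValueError(
                            f"missing centile table: subject={sub!r}, parameter={par!r}, "
                            f"visit={visit}"
                        )

    @classmethod
    def from_tables(cls, tables: Sequence[CentileTable],
                    subgroups: Optional[Dict[str, str]] = None) -> "PairedCohort":
        index = {(t.subject_id, t.parameter, t.visit): t for t in tables}
        subjects = tuple(dict.fromkeys(t.subject_id for t in tables))
        parameters = tuple(dict.fromkeys(t.parameter for t in tables))
        return cls(index, subjects, parameters, subgroups or {})

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def centile_values(self, parameter: str, centile: int) -> Tuple[np.ndarray, np.ndarray]:
        v1 = np.array([self.tables[(s, parameter, 1)].at(centile) for s in self.subjects])
        v2 = np.array([self.tables[(s, parameter, 2)].at(centile) for s in self.subjects])
        return v1, v2

    def medians(self, parameter: str) -> Tuple[np.ndarray, np.ndarray]:
        return self.centile_values(parameter, 50)

    def filter(self, label: str) -> "PairedCohort":
        keep = tuple(s for s in self.subjects if self.subgroups.get(s) == label)
        if len(keep) < 2:
            raise ValueError(f"subgroup {label!r} has fewer than 2 subjects")
        tables = {k: v for k, v in self.tables.items() if k[0] in keep}
        return PairedCohort(tables, keep, self.parameters,
                            {s: label for s in keep})


def cv_by_centile(cohort: PairedCohort, parameter: str,
                  convention: str = "mean_subtracted", level: float = 0.95) -> List[CVResult]:
    """CV profile across the 0th-100th centile grid for one parameter.

    Centiles where any subject has a non-positive value (possible for f,
    alpha, K near their lower limits) are skipped with a logged warning.
    """
    results: List[CVResult] = []
    for p in CENTILES:
        v1, v2 = cohort.centile_values(parameter, int(p))
        if np.any(v1 <= 0) or np.any(v2 <= 0):
            logger.warning(
                "skipping centile %d for %s: non-positive value in cohort", p, parameter
            )
            continue
        results.append(
            cv_repeated(v1, v2, parameter=parameter, centile=int(p),
                        convention=convention, level=level)
        )
    return results


def compare_medians(cohort: PairedCohort, parameter: str) -> MedianComparison:
    """Two-sided paired t-test on the per-subject medians (raw scale).

    A zero-variance set of differences is degenerate for the t statistic and
    is reported as t=0, p=1 with the degenerate flag set.
    """
    v1, v2 = cohort.medians(parameter)
    diff = v2 - v1
    n = diff.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.var(diff, ddof=1) == 0.0:
        return MedianComparison(parameter, t=0.0, df=n - 1, p_value=1.0, degenerate=True)
    t, p = stats.ttest_rel(v2, v1)
    return MedianComparison(parameter, t=float(t), df=n - 1, p_value=float(p))


def parameter_correlations(cohort: PairedCohort,
                           parameters: Optional[Sequence[str]] = None) -> CorrelationMatrix:
    """Pearson correlation of visit-averaged medians across subjects.

    For each subject and parameter the two visit medians are averaged; the
    matrix is the pairwise Pearson rho of those averages across subjects.
    Parameters constant across the cohort have undefined correlations,
    reported as NaN off the diagonal.
    """
    params = tuple(parameters) if parameters is not None else cohort.parameters
    if cohort.n_subjects < 3:
        raise ValueError("correlations need at least 3 subjects")
    k = len(params)
    averaged = np.empty((k, cohort.n_subjects))
    for i, par in enumerate(params):
        v1, v2 = cohort.medians(par)
        averaged[i] = (v1 + v2) / 2.0
    rho = np.eye(k)
    sd = averaged.std(axis=1)
    for i in range(k):
        for j in range(i + 1, k):
            if sd[i] == 0 or sd[j] == 0:
                rho[i, j] = rho[j, i] = np.nan
            else:
                xi = averaged[i] - averaged[i].mean()
                xj = averaged[j] - averaged[j].mean()
                rho[i, j] = rho[j, i] = float(
                    np.clip((xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj)), -1.0, 1.0)
                )
    return CorrelationMatrix(parameters=params, rho=rho)
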