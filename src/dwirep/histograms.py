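"""ROI pooling and centile tables.

Voxel values from the (up to) three mask-bearing slices nearest the mask's
centre of mass are pooled into one sample per subject-visit-parameter, and
the 0th-100th integer percentiles computed by linear interpolation between
order statistics (numpy's default, the "type 7" rule).  The 50th centile of
the table is, by construction, the sample median used by the repeatability
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fitting import ParameterMap

__all__ = ["ROISample", "CentileTable", "pool_roi", "centile_table", "CENTILES"]

logger = logging.getLogger(__name__)

#: The integer percentile grid 0..100.
CENTILES = np.arange(101)


@dataclass
class ROISample:
    """Pooled in-mask voxel values for one parameter, subject and visit."""

    parameter: str
    values: np.ndarray
    subject_id: str = ""
    visit: int = 0
    n_slices: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError(
                f"empty ROI sample (subject={self.subject_id!r}, parameter={self.parameter!r})"
            )
        if np.isnan(self.values).any():
            raise ValueError("ROISample must not retain NaN values")

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)


@dataclass
class CentileTable:
    """Values of one parameter at integer percentiles 0..100."""

    parameter: str
    centiles: np.ndarray
    subject_id: str = ""
    visit: int = 0
    n_voxels: int = 0

    def __post_init__(self):
        self.centiles = np.asarray(self.centiles, dtype=float)
        if self.centiles.shape != (101,):
            raise ValueError("centile table must have 101 entries (0th-100th)")
        if np.any(np.diff(self.centiles) < 0):
            raise ValueError("centiles must be monotone non-decreasing")

    @property
    def median(self) -> float:
        return float(self.centiles[50])

    def at(self, p: int) -> float:
        return float(self.centiles[int(p)])


def _select_slices(mask: np.ndarray, max_slices: int) -> np.ndarray:
    """Indices (slice axis = last) of the mask slices nearest the mask's
    centre of mass; ties break toward the inferior (lower-index) slice."""
    counts = mask.sum(axis=(0, 1))
    present = np.flatnonzero(counts)
    if present.size <= max_slices:
        return present
    com = float((present * counts[present]).sum() / counts[present].sum())
    # sort by distance to the centre of mass, then by slice index (inferior first)
    order = sorted(present, key=lambda z: (abs(z - com), z))
    return np.sort(np.asarray(order[:max_slices]))


def pool_roi(pmap: ParameterMap, mask: Optional[np.ndarray] = None, max_slices: int = 3,
             subject_id: str = "", visit: int = 0) -> ROISample:
    """Pool in-mask voxel values from at most ``max_slices`` central slices.

    NaN voxels inside the mask (failed fits) are excluded with a logged
    warning.  An empty intersection raises, naming the subject/parameter.
    """
    mask = pmap.mask if mask is None else np.asarray(mask).astype(bool)
    if mask.shape != pmap.values.shape:
        raise ValueError("mask geometry does not match the parameter map")
    slices = _select_slices(mask, max_slices)
    if slices.size == 0:
        raise ValueError(
            f"mask is empty (subject={subject_id!r}, parameter={pmap.parameter!r})"
        )
    selected = np.zeros_like(mask)
    selected[:, :, slices] = mask[:, :, slices]
    values = pmap.values[selected]
    n_nan = int(np.isnan(values).sum())
    if n_nan:
        logger.warning(
            "dropping %d NaN voxel(s) inside ROI (subject=%s, parameter=%s)",
            n_nan, subject_id, pmap.parameter,
        )
        values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError(
            f"no usable voxels in ROI (subject={subject_id!r}, parameter={pmap.parameter!r})"
        )
    return ROISample(
        parameter=pmap.parameter,
        values=values,
        subject_id=subject_id,
        visit=visit,
        n_slices=int(slices.size),
    )


def centile_table(sample: ROISample) -> CentileTable:
    """Integer-percentile table of the pooled sample (linear interpolation)."""
    if sample.n_voxels < 2:
        raise ValueError("centile table needs at least 2 voxels")
    values = np.percentile(sample.values, CENTILES)
    return CentileTable(
        parameter=sample.parameter,
        centiles=values,
        subject_id=sample.subject_id,
        visit=sample.visit,
        n_voxels=sample.n_voxels,
    )
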