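"""Dose grids, structure masks, exact cumulative DVHs and plan QA.

A treatment plan is represented by one or two :class:`DoseGrid` objects
(the RBE-weighted dose computed under a biophysical model, LEM-I or MKM,
on a regular voxel grid) plus boolean :class:`StructureMask` objects on
the same grid (CTV1, CTV2, organs at risk).

The cumulative dose-volume histogram (:class:`CumulativeDVH`) is built by
*exact voxel counting* at the unique voxel doses, not by fixed-width
binning: the isovolumetric conversion inverts the DVH, and exact counting
makes the brute-force voxel-count oracle an equality test rather than an
approximation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    ConfigurationError,
    DomainError,
    EmptyStructureError,
    GeometryError,
)

logger = logging.getLogger(__name__)

MODEL_TAGS = ("LEM", "MKM")

_DVOL_RE = re.compile(r"^D(\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class DoseGrid:
    """A 3-D scalar field of *total* RBE-weighted dose in Gy (RBE).

    Parameters
    ----------
    values
        3-D array of total dose, Gy (RBE); finite and non-negative.
    spacing
        Voxel edge lengths in mm, one per array axis.
    origin
        Physical position of the first voxel centre, mm.
    n_fractions
        Number of fractions the total dose is delivered in.  The
        per-fraction dose is always derived as ``values / n_fractions``
        and never stored separately.
    model_tag
        Which biophysical model produced the RBE weighting: ``"LEM"`` or
        ``"MKM"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_fractions: int = 1
    model_tag: str = "LEM"
    patient_id: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 3:
            raise GeometryError(f"dose grid must be 3-D, got {vals.ndim}-D")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise DomainError("dose values must be finite and >= 0")
        object.__setattr__(self, "values", vals)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise DomainError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if int(self.n_fractions) < 1:
            raise DomainError("n_fractions must be >= 1")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        if self.model_tag not in MODEL_TAGS:
            raise ConfigurationError(
                f"model_tag must be one of {MODEL_TAGS}, got {self.model_tag!r}"
            )

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3 (1 cc = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def fraction_values(self) -> np.ndarray:
        """Per-fraction dose at every voxel, Gy (RBE)."""
        return self.values / self.n_fractions


@dataclass(frozen=True)
class StructureMask:
    """Boolean voxel mask of one anatomical structure, congruent with a DoseGrid."""

    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.dtype != bool:
            vals = vals.astype(bool)
        if vals.ndim != 3:
            raise GeometryError(f"structure mask must be 3-D, got {vals.ndim}-D")
        object.__setattr__(self, "values", vals)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def is_empty(self) -> bool:
        return self.voxel_count == 0


def _check_congruent(grid: DoseGrid, mask: StructureMask) -> None:
    if grid.values.shape != mask.values.shape:
        raise GeometryError(
            f"mask '{mask.name}' shape {mask.values.shape} does not match "
            f"grid shape {grid.values.shape}"
        )


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative dose-volume histogram of one structure.

    ``dose_levels`` are the sorted unique voxel doses inside the mask
    (ascending, Gy (RBE)); ``volumes[i]`` is the absolute volume in cc
    receiving at least ``dose_levels[i]``.  Volumes are strictly
    decreasing, ``volumes[0]`` is the total structure volume when the
    minimum voxel dose is the first level, and the volume above the
    maximum voxel dose is zero.
    """

    dose_levels: np.ndarray
    volumes: np.ndarray
    total_volume: float
    structure_name: str = ""

    def __post_init__(self) -> None:
        levels = np.asarray(self.dose_levels, dtype=np.float64)
        vols = np.asarray(self.volumes, dtype=np.float64)
        if levels.ndim != 1 or levels.shape != vols.shape or levels.size == 0:
            raise DomainError("dose_levels and volumes must be matching non-empty 1-D arrays")
        if np.any(np.diff(levels) <= 0):
            raise DomainError("dose_levels must be strictly increasing")
        if np.any(np.diff(vols) > 0):
            raise DomainError("volumes must be non-increasing in dose")
        object.__setattr__(self, "dose_levels", levels)
        object.__setattr__(self, "volumes", vols)
        object.__setattr__(self, "total_volume", float(self.total_volume))

    # -- evaluation ---------------------------------------------------------

    def volume_at_dose(self, dose: float, *, interpolate: bool = False) -> float:
        """Absolute volume (cc) receiving at least ``dose``.

        By default this is the exact step function of the voxel counts:
        the volume equals ``count(voxels >= dose) * voxel volume``.  With
        ``interpolate=True`` the piecewise-linear inverse of
        :meth:`dose_at_volume` is evaluated instead, which is the
        self-consistent choice when the result is fed back into
        ``dose_at_volume`` on a second DVH (isovolumetric matching).
        """
        if dose < 0:
            raise DomainError(f"dose must be >= 0, got {dose}")
        levels, vols = self.dose_levels, self.volumes
        if dose <= levels[0]:
            # every masked voxel receives at least the minimum voxel dose
            return float(self.total_volume)
        if interpolate:
            if dose > levels[-1]:
                return 0.0
            return float(np.interp(dose, levels, vols))
        idx = int(np.searchsorted(levels, dose, side="left"))
        if idx >= levels.size:
            return 0.0
        return float(vols[idx])

    def dose_at_volume(self, volume: float) -> float:
        """Largest dose covering ``volume`` cc, Gy (RBE).

        Returns the largest dose level D whose covered volume is at least
        the query, with linear interpolation between adjacent distinct
        voxel-dose levels when the query falls strictly between two step
        values; ties resolve toward the higher dose.  Queries smaller than
        the single-voxel step at the maximum dose return the maximum dose.
        """
        if volume <= 0 or volume > self.total_volume:
            raise DomainError(
                f"volume must be in (0, {self.total_volume}] cc, got {volume}"
            )
        # volumes descending vs levels ascending: interpolate on reversed axes
        return float(np.interp(volume, self.volumes[::-1], self.dose_levels[::-1]))

    @property
    def min_dose(self) -> float:
        return float(self.dose_levels[0])

    @property
    def max_dose(self) -> float:
        return float(self.dose_levels[-1])


def compute_cumulative_dvh(grid: DoseGrid, mask: StructureMask) -> CumulativeDVH:
    """Exact cumulative DVH of ``mask`` on ``grid`` by voxel counting.

    The dose levels are the sorted unique masked voxel doses; the volume
    at each level is the number of masked voxels at or above it times the
    voxel volume in cc.
    """
    _check_congruent(grid, mask)
    if mask.is_empty:
        raise EmptyStructureError(mask.name or "<unnamed>")
    doses = grid.values[mask.values]
    levels, counts = np.unique(doses, return_counts=True)
    # cumulative count of voxels >= each level
    ge_counts = np.cumsum(counts[::-1])[::-1]
    vcc = grid.voxel_volume_cc
    return CumulativeDVH(
        dose_levels=levels,
        volumes=ge_counts * vcc,
        total_volume=float(doses.size) * vcc,
        structure_name=mask.name,
    )


def expand_shell(
    ctv: StructureMask,
    spacing: Sequence[float],
    margin_mm: float = 20.0,
) -> StructureMask:
    """Voxels outside the CTV within ``margin_mm`` of it (Euclidean, physical).

    The shell is the set of voxels not in the CTV whose centre lies within
    ``margin_mm`` of the nearest CTV voxel centre, computed with an exact
    Euclidean distance transform using the physical voxel spacing.  The
    result is disjoint from the CTV and clipped to the grid bounds.
    """
    if ctv.is_empty:
        raise EmptyStructureError(ctv.name or "<unnamed>")
    if margin_mm <= 0:
        raise DomainError(f"margin_mm must be > 0, got {margin_mm}")
    dist = ndimage.distance_transform_edt(~ctv.values, sampling=tuple(spacing))
    shell = (dist > 0) & (dist <= margin_mm)
    return StructureMask(shell, name=f"{ctv.name}+{margin_mm:g}mm shell")


# -- DVH point metrics -------------------------------------------------------


def dose_max(grid: DoseGrid, mask: StructureMask) -> float:
    """Maximum voxel dose inside the mask (Dmax), Gy (RBE)."""
    _check_congruent(grid, mask)
    if mask.is_empty:
        raise EmptyStructureError(mask.name or "<unnamed>")
    return float(grid.values[mask.values].max())


def dose_at_volume_percent(grid: DoseGrid, mask: StructureMask, percent: float) -> float:
    """Dose covering ``percent`` % of the structure volume (e.g. D99, D20)."""
    if not 0 < percent <= 100:
        raise DomainError(f"percent must be in (0, 100], got {percent}")
    dvh = compute_cumulative_dvh(grid, mask)
    return dvh.dose_at_volume(dvh.total_volume * percent / 100.0)


# -- plan QA -----------------------------------------------------------------


@dataclass(frozen=True)
class QARecord:
    criterion: str
    structure: str
    required: float
    achieved: float
    passed: bool


@dataclass(frozen=True)
class PlanQAReport:
    """Per-criterion pass/fail records for one plan."""

    records: tuple[QARecord, ...]

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.records)

    def to_rows(self) -> list[dict]:
        return [
            {
                "criterion": r.criterion,
                "structure": r.structure,
                "required": r.required,
                "achieved": r.achieved,
                "pass": r.passed,
            }
            for r in self.records
        ]


def evaluate_plan(
    grid: DoseGrid,
    targets: Iterable[tuple[StructureMask, float]],
    oar_rules: Iterable = (),
    coverage_fraction: float = 0.95,
) -> PlanQAReport:
    """Check plan pass criteria: target coverage and OAR dose limits.

    Each target (mask, total prescription) passes when its D99 — the dose
    covering 99% of the volume — is at least ``coverage_fraction`` times
    the prescription.  Each OAR rule (a :class:`~rbeconv.constraints.DoseConstraint`
    or any object with ``organ_mask``/``organ``, ``metric`` and
    ``total_dose`` attributes paired with a mask) is checked strictly:
    the achieved metric must be *below* the limit.

    ``oar_rules`` items are ``(mask, metric, limit)`` triples with metric
    ``"Dmax"`` or ``"D<percent>"`` (e.g. ``"D20"``).  Empty structures are
    skipped with a logged warning (a boost patient may lack CTV2).
    """
    records: list[QARecord] = []
    for mask, prescription in targets:
        _check_congruent(grid, mask)
        if mask.is_empty:
            logger.warning("skipping empty target structure '%s'", mask.name)
            continue
        d99 = dose_at_volume_percent(grid, mask, 99.0)
        required = coverage_fraction * prescription
        records.append(
            QARecord(
                criterion=f"D99 >= {coverage_fraction:.0%} prescription",
                structure=mask.name,
                required=required,
                achieved=d99,
                passed=bool(d99 >= required),
            )
        )
    for mask, metric, limit in oar_rules:
        _check_congruent(grid, mask)
        if mask.is_empty:
            logger.warning("skipping empty OAR structure '%s'", mask.name)
            continue
        achieved = evaluate_metric(grid, mask, metric)
        records.append(
            QARecord(
                criterion=f"{metric} < {limit:g} Gy (RBE)",
                structure=mask.name,
                required=limit,
                achieved=achieved,
                passed=bool(achieved < limit),
            )
        )
    return PlanQAReport(records=tuple(records))


def evaluate_metric(grid: DoseGrid, mask: StructureMask, metric: str) -> float:
    """Evaluate a named DVH metric (``Dmax`` or ``D<percent>``) on a structure."""
    if metric == "Dmax":
        return dose_max(grid, mask)
    m = _DVOL_RE.match(metric)
    if m:
        return dose_at_volume_percent(grid, mask, float(m.group(1)))
    raise ConfigurationError(f"unknown DVH metric {metric!r} (expected 'Dmax' or 'D<percent>')")
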