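"""Isovolumetric conversion-factor extraction and cohort curve aggregation.

The conversion factor f is the ratio of the LEM-I RBE-weighted dose to the
MKM RBE-weighted dose at *matched isodose volume*: for each LEM isodose
level D the enclosed volume V inside a region of interest is read off the
LEM DVH, the MKM dose enclosing that same volume is read off the MKM DVH,
and f = D / D_MKM.  Matching by equal volume is valid because both grids
weight the *same* physical dose, so iso-physical-dose surfaces coincide
and the DVHs are monotone transforms of each other.

Inside the target (CTV) the LEM dose is the prescription itself, so the
factor reduces to prescription / (representative MKM dose in the CTV).

Cohort aggregation averages the per-patient factors at each per-fraction
dose level and attaches a Student-t 95% confidence interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError, GeometryError
from .plan import (
    CumulativeDVH,
    DoseGrid,
    StructureMask,
    compute_cumulative_dvh,
)

logger = logging.getLogger(__name__)

Region = Literal["CTV1", "CTV2", "SHELL"]


@dataclass(frozen=True)
class IsodoseLevelGrid:
    """The ladder of total-dose isodose levels scanned during extraction.

    Levels are strictly decreasing total doses in Gy (RBE); per-fraction
    levels are derived by exact division by ``n_fractions`` and rounded
    only at presentation.
    """

    total_dose_levels: np.ndarray
    n_fractions: int

    def __post_init__(self) -> None:
        levels = np.asarray(self.total_dose_levels, dtype=np.float64)
        if levels.size < 1 or np.any(levels <= 0) or np.any(np.diff(levels) >= 0):
            raise DomainError("total_dose_levels must be strictly decreasing and > 0")
        object.__setattr__(self, "total_dose_levels", levels)
        if int(self.n_fractions) < 1:
            raise DomainError("n_fractions must be >= 1")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))

    @property
    def fraction_dose_levels(self) -> np.ndarray:
        return self.total_dose_levels / self.n_fractions

    def __len__(self) -> int:
        return int(self.total_dose_levels.size)


def make_isodose_levels(
    d_max_total: float = 60.0,
    d_min_total: float = 5.0,
    step: float = 1.0,
    n_fractions: int = 21,
) -> IsodoseLevelGrid:
    """Build the descending isodose ladder d_max, d_max - step, ..., >= d_min.

    The default 60.00 -> 5.00 Gy (RBE) ladder in 1.00 Gy (RBE) steps has 56
    levels; at 21 fractions the per-fraction doses run from 2.86 down to
    0.24 Gy (RBE) (2-decimal presentation).
    """
    if step <= 0:
        raise DomainError(f"step must be > 0, got {step}")
    if not d_max_total > d_min_total > 0:
        raise DomainError("require d_max_total > d_min_total > 0")
    count = int(np.floor((d_max_total - d_min_total) / step + 1e-9)) + 1
    levels = d_max_total - step * np.arange(count, dtype=np.float64)
    return IsodoseLevelGrid(total_dose_levels=levels, n_fractions=n_fractions)


@dataclass(frozen=True)
class ConversionSample:
    """One matched isodose pair: (d, D_LEM, V, D_MKM, f) for one patient/region."""

    patient_id: str
    region: str
    d_lem_fraction: float
    d_lem_total: float
    matched_volume: float
    d_mkm_total: float
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise DomainError(f"conversion factor must be > 0, got {self.factor}")
        if self.matched_volume <= 0:
            raise DomainError(f"matched volume must be > 0, got {self.matched_volume}")

    @property
    def d_mkm_fraction(self) -> float:
        return self.d_mkm_total * self.d_lem_fraction / self.d_lem_total


@dataclass(frozen=True)
class ConversionCurve:
    """Cohort-aggregated conversion curve f(d) with 95% confidence band.

    ``fraction_doses`` ascending, Gy (RBE) per fraction; ``mean_factors``
    the across-patient means; ``ci_low``/``ci_high`` the Student-t 95%
    interval (NaN where fewer than two patients contribute);
    ``n_patients`` the per-level patient count.
    """

    fraction_doses: np.ndarray
    mean_factors: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_patients: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.fraction_doses, dtype=np.float64)
        m = np.asarray(self.mean_factors, dtype=np.float64)
        lo = np.asarray(self.ci_low, dtype=np.float64)
        hi = np.asarray(self.ci_high, dtype=np.float64)
        n = np.asarray(self.n_patients, dtype=np.int64)
        if not (d.shape == m.shape == lo.shape == hi.shape == n.shape) or d.ndim != 1:
            raise DomainError("curve arrays must share one 1-D shape")
        if np.any(np.diff(d) <= 0):
            raise DomainError("fraction_doses must be strictly increasing")
        if np.any(~np.isfinite(m)) or np.any(m <= 0):
            raise DomainError("mean factors must be finite and > 0")
        with_ci = np.isfinite(lo) & np.isfinite(hi)
        if np.any(lo[with_ci] > m[with_ci]) or np.any(hi[with_ci] < m[with_ci]):
            raise DomainError("confidence interval must bracket the mean")
        for name, arr in (("fraction_doses", d), ("mean_factors", m),
                          ("ci_low", lo), ("ci_high", hi), ("n_patients", n)):
            object.__setattr__(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction_dose_Gy_RBE": self.fraction_doses,
                "mean_factor": self.mean_factors,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_patients": self.n_patients,
            }
        )

    @classmethod
    def from_constant(cls, factor: float, fraction_doses: Sequence[float],
                      provenance: str = "constant") -> "ConversionCurve":
        d = np.asarray(sorted(fraction_doses), dtype=np.float64)
        m = np.full_like(d, float(factor))
        nan = np.full_like(d, np.nan)
        return cls(d, m, nan, nan, np.ones(d.size, dtype=np.int64), provenance)


def extract_oar_conversion_samples(
    lem: DoseGrid,
    mkm: DoseGrid,
    shell: StructureMask,
    levels: IsodoseLevelGrid,
) -> list[ConversionSample]:
    """Isovolumetric factor extraction over a region outside the CTV.

    For each total-dose level D on the ladder with a non-zero LEM isodose
    volume inside ``shell``, the enclosed volume V is read off the LEM
    DVH and the MKM dose enclosing the same volume is read off the MKM
    DVH; the sample records f = D / D_MKM.  Levels above the maximum LEM
    dose in the region, or whose matched volume exceeds what the MKM DVH
    covers, are skipped with a logged reason — in clinical cohorts some
    LEM levels simply have no MKM counterpart in range.

    Both DVH inversions use the piecewise-linear (interpolated) form so
    the LEM->volume and volume->MKM lookups are mutually consistent.
    """
    if lem.values.shape != mkm.values.shape or lem.spacing != mkm.spacing:
        raise GeometryError("LEM and MKM grids must share shape and spacing")
    if lem.n_fractions != mkm.n_fractions:
        raise ConfigurationError(
            f"fraction counts differ: LEM {lem.n_fractions} vs MKM {mkm.n_fractions}"
        )
    if lem.model_tag != "LEM" or mkm.model_tag != "MKM":
        raise ConfigurationError(
            f"expected model tags (LEM, MKM), got ({lem.model_tag}, {mkm.model_tag})"
        )
    dvh_lem = compute_cumulative_dvh(lem, shell)
    dvh_mkm = compute_cumulative_dvh(mkm, shell)
    n = lem.n_fractions
    samples: list[ConversionSample] = []
    for d_total in levels.total_dose_levels:
        if d_total > dvh_lem.max_dose or d_total < dvh_lem.min_dose:
            # the isodose surface does not intersect the region
            logger.info(
                "patient %s: level %.2f Gy (RBE) outside the LEM dose range of %s, skipped",
                lem.patient_id, d_total, shell.name,
            )
            continue
        volume = dvh_lem.volume_at_dose(d_total, interpolate=True)
        if volume <= 0:
            logger.info(
                "patient %s: level %.2f Gy (RBE) has zero isodose volume, skipped",
                lem.patient_id, d_total,
            )
            continue
        if volume > dvh_mkm.total_volume:
            logger.info(
                "patient %s: matched volume %.3f cc exceeds MKM coverage, skipped",
                lem.patient_id, volume,
            )
            continue
        d_mkm = dvh_mkm.dose_at_volume(volume)
        samples.append(
            ConversionSample(
                patient_id=lem.patient_id,
                region="SHELL",
                d_lem_fraction=float(d_total) / n,
                d_lem_total=float(d_total),
                matched_volume=float(volume),
                d_mkm_total=float(d_mkm),
                factor=float(d_total) / float(d_mkm),
            )
        )
    return samples


def extract_target_factor(
    lem: DoseGrid,
    mkm: DoseGrid,
    ctv: StructureMask,
    prescription_fraction_dose: float,
    statistic: Literal["median", "mean"] = "median",
) -> ConversionSample | None:
    """In-target conversion factor at the prescription per-fraction dose.

    The LEM side is fixed at the prescription (plans are normalised to
    cover the CTV at prescription); the MKM side is the median (default)
    or mean per-fraction MKM dose over the CTV voxels.  Returns ``None``
    with a warning for an empty CTV (a boost patient may lack CTV2).
    """
    if prescription_fraction_dose <= 0:
        raise DomainError("prescription_fraction_dose must be > 0")
    if ctv.is_empty:
        logger.warning(
            "patient %s: structure '%s' is empty, target factor skipped",
            lem.patient_id, ctv.name,
        )
        return None
    stat = {"median": np.median, "mean": np.mean}.get(statistic)
    if stat is None:
        raise ConfigurationError(f"unknown in-target statistic {statistic!r}")
    mkm_fraction = float(stat(mkm.values[ctv.values])) / mkm.n_fractions
    factor = prescription_fraction_dose / mkm_fraction
    vcc = mkm.voxel_volume_cc * ctv.voxel_count
    return ConversionSample(
        patient_id=lem.patient_id,
        region=ctv.name.upper() if ctv.name else "CTV1",
        d_lem_fraction=float(prescription_fraction_dose),
        d_lem_total=float(prescription_fraction_dose) * lem.n_fractions,
        matched_volume=vcc,
        d_mkm_total=mkm_fraction * mkm.n_fractions,
        factor=factor,
    )


def aggregate_conversion_curve(
    samples: Iterable[ConversionSample],
    region: str | None = None,
    confidence: float = 0.95,
) -> ConversionCurve:
    """Average per-patient factors at each per-fraction dose level.

    The 95% CI at each level is the Student-t interval
    mean +/- t(0.975, n-1) * sd / sqrt(n) across patients; levels with a
    single patient carry no CI (NaN, flagged by ``n_patients``).
    """
    samples = list(samples)
    if region is not None:
        samples = [s for s in samples if s.region == region]
    if not samples:
        raise DomainError("no conversion samples to aggregate"
                          + (f" for region {region!r}" if region else ""))
    regions = {s.region for s in samples}
    if len(regions) > 1:
        raise ConfigurationError(
            f"samples span several regions {sorted(regions)}; pass region= to filter"
        )
    groups: dict[float, list[float]] = {}
    for s in samples:
        groups.setdefault(round(s.d_lem_fraction, 9), []).append(s.factor)
    doses = np.array(sorted(groups), dtype=np.float64)
    means, lo, hi, ns = [], [], [], []
    for d in doses:
        vals = np.asarray(groups[round(float(d), 9)], dtype=np.float64)
        n = vals.size
        m = float(vals.mean())
        if n >= 2:
            sem = float(vals.std(ddof=1)) / np.sqrt(n)
            tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
            lo.append(m - tcrit * sem)
            hi.append(m + tcrit * sem)
        else:
            lo.append(np.nan)
            hi.append(np.nan)
        means.append(m)
        ns.append(n)
    return ConversionCurve(
        fraction_doses=doses,
        mean_factors=np.array(means),
        ci_low=np.array(lo),
        ci_high=np.array(hi),
        n_patients=np.array(ns, dtype=np.int64),
        provenance=f"aggregate of {len(samples)} samples, region {samples[0].region}",
    )


def lookup_factor(curve: ConversionCurve, fraction_dose: float) -> float:
    """Interpolate the mean conversion factor at a per-fraction dose.

    Monotone piecewise-linear interpolation over the tabulated levels;
    queries outside the tabulated range return the endpoint value with a
    clamping warning.
    """
    if fraction_dose <= 0:
        raise DomainError(f"fraction_dose must be > 0, got {fraction_dose}")
    if curve.fraction_doses.size < 2:
        raise ConfigurationError("conversion curve needs at least 2 levels for lookup")
    d = curve.fraction_doses
    if fraction_dose < d[0] or fraction_dose > d[-1]:
        warnings.warn(
            f"fraction dose {fraction_dose:g} Gy (RBE) outside tabulated range "
            f"[{d[0]:g}, {d[-1]:g}]; endpoint factor used",
            stacklevel=2,
        )
        logger.warning("curve lookup clamped at %g Gy (RBE)", fraction_dose)
    return float(np.interp(fraction_dose, d, curve.mean_factors))


def prescription_isodose(prescription_total: float, percent: float) -> float:
    """Relative isodose level, Gy (RBE): e.g. V80 of 63 Gy (RBE) is 50.40.

    ``percent`` is the V-number (V50/V80/V90...), the isodose expressed as
    a percentage of the total prescription.
    """
    if prescription_total <= 0:
        raise DomainError(f"prescription must be > 0, got {prescription_total}")
    if not 0 < percent <= 100:
        raise DomainError(f"percent must be in (0, 100], got {percent}")
    return prescription_total * percent / 100.0


def percent_difference(factor: float) -> float:
    """Dose percentage difference (factor - 1) x 100, in percent."""
    if factor <= 0:
        raise DomainError(f"factor must be > 0, got {factor}")
    return (factor - 1.0) * 100.0


def samples_to_frame(samples: Iterable[ConversionSample]) -> pd.DataFrame:
    """Tabulate samples as the CSV-facing DataFrame."""
    return pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "region": s.region,
                "fraction_dose_Gy_RBE": s.d_lem_fraction,
                "lem_total_Gy_RBE": s.d_lem_total,
                "matched_volume_cc": s.matched_volume,
                "mkm_total_Gy_RBE": s.d_mkm_total,
                "factor": s.factor,
            }
            for s in samples
        ]
    )
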