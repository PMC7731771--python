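"""OAR-constraint conversion and the re-irradiation safety comparison.

A LEM-tagged organ-at-risk constraint is converted to its MKM equivalent
in five audited steps: (1) express the LEM total dose at the target
fraction count — either by LQ isoeffect rescaling or by supplying an
explicit, externally computed value; (2) derive the per-fraction LEM
dose; (3) look up the conversion factor f at that per-fraction dose on
the cohort conversion curve; (4) divide to get the per-fraction MKM
dose; (5) multiply back by the fraction count for the MKM total.

The safety check compares converted MKM constraints against a safety
fraction (default 70%) of the NIRS 16-fraction reference limits — the
margin adopted for re-irradiation of previously treated tissue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .convert import ConversionCurve, lookup_factor
from .errors import ConfigurationError, DomainError
from .fractionation import LQParams, lq_rescale_total_dose
from .util import round_half_up

_METRIC_RE = re.compile(r"^(Dmax|D\d+(?:\.\d+)?)$")

#: Normalised organ-name aliases (all keys lowercase).
ORGAN_ALIASES = {
    "brainstem": "brain stem",
    "brain-stem": "brain stem",
    "optical nerve": "optic nerve",
    "optic nerves": "optic nerve",
    "optic chiasm": "optic nerve",
    "spinal-cord": "spinal cord",
}


def normalize_organ(name: str) -> str:
    key = " ".join(name.strip().lower().split())
    return ORGAN_ALIASES.get(key, key)


@dataclass(frozen=True)
class DoseConstraint:
    """An organ dose limit: metric (Dmax or D<percent>), total dose, scheme, model."""

    organ: str
    metric: str
    total_dose: float
    n_fractions: int
    model_tag: Literal["LEM", "MKM"]

    def __post_init__(self) -> None:
        if not _METRIC_RE.match(self.metric):
            raise ConfigurationError(
                f"metric must be 'Dmax' or 'D<percent>', got {self.metric!r}"
            )
        if self.metric != "Dmax":
            pct = float(self.metric[1:])
            if not 0 < pct < 100:
                raise DomainError(f"Dvol percent must be in (0, 100), got {pct}")
        if self.total_dose <= 0:
            raise DomainError(f"total_dose must be > 0, got {self.total_dose}")
        if self.n_fractions < 1:
            raise DomainError(f"n_fractions must be >= 1, got {self.n_fractions}")
        if self.model_tag not in ("LEM", "MKM"):
            raise ConfigurationError(f"model_tag must be LEM or MKM, got {self.model_tag!r}")

    @property
    def fraction_dose(self) -> float:
        return self.total_dose / self.n_fractions


@dataclass(frozen=True)
class NIRSReference:
    """A NIRS 16-fraction MKM reference limit; per-fraction dose is derived."""

    organ: str
    metric: str
    total_dose: float
    n_fractions: int = 16

    def __post_init__(self) -> None:
        if self.total_dose <= 0:
            raise DomainError(f"total_dose must be > 0, got {self.total_dose}")
        if self.n_fractions != 16:
            raise ConfigurationError("NIRS head-and-neck references are 16-fraction limits")

    @property
    def per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


def nirs_per_fraction(ref: NIRSReference) -> float:
    """Per-fraction NIRS reference dose, Gy (RBE), 2-decimal presentation."""
    return round_half_up(ref.per_fraction, 2)


@dataclass(frozen=True)
class ConstraintAudit:
    """Full-precision intermediates of one constraint conversion."""

    lem_total_source: float
    lem_total_at_target: float
    lem_fraction_dose: float
    factor: float
    mkm_fraction_dose: float
    mkm_total: float
    mode: str
    clamped: bool = False
    mkm_total_ci: tuple[float, float] | None = None


def convert_constraint(
    c: DoseConstraint,
    n_target: int,
    curve: ConversionCurve,
    lq: LQParams | None = None,
    mode: Literal["lq_rescale", "explicit"] = "explicit",
    explicit_dose: float | None = None,
    propagate_ci: bool = False,
) -> tuple[DoseConstraint, ConstraintAudit]:
    """Convert a LEM constraint to its MKM equivalent at ``n_target`` fractions.

    In ``explicit`` mode the LEM total at ``n_target`` fractions is supplied
    directly (``explicit_dose``); in ``lq_rescale`` mode it is computed by
    LQ isoeffect with the supplied ``lq`` parameters.  With
    ``propagate_ci=True`` the curve's 95% CI endpoints are pushed through
    the division and reported in the audit (labelled as curve-CI
    propagation, not a full uncertainty analysis).
    """
    if c.model_tag != "LEM":
        raise ConfigurationError(f"constraint for {c.organ!r} is not LEM-tagged")
    if mode == "explicit":
        if explicit_dose is None:
            raise ConfigurationError(
                f"explicit mode requires explicit_dose (LEM total at {n_target} fractions)"
            )
        lem_total = float(explicit_dose)
    elif mode == "lq_rescale":
        if lq is None:
            raise ConfigurationError("lq_rescale mode requires LQ parameters (alpha/beta)")
        lem_total = lq_rescale_total_dose(c.total_dose, c.n_fractions, n_target, lq)
    else:
        raise ConfigurationError(f"unknown conversion mode {mode!r}")

    d_lem = lem_total / n_target
    clamped = not (curve.fraction_doses[0] <= d_lem <= curve.fraction_doses[-1])
    f = lookup_factor(curve, d_lem)
    d_mkm = d_lem / f
    mkm_total = d_mkm * n_target

    ci = None
    if propagate_ci:
        import numpy as np

        lo = float(np.interp(d_lem, curve.fraction_doses, curve.ci_low))
        hi = float(np.interp(d_lem, curve.fraction_doses, curve.ci_high))
        if not (pd.isna(lo) or pd.isna(hi)):
            # a larger factor gives a smaller converted dose
            ci = (d_lem / hi * n_target, d_lem / lo * n_target)

    converted = DoseConstraint(
        organ=c.organ,
        metric=c.metric,
        total_dose=mkm_total,
        n_fractions=n_target,
        model_tag="MKM",
    )
    audit = ConstraintAudit(
        lem_total_source=c.total_dose,
        lem_total_at_target=lem_total,
        lem_fraction_dose=d_lem,
        factor=f,
        mkm_fraction_dose=d_mkm,
        mkm_total=mkm_total,
        mode=mode,
        clamped=clamped,
        mkm_total_ci=ci,
    )
    return converted, audit


def convert_prescription(
    fraction_dose_lem: float,
    curve_or_factor: ConversionCurve | float,
) -> float:
    """MKM per-fraction prescription equivalent: LEM fraction dose / factor."""
    if fraction_dose_lem <= 0:
        raise DomainError(f"fraction_dose_lem must be > 0, got {fraction_dose_lem}")
    if isinstance(curve_or_factor, ConversionCurve):
        f = lookup_factor(curve_or_factor, fraction_dose_lem)
    else:
        f = float(curve_or_factor)
    if f <= 0:
        raise DomainError(f"conversion factor must be > 0, got {f}")
    return fraction_dose_lem / f


@dataclass(frozen=True)
class SafetyRecord:
    organ: str
    metric: str
    converted_mkm_total: float
    reference_total: float
    safety_fraction: float
    threshold: float
    within_threshold: bool
    margin: float


@dataclass(frozen=True)
class SafetyReport:
    """Per-organ comparison of converted MKM constraints against safety thresholds."""

    records: tuple[SafetyRecord, ...]
    safety_fraction: float

    @property
    def all_within(self) -> bool:
        return all(r.within_threshold for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "organ": r.organ,
                    "metric": r.metric,
                    "converted_mkm_Gy_RBE": r.converted_mkm_total,
                    "reference_Gy_RBE": r.reference_total,
                    "safety_fraction": r.safety_fraction,
                    "threshold_Gy_RBE": r.threshold,
                    "within_threshold": r.within_threshold,
                    "margin_Gy_RBE": r.margin,
                }
                for r in self.records
            ]
        )


def safety_check(
    converted: Sequence[DoseConstraint],
    refs: Sequence[NIRSReference],
    safety_fraction: float = 0.70,
) -> SafetyReport:
    """Compare converted MKM constraints to ``safety_fraction`` x NIRS limits.

    An organ is within the re-irradiation threshold when its converted
    total is <= safety_fraction * reference total.  Organs are matched by
    normalised lowercase name through the alias table; a converted organ
    with no reference is a configuration error.
    """
    if not 0 < safety_fraction <= 1:
        raise DomainError(f"safety_fraction must be in (0, 1], got {safety_fraction}")
    ref_by_organ = {normalize_organ(r.organ): r for r in refs}
    missing = [c.organ for c in converted if normalize_organ(c.organ) not in ref_by_organ]
    if missing:
        raise ConfigurationError(
            f"no reference limit for organ(s): {sorted(set(missing))}"
        )
    records = []
    for c in converted:
        ref = ref_by_organ[normalize_organ(c.organ)]
        threshold = safety_fraction * ref.total_dose
        records.append(
            SafetyRecord(
                organ=normalize_organ(c.organ),
                metric=c.metric,
                converted_mkm_total=c.total_dose,
                reference_total=ref.total_dose,
                safety_fraction=safety_fraction,
                threshold=threshold,
                within_threshold=bool(c.total_dose <= threshold),
                margin=threshold - c.total_dose,
            )
        )
    return SafetyReport(records=tuple(records), safety_fraction=safety_fraction)
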