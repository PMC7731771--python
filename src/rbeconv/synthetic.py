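"""Synthetic paired LEM/MKM plans with a known ground-truth factor curve.

No public dataset of paired LEM-I/MKM RBE-weighted grids exists, so the
pipeline is exercised on phantom plans that reproduce the *structure* of
the clinical cohort: an ellipsoidal CTV1 covered uniformly at prescription,
a surrounding CTV2 ring at its own (lower) prescription, an exponential
lateral/distal falloff outside the targets, and an MKM grid derived from
the LEM grid by a voxelwise division by a known factor curve f(d).

The ground-truth family is f(d) = 1 + a * d^(-b) for per-fraction dose d:
non-increasing in d, tending to 1 at high fraction dose, and >= 1
everywhere — the qualitative shape of published LEM-to-MKM conversion
curves.  It is calibration scaffolding, not a radiobiological model.
Because D_MKM = D_LEM / f(D_LEM/n) is a strictly increasing map of the
LEM dose, the two grids have identical isodose-volume orderings and the
isovolumetric extractor must recover f exactly (up to DVH interpolation)
— the package's central self-test.

Falloff distances use a continuous scaled ellipsoidal pseudo-distance
((rho - 1) x smallest semi-axis) rather than a voxelised Euclidean
distance transform: voxel-centre EDT values are quantised to a lattice,
which would collapse many voxels onto shared dose values and leave gaps
in the DVH near the CTV; the continuous coordinate gives generically
distinct voxel doses and a smooth, densely sampled DVH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import DomainError, GeometryError
from .plan import DoseGrid, StructureMask, expand_shell

#: Default calibration anchors (per-fraction dose Gy (RBE), factor):
#: the published shell-curve endpoints at the exact 5/21 and 60/21
#: per-fraction level doses.
DEFAULT_ANCHORS = ((5.0 / 21.0, 3.09), (60.0 / 21.0, 1.37))


@dataclass(frozen=True)
class GroundTruthFactorCurve:
    """f(d) = 1 + a * d^(-b), the generator's known conversion curve.

    ``a >= 0`` and ``b >= 0`` guarantee f >= 1 and monotone non-increasing
    in the per-fraction dose d.  ``d_lo``/``d_hi`` record the calibrated
    validity range (the power law itself is evaluated for any d > 0).
    """

    a: float
    b: float
    d_lo: float = 0.1
    d_hi: float = 3.2

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise DomainError("require a >= 0 and b >= 0 for a monotone factor >= 1")
        if not 0 < self.d_lo <= self.d_hi:
            raise DomainError("require 0 < d_lo <= d_hi")

    def __call__(self, d):
        d = np.asarray(d, dtype=np.float64)
        with np.errstate(divide="ignore"):
            out = 1.0 + self.a * np.power(d, -self.b, where=d > 0,
                                          out=np.full_like(d, np.inf))
        return out if out.ndim else float(out)


def calibrate_ground_truth(
    anchor_lo: tuple[float, float] = DEFAULT_ANCHORS[0],
    anchor_hi: tuple[float, float] = DEFAULT_ANCHORS[1],
) -> GroundTruthFactorCurve:
    """Solve f(d) = 1 + a d^-b through two (dose, factor) anchors.

    ``anchor_lo`` is the low-dose/high-factor anchor, ``anchor_hi`` the
    high-dose/low-factor one; a decreasing curve requires
    f_lo > f_hi >= 1 (equal factors give the constant b = 0 curve).
    """
    (d_lo, f_lo), (d_hi, f_hi) = anchor_lo, anchor_hi
    if not 0 < d_lo < d_hi:
        raise DomainError(f"anchor doses must satisfy 0 < d_lo < d_hi, got {d_lo}, {d_hi}")
    if f_hi < 1 or f_lo < f_hi:
        raise DomainError(
            f"anchors must satisfy f_lo >= f_hi >= 1 (decreasing curve), got {f_lo}, {f_hi}"
        )
    if f_lo == f_hi:
        return GroundTruthFactorCurve(a=f_lo - 1.0, b=0.0, d_lo=d_lo, d_hi=d_hi)
    if f_hi == 1.0:
        raise DomainError("a power-law factor cannot reach exactly 1 at finite dose")
    b = math.log((f_lo - 1.0) / (f_hi - 1.0)) / math.log(d_hi / d_lo)
    a = (f_lo - 1.0) * d_lo**b
    return GroundTruthFactorCurve(a=a, b=b, d_lo=d_lo, d_hi=d_hi)


@dataclass(frozen=True)
class SyntheticPlanSpec:
    """Parameters of one synthetic paired plan.

    Defaults mirror the clinical cohort the generator stands in for:
    3.00 Gy (RBE)/fraction to CTV1 and 2.70 to the CTV2 ring, 21
    fractions, head-and-neck-sized ellipsoidal targets on a 2 mm grid.
    ``falloff_lambda_mm`` is the exponential length scale of the dose
    falloff outside CTV1; ``ripple`` a uniform in-target dose
    inhomogeneity (fraction of prescription, must stay below 5% so plans
    pass coverage QA by construction); ``noise_sigma`` the lognormal
    multiplicative noise applied to the MKM grid only.
    """

    patient_id: str = "P01"
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    ctv1_semi_axes_mm: tuple[float, float, float] = (16.0, 13.5, 18.5)
    ctv2_margin_mm: float = 5.0
    center_mm: tuple[float, float, float] | None = None
    prescription_fraction_dose: float = 3.0
    ctv2_fraction_dose: float = 2.7
    n_fractions: int = 21
    falloff_lambda_mm: float = 6.0
    falloff_lambda2_mm: float = 4.0
    ripple: float = 0.0
    noise_sigma: float = 0.0
    oar_enabled: bool = True
    has_ctv2: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prescription_fraction_dose <= 0 or self.ctv2_fraction_dose <= 0:
            raise DomainError("prescriptions must be > 0")
        if self.ctv2_fraction_dose >= self.prescription_fraction_dose:
            raise DomainError("CTV2 prescription must be below the CTV1 prescription")
        if self.falloff_lambda_mm <= 0 or self.falloff_lambda2_mm <= 0:
            raise DomainError("falloff length scales must be > 0")
        if not 0 <= self.ripple < 0.05:
            raise DomainError(f"ripple must be in [0, 0.05), got {self.ripple}")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        if self.n_fractions < 1:
            raise DomainError("n_fractions must be >= 1")


def _ellipsoid_rho(shape, spacing, center, semi_axes) -> np.ndarray:
    """Scaled radial coordinate: rho <= 1 inside the ellipsoid."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    rho2 = 0.0
    for g, sp, c, ax in zip(grids, spacing, center, semi_axes):
        rho2 = rho2 + ((g * sp - c) / ax) ** 2
    return np.sqrt(rho2)


def generate_paired_plans(
    spec: SyntheticPlanSpec,
    truth: GroundTruthFactorCurve,
) -> tuple[DoseGrid, DoseGrid, dict[str, StructureMask]]:
    """Build one (LEM, MKM) grid pair plus structure masks.

    LEM grid: CTV1 voxels at prescription x (1 + ripple); the CTV2 ring
    at its prescription; outside, the larger of two exponential falloffs
    (length scales ``falloff_lambda_mm`` from CTV1 and
    ``falloff_lambda2_mm`` from the CTV2 surface).  MKM grid: voxelwise
    D_LEM / f(D_LEM / n), then multiplied by seeded lognormal noise.
    Masks: CTV1, CTV2 (the ring prescribed the CTV2 dose, exclusive of
    CTV1), the 20 mm shell around CTV1, and a small brain-stem-like OAR.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.spacing_mm)
    if spec.center_mm is None:
        # slightly off the grid centre: a lattice-aligned target makes many
        # voxels share exact radii, which thins out the DVH's dose levels
        center = tuple(
            (n - 1) * s / 2.0 + off
            for n, s, off in zip(shape, spacing, (0.37, 0.73, 1.19))
        )
    else:
        center = tuple(float(c) for c in spec.center_mm)
    axes1 = tuple(float(a) for a in spec.ctv1_semi_axes_mm)
    axes2 = tuple(a + spec.ctv2_margin_mm for a in axes1)

    rho1 = _ellipsoid_rho(shape, spacing, center, axes1)
    rho2 = _ellipsoid_rho(shape, spacing, center, axes2)
    ctv1 = rho1 <= 1.0
    ctv2_full = rho2 <= 1.0
    if not ctv1.any():
        raise GeometryError("CTV1 contains no voxels on this grid")
    border = np.zeros(shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    if (ctv2_full & border).any():
        raise GeometryError("CTV (with its CTV2 margin) does not fit inside the grid")

    n = spec.n_fractions
    p1_total = spec.prescription_fraction_dose * n
    p2_total = spec.ctv2_fraction_dose * n

    # continuous surface pseudo-distances (mm)
    s1 = np.clip(rho1 - 1.0, 0.0, None) * min(axes1)
    s2 = np.clip(rho2 - 1.0, 0.0, None) * min(axes2)
    lem = np.maximum(
        p1_total * np.exp(-s1 / spec.falloff_lambda_mm),
        (p2_total if spec.has_ctv2 else 0.0) * np.exp(-s2 / spec.falloff_lambda2_mm),
    )

    rng = np.random.default_rng(spec.seed)
    if spec.ripple > 0:
        ripple_region = ctv2_full if spec.has_ctv2 else ctv1
        u = rng.uniform(-spec.ripple, spec.ripple, size=int(ripple_region.sum()))
        lem = lem.copy()
        lem[ripple_region] *= 1.0 + u

    with np.errstate(divide="ignore", invalid="ignore"):
        mkm = np.where(lem > 0, lem / truth(lem / n), 0.0)
    if spec.noise_sigma > 0:
        mkm = mkm * rng.lognormal(mean=0.0, sigma=spec.noise_sigma, size=shape)

    lem_grid = DoseGrid(lem, spacing, n_fractions=n, model_tag="LEM",
                        patient_id=spec.patient_id)
    mkm_grid = DoseGrid(mkm, spacing, n_fractions=n, model_tag="MKM",
                        patient_id=spec.patient_id)

    masks: dict[str, StructureMask] = {
        "CTV1": StructureMask(ctv1, name="CTV1"),
        "CTV2": StructureMask(ctv2_full & ~ctv1 if spec.has_ctv2
                              else np.zeros(shape, dtype=bool), name="CTV2"),
        "SHELL": expand_shell(StructureMask(ctv1, name="CTV1"), spacing, 20.0),
    }
    if spec.oar_enabled:
        # small ellipsoid just beyond the CTV2 surface along the first axis
        oar_axes = (6.0, 6.0, 6.0)
        oar_center = (center[0] + axes2[0] + 4.0 + oar_axes[0], center[1], center[2])
        oar = _ellipsoid_rho(shape, spacing, oar_center, oar_axes) <= 1.0
        masks["OAR"] = StructureMask(oar & ~ctv2_full, name="brain stem")
    return lem_grid, mkm_grid, masks


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    lem: DoseGrid
    mkm: DoseGrid
    masks: Mapping[str, StructureMask]
    spec: SyntheticPlanSpec


@dataclass(frozen=True)
class SyntheticCohort:
    patients: tuple[SyntheticPatient, ...]
    truth: GroundTruthFactorCurve

    def __len__(self) -> int:
        return len(self.patients)


@dataclass(frozen=True)
class CohortVariation:
    """Uniform per-patient variation ranges around the base plan spec."""

    ctv_scale: tuple[float, float] = (0.85, 1.15)
    falloff_lambda_mm: tuple[float, float] = (5.0, 7.0)
    ripple: tuple[float, float] = (0.0, 0.02)


def generate_cohort(
    n_patients: int,
    base_spec: SyntheticPlanSpec,
    variation: CohortVariation | None = None,
    truth: GroundTruthFactorCurve | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a deterministic cohort of paired plans.

    Per-patient CTV size, falloff scale and ripple are drawn uniformly
    from the variation ranges using a master generator; each patient's
    voxel-level randomness flows from a spawned per-patient seed, so the
    whole cohort is a pure function of ``seed``.  A single-patient cohort
    uses the midpoint of every variation range (no sampling).
    """
    if n_patients < 1:
        raise DomainError("n_patients must be >= 1")
    variation = variation or CohortVariation()
    truth = truth or calibrate_ground_truth()
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)
    child_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_patients)]

    patients = []
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        if n_patients == 1:
            scale = sum(variation.ctv_scale) / 2.0
            lam = sum(variation.falloff_lambda_mm) / 2.0
            rip = sum(variation.ripple) / 2.0
        else:
            scale = master.uniform(*variation.ctv_scale)
            lam = master.uniform(*variation.falloff_lambda_mm)
            rip = master.uniform(*variation.ripple)
        spec = replace(
            base_spec,
            patient_id=pid,
            ctv1_semi_axes_mm=tuple(a * scale for a in base_spec.ctv1_semi_axes_mm),
            falloff_lambda_mm=lam,
            ripple=rip,
            seed=child_seeds[i],
        )
        lem, mkm, masks = generate_paired_plans(spec, truth)
        patients.append(SyntheticPatient(pid, lem, mkm, masks, spec))
    return SyntheticCohort(patients=tuple(patients), truth=truth)
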