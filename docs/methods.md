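# Methods

## Problem and model

Carbon-ion centres weight the same physical dose with different
radiobiological models: European-style planning uses the local effect
model (LEM-I), whose RBE depends on the delivered dose, while the
Japanese (NIRS) convention uses the microdosimetric kinetic model (MKM),
whose RBE is driven by LETd and is taken as dose-independent. The same
physical plan therefore carries two different RBE-weighted dose numbers,
and prescriptions or organ-at-risk (OAR) limits quoted under one model
cannot be reused under the other without conversion.

This package implements the *isovolumetric* conversion: when a LEM plan
is recalculated under MKM on identical geometry and physical dose, every
iso-physical-dose surface is shared by the two weighted grids, so the LEM
isodose enclosing volume V inside a region corresponds to the MKM isodose
enclosing the same V. The conversion factor at LEM level D is

    f(d) = D_LEM / D_MKM   at matched volume,  d = D_LEM / n fractions,

and is tabulated per patient over a ladder of total-dose levels
(default 60.00 → 5.00 Gy (RBE) in 1.00 Gy (RBE) steps, i.e. 56 levels;
0.24–2.86 Gy (RBE)/fraction at n = 21). Inside the target the LEM dose is
the prescription itself, so the factor reduces to prescription divided by
a representative per-fraction MKM dose over the CTV — the median by
default (the mean is a configuration option); the choice matters little
for near-uniform target coverage but the median is robust to the dose
tails at the CTV edge.

Cohort aggregation averages per-patient factors at each per-fraction
level; the 95% confidence band is the Student-t interval
mean ± t(0.975, n−1)·sd/√n. Levels retained by fewer than two patients
carry no interval. Curve lookup is monotone piecewise-linear in the
per-fraction dose, clamped (with a warning) outside the tabulated range.

## DVH construction and inversion

Cumulative DVHs are exact: dose levels are the sorted unique masked voxel
doses and the volume at each level is the voxel count at-or-above it
times the voxel volume. There is no binning, so the brute-force count is
an equality oracle, not an approximation. `volume_at_dose` is by default
the exact right-continuous step function; `dose_at_volume` interpolates
linearly between adjacent distinct levels, resolving ties toward the
higher dose (the conservative reading of "largest dose covering the
volume").

For isovolumetric matching the extractor evaluates *both* inversions in
their piecewise-linear form. Using the raw step function for the
LEM-side volume lookup would snap every queried level to the nearest
voxel dose above it, injecting an error of the order of the local
voxel-dose gap into every factor; with the linear form on both sides the
composite LEM→volume→MKM map is exactly linear interpolation of the
voxelwise dose transform between adjacent voxel-dose nodes, and the
residual is second-order in the node spacing (~1e-8 relative on the
default synthetic grids). Levels whose isodose surface does not
intersect the region, or whose matched volume exceeds the MKM DVH's
coverage, are skipped with a logged reason and recorded as per-level
attrition in the aggregated curve.

`expand_shell` builds the out-of-target region of interest (CTV + 20 mm,
CTV excluded) with an exact Euclidean distance transform on voxel
centres using the physical spacing. Masks must be congruent with their
grid; resampling and contour rasterisation are out of scope.

Plan QA follows the clinical pass criteria: target D99 ≥ 95% of
prescription; OAR limits strict (`Dmax < 45 Gy (RBE)` fails at exactly
45.00). Dmax is the maximum voxel dose (no near-max percentile); D99/D20
are `dose_at_volume` at 99%/20% of the structure volume. Empty
structures (a boost patient without CTV2) are skipped with a warning,
never an error.

## Fractionation and constraint conversion

Isoeffect conversion between schemes uses the linear-quadratic
biologically effective dose, BED = D(1 + d/(α/β)), with the closed-form
positive root for the rescaled per-fraction dose. BED is conserved to
1e-9 relative and rescaling composes transitively. α/β is always an
explicit parameter: 2 Gy (RBE) is the conventional late-CNS value and is
documented as such, but the library applies no default silently —
published 21→16-fraction constraint pairs in this clinical context are
not reproducible with a single conventional α/β (back-solving the two
rows gives ≈17 and ≈15 Gy (RBE)), so the pipeline's default *explicit
mode* takes the 16-fraction LEM doses as authoritative inputs and offers
standard LQ rescaling as the computed alternative.

A LEM constraint is converted in five audited steps: LEM total at the
target fraction count (explicit or LQ) → per-fraction LEM dose → factor
lookup on the cohort curve → per-fraction MKM dose by division → MKM
total by multiplication. The audit trail keeps full precision and the
identity LEM/MKM = f holds to 1e-12; reports round half-up to two
decimals only at presentation. Optionally the curve's CI endpoints are
propagated through the division and labelled as such (this is curve
uncertainty only, not a full error budget).

The re-irradiation safety check compares each converted MKM constraint
against a safety fraction (default 70%) of the NIRS 16-fraction
reference limits, matching organs by normalised name with an alias table
("optical nerve" ≡ "optic nerve", "brainstem" ≡ "brain stem"). An organ
is within threshold when converted ≤ fraction × reference; decreasing the
fraction can only move organs from passing to failing.

## Synthetic cohort

No public paired LEM/MKM dataset exists, so the pipeline is validated on
synthetic plans with a *known* conversion curve. The ground-truth family
is f(d) = 1 + a·d^(−b): ≥ 1, monotone non-increasing, approaching 1 at
high per-fraction dose — the qualitative shape of published conversion
curves — and calibrated through two anchors, by default the published
shell-curve endpoints (0.24 Gy (RBE), 3.09) and (2.86 Gy (RBE), 1.37)
taken at the exact 5/21 and 60/21 level doses. It is scaffolding for
validation, not a radiobiological model; between its anchors it is an
interpolation by the chosen family, not data.

Each synthetic patient has an ellipsoidal CTV1 (default semi-axes
16 × 13.5 × 18.5 mm, ≈ 17 cc, head-and-neck scale) covered uniformly at
3.00 Gy (RBE) × 21 fractions with an optional sub-5% ripple, a CTV2 ring
(5 mm margin) at 2.70 Gy (RBE), an exponential falloff outside the
targets (length scales ~6 mm from CTV1 and ~4 mm beyond the CTV2
surface, chosen so the 20 mm shell spans the full 60→5 Gy (RBE) ladder),
and a small brain-stem-like OAR placed so the default plan passes its
Dmax limit. The MKM grid is the voxelwise image D_LEM / f(D_LEM/n),
optionally multiplied by seeded lognormal noise (MKM side only, so LEM
plan QA is untouched). Defaults emulate the clinical cohort: 20
patients, 64³ grids at 2 mm, uniform variation in CTV size (±15%),
falloff scale (5–7 mm) and ripple (0–2%), lognormal noise σ = 0.01.

Two numerical choices matter here. Falloff distance is a continuous
scaled ellipsoidal pseudo-distance ((ρ−1) × smallest semi-axis) rather
than a voxelised distance transform, and the target centre sits slightly
off the grid centre: lattice-aligned, symmetric geometry makes many
voxels share exact radii, which collapses DVH nodes and degrades the
recovery oracle from ~1e-7 to ~1e-4 relative. Neither choice affects
the analysis side, which always uses exact EDT distances.

Because D_MKM is a strictly increasing function of D_LEM, same-volume
isodose pairs are exactly (D, D/f(D/n)) and the extractor must return
the ground truth at every retained level — the package's central
self-test, which passes at ≤ 1e-6 relative on a noise-free five-patient
cohort. What passing does *not* show: real paired plans differ by more
than a smooth voxelwise transform (fragment-spectrum and LETd structure,
independent optimisation noise, planning-system interpolation), so
recovery on phantoms validates the machinery, not the clinical curve.
In-target CTV2 factors illustrate the limit: the power-law family through
the shell anchors gives f(2.70) ≈ 1.39, whereas the clinical cohort
reports 1.46 — the published in-target factors are carried as fixed
reference inputs, not re-derived from phantoms.

All randomness flows from one master seed through spawned per-patient
seeds; identical configurations give bitwise-identical grids and
byte-identical CSV outputs.

## Pipeline, sizes and determinism

`run_pipeline` chains cohort generation, plan QA, factor extraction
(targets and shell), curve aggregation, constraint conversion and the
safety check, and writes the CSV bundle atomically (staging directory,
then move), so a failing stage — reported by name — leaves no partial
outputs. Shell-curve cohort membership is an explicit configuration
list, never inferred. Default problem sizes (20 patients × 64³ voxels)
run the whole pipeline in a few seconds on one core; the validation
suite uses 3–5-patient cohorts on 40–64³ grids.

## Known limitations

- NRRD is the only volumetric interchange format (DICOM-RT Dose/Struct
  would need an adapter); masks must share the dose grid exactly.
- Voxel-counting DVHs approximate planning-system (sub-voxel
  interpolated) isodose volumes at coarse grids.
- The CI-shrinkage property is checked against the t-quantile/√n law
  (the plain 1/√n law only holds asymptotically; at n = 5 the t quantile
  inflates widths by ~25%).
- The safety check reproduces constraint arithmetic; it is not clinical
  decision support, and no claim about safe human dosing is made beyond
  that arithmetic.
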