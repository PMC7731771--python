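"""Published reference values for LEM-I <-> MKM dose conversion in rNPC CIRT.

These constants transcribe the printed results of a 20-patient clinical
conversion study for locally recurrent nasopharyngeal carcinoma (rNPC)
treated with carbon-ion radiotherapy under 21-fraction LEM-I planning:
per-patient in-target conversion factors, the worked matched-isodose pairs
of the first patient, the institutional LEM organ-at-risk constraints with
their published 16-fraction equivalents, the NIRS 16-fraction MKM reference
limits, and the endpoints of the published shell conversion curve.  They
serve as calibration anchors for the synthetic cohort generator and as
fixed inputs/cross-checks for the constraint pipeline; nothing here is a
computed output of this package.
"""

from __future__ import annotations

from .constraints import DoseConstraint, NIRSReference

#: Per-patient in-target conversion factors at the CTV1 prescription of
#: 3.00 Gy (RBE)/fraction (20 patients, P01..P20).
CTV1_PRESCRIPTION_FRACTION = 3.00
CTV1_FACTORS = (
    1.35, 1.38, 1.33, 1.37, 1.38, 1.40, 1.36, 1.34, 1.38, 1.39,
    1.39, 1.37, 1.39, 1.36, 1.39, 1.36, 1.38, 1.39, 1.38, 1.35,
)

#: Per-patient in-target factors at the CTV2 prescription of 2.70 Gy (RBE)/fraction.
#: 19 patients — the last patient's plan was a boost without CTV2.
CTV2_PRESCRIPTION_FRACTION = 2.70
CTV2_FACTORS = (
    1.67, 1.45, 1.42, 1.47, 1.45, 1.45, 1.45, 1.44, 1.44, 1.45,
    1.47, 1.46, 1.47, 1.44, 1.46, 1.41, 1.44, 1.45, 1.46,
)

#: First patient's worked shell pairs: (LEM per-fraction isodose Gy (RBE),
#: matched volume cc, MKM per-fraction isodose at the same volume).
PATIENT01_SHELL_PAIRS = (
    (2.86, 8.25, 2.05),
    (2.81, 12.12, 2.00),
    (2.76, 17.27, 1.95),
)

#: Published shell-curve endpoints: per-fraction LEM dose -> (mean factor, 95% CI).
SHELL_CURVE_ENDPOINTS = {
    2.86: (1.37, (1.33, 1.41)),
    0.24: (3.09, (2.94, 3.24)),
}

#: Institutional OAR constraints of the 21-fraction LEM plans.
LEM_CONSTRAINTS_21FX = (
    DoseConstraint(organ="brain stem", metric="Dmax", total_dose=45.00,
                   n_fractions=21, model_tag="LEM"),
    DoseConstraint(organ="spinal cord", metric="Dmax", total_dose=30.00,
                   n_fractions=21, model_tag="LEM"),
    DoseConstraint(organ="optic nerve", metric="D20", total_dose=30.00,
                   n_fractions=21, model_tag="LEM"),
)

#: Published 16-fraction LEM equivalents of the constraints above.  The
#: study's own 21->16 LQ computation is not reproducible from its text
#: (no alpha/beta is stated and no single value back-solves both rows),
#: so these are carried as authoritative *inputs* for explicit-mode
#: constraint conversion.
LEM_CONSTRAINTS_16FX_EXPLICIT = {
    "brain stem": 43.68,
    "spinal cord": 29.28,
    "optic nerve": 29.28,
}

#: Published MKM 16-fraction converted constraints (cross-check values).
MKM_CONSTRAINTS_16FX_PUBLISHED = {
    "brain stem": 30.72,
    "spinal cord": 16.64,
    "optic nerve": 16.64,
}

#: NIRS 16-fraction MKM reference limits for first-course head-and-neck CIRT.
NIRS_REFERENCES_16FX = (
    NIRSReference(organ="brain stem", metric="Dmax", total_dose=40.00),
    NIRSReference(organ="spinal cord", metric="Dmax", total_dose=30.00),
    NIRSReference(organ="optic nerve", metric="D20", total_dose=28.00),
)

#: Re-irradiation safety fraction applied to the NIRS limits.
REIRRADIATION_SAFETY_FRACTION = 0.70

#: In-target dose percentage differences of the Fossati conversion curve at
#: the CTV1/CTV2 prescriptions, used only for comparison reporting.
FOSSATI_PERCENT_DIFFERENCES = {3.00: 38.00, 2.70: 47.20}
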