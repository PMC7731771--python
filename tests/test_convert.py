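"""Isodose ladders, factor extraction, curve aggregation and lookup."""

import numpy as np
import pytest

from rbeconv.convert import (
    ConversionCurve,
    ConversionSample,
    aggregate_conversion_curve,
    extract_oar_conversion_samples,
    extract_target_factor,
    lookup_factor,
    make_isodose_levels,
    percent_difference,
    prescription_isodose,
)
from rbeconv.errors import ConfigurationError, DomainError, GeometryError
from rbeconv.plan import DoseGrid, StructureMask
from rbeconv.util import round_half_up
from rbeconv import reference

from conftest import full_mask, random_grid


def make_samples(values_by_dose, region="SHELL"):
    """Samples from {fraction_dose: [per-patient factors]}."""
    out = []
    for d, factors in values_by_dose.items():
        for i, f in enumerate(factors):
            out.append(
                ConversionSample(
                    patient_id=f"P{i + 1:02d}", region=region,
                    d_lem_fraction=d, d_lem_total=d * 21,
                    matched_volume=1.0, d_mkm_total=d * 21 / f, factor=f,
                )
            )
    return out


# --- isodose ladder ---------------------------------------------------------


def test_default_ladder_has_56_levels_down_to_quarter_gray():
    levels = make_isodose_levels(n_fractions=21)
    assert len(levels) == 56
    assert levels.total_dose_levels[0] == 60.0
    assert levels.total_dose_levels[-1] == 5.0
    fr = levels.fraction_dose_levels
    assert round_half_up(fr[0], 2) == 2.86
    assert round_half_up(fr[-1], 2) == 0.24
    assert np.allclose(fr * 21, levels.total_dose_levels)


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(d_max_total=6.0, d_min_total=5.0, step=1.0, n_fractions=1), 2),
        (dict(n_fractions=16), 56),
    ],
)
def test_ladder_level_counts(kwargs, expected):
    assert len(make_isodose_levels(**kwargs)) == expected


def test_ladder_16_fraction_top_dose():
    levels = make_isodose_levels(n_fractions=16)
    assert levels.fraction_dose_levels[0] == pytest.approx(3.75)


def test_ladder_rejects_bad_steps():
    with pytest.raises(DomainError):
        make_isodose_levels(step=0.0)
    with pytest.raises(DomainError):
        make_isodose_levels(d_max_total=5.0, d_min_total=60.0)


def test_prescription_isodose_levels():
    assert prescription_isodose(63.0, 80.0) == pytest.approx(50.40)
    assert prescription_isodose(63.0, 50.0) == pytest.approx(31.50)
    with pytest.raises(DomainError):
        prescription_isodose(63.0, 0.0)


# --- extraction -------------------------------------------------------------


def test_identical_grids_give_unit_factors():
    rng = np.random.default_rng(2)
    shape = (10, 10, 10)
    values = rng.uniform(1.0, 63.0, size=shape)
    lem = DoseGrid(values, (2, 2, 2), n_fractions=21, model_tag="LEM")
    mkm = DoseGrid(values, (2, 2, 2), n_fractions=21, model_tag="MKM")
    levels = make_isodose_levels(d_max_total=60.0, d_min_total=5.0, n_fractions=21)
    samples = extract_oar_conversion_samples(lem, mkm, full_mask(shape), levels)
    assert samples
    assert all(s.factor == pytest.approx(1.0, rel=1e-12) for s in samples)


def test_extraction_validates_tags_and_geometry():
    rng = np.random.default_rng(0)
    lem = random_grid(rng, n_fractions=21)
    mkm_wrong_tag = random_grid(rng, n_fractions=21, model_tag="LEM")
    levels = make_isodose_levels(n_fractions=21)
    with pytest.raises(ConfigurationError):
        extract_oar_conversion_samples(lem, mkm_wrong_tag, full_mask((8, 8, 8)), levels)
    mkm_small = random_grid(rng, shape=(4, 4, 4), n_fractions=21, model_tag="MKM")
    with pytest.raises(GeometryError):
        extract_oar_conversion_samples(lem, mkm_small, full_mask((8, 8, 8)), levels)
    mkm_other_n = random_grid(rng, n_fractions=16, model_tag="MKM")
    with pytest.raises(ConfigurationError):
        extract_oar_conversion_samples(lem, mkm_other_n, full_mask((8, 8, 8)), levels)


def test_levels_outside_dose_range_are_skipped():
    shape = (6, 6, 6)
    lem = DoseGrid(np.full(shape, 30.0), (1, 1, 1), n_fractions=21, model_tag="LEM")
    mkm = DoseGrid(np.full(shape, 20.0), (1, 1, 1), n_fractions=21, model_tag="MKM")
    levels = make_isodose_levels(n_fractions=21)  # 60..5, only 30 matches
    samples = extract_oar_conversion_samples(lem, mkm, full_mask(shape), levels)
    assert len(samples) == 1
    assert samples[0].d_lem_total == 30.0
    assert samples[0].factor == pytest.approx(1.5)


def test_target_factor_uniform_ctv():
    shape = (5, 5, 5)
    lem = DoseGrid(np.full(shape, 63.0), (1, 1, 1), n_fractions=21, model_tag="LEM")
    mkm = DoseGrid(np.full(shape, 63.0 / 1.37), (1, 1, 1), n_fractions=21,
                   model_tag="MKM")
    s = extract_target_factor(lem, mkm, full_mask(shape, "CTV1"), 3.0)
    assert s.factor == pytest.approx(1.37, rel=1e-12)
    assert s.region == "CTV1"


def test_target_factor_empty_ctv_returns_none(caplog):
    shape = (4, 4, 4)
    lem = random_grid(np.random.default_rng(1), shape=shape, n_fractions=21)
    mkm = random_grid(np.random.default_rng(1), shape=shape, n_fractions=21,
                      model_tag="MKM")
    empty = StructureMask(np.zeros(shape, dtype=bool), name="CTV2")
    with caplog.at_level("WARNING"):
        assert extract_target_factor(lem, mkm, empty, 2.7) is None
    assert "CTV2" in caplog.text


# --- aggregation ------------------------------------------------------------


def test_published_cohort_means():
    """The published per-patient in-target factors average to 1.37 and 1.46."""
    samples = make_samples(
        {3.0: reference.CTV1_FACTORS}, region="CTV1"
    ) + make_samples({2.7: reference.CTV2_FACTORS}, region="CTV2")
    ctv1 = aggregate_conversion_curve(samples, region="CTV1")
    ctv2 = aggregate_conversion_curve(samples, region="CTV2")
    assert round_half_up(ctv1.mean_factors[0], 2) == 1.37
    assert round_half_up(ctv2.mean_factors[0], 2) == 1.46
    assert int(ctv1.n_patients[0]) == 20
    assert int(ctv2.n_patients[0]) == 19
    assert ctv1.ci_low[0] <= ctv1.mean_factors[0] <= ctv1.ci_high[0]


def test_zero_variance_cohort_has_zero_ci_width():
    curve = aggregate_conversion_curve(make_samples({1.0: [1.5] * 6, 2.0: [1.2] * 6}))
    assert np.allclose(curve.mean_factors, [1.5, 1.2])
    assert np.allclose(curve.ci_high - curve.ci_low, 0.0, atol=1e-12)


def test_single_patient_level_has_no_ci():
    curve = aggregate_conversion_curve(make_samples({1.0: [1.5]}))
    assert np.isnan(curve.ci_low[0]) and np.isnan(curve.ci_high[0])
    assert curve.n_patients[0] == 1


def test_aggregation_rejects_empty_and_mixed_regions():
    with pytest.raises(DomainError):
        aggregate_conversion_curve([])
    mixed = make_samples({1.0: [1.5]}, "SHELL") + make_samples({1.0: [1.4]}, "CTV1")
    with pytest.raises(ConfigurationError):
        aggregate_conversion_curve(mixed)
    # but a region filter resolves the mix
    curve = aggregate_conversion_curve(mixed, region="SHELL")
    assert curve.mean_factors[0] == pytest.approx(1.5)


def test_ci_shrinks_with_cohort_size():
    """Mean CI width follows the t-quantile / sqrt(n) law across cohort sizes."""
    from scipy import stats

    rng = np.random.default_rng(17)
    doses = np.linspace(0.5, 2.5, 40)
    widths = {}
    for n in (5, 20, 80):
        samples = make_samples(
            {float(d): list(1.5 + rng.normal(0, 0.1, size=n)) for d in doses}
        )
        curve = aggregate_conversion_curve(samples)
        widths[n] = float(np.mean(curve.ci_high - curve.ci_low))
    for n1, n2 in ((5, 20), (20, 80)):
        expected = (stats.t.ppf(0.975, n1 - 1) / stats.t.ppf(0.975, n2 - 1)
                    * np.sqrt(n2 / n1))
        assert widths[n1] / widths[n2] == pytest.approx(expected, rel=0.15)


# --- lookup and reporting ---------------------------------------------------


def test_lookup_interpolates_and_clamps():
    curve = ConversionCurve(
        fraction_doses=np.array([1.0, 2.0]),
        mean_factors=np.array([3.0, 2.0]),
        ci_low=np.array([np.nan, np.nan]),
        ci_high=np.array([np.nan, np.nan]),
        n_patients=np.array([3, 3]),
    )
    assert lookup_factor(curve, 1.0) == 3.0  # tabulated node
    assert lookup_factor(curve, 1.5) == pytest.approx(2.5)  # linear midpoint
    with pytest.warns(UserWarning, match="outside tabulated range"):
        assert lookup_factor(curve, 0.5) == 3.0  # clamped to lowest level
    with pytest.raises(DomainError):
        lookup_factor(curve, 0.0)


def test_lookup_needs_two_levels():
    single = ConversionCurve(
        fraction_doses=np.array([1.0]), mean_factors=np.array([1.5]),
        ci_low=np.array([np.nan]), ci_high=np.array([np.nan]),
        n_patients=np.array([1]),
    )
    with pytest.raises(ConfigurationError):
        lookup_factor(single, 1.0)


@pytest.mark.parametrize("factor, expected", [(1.3727, 37.27), (1.0, 0.0), (2.0, 100.0)])
def test_percent_difference(factor, expected):
    assert percent_difference(factor) == pytest.approx(expected)


def test_presentation_rounding_is_half_up():
    assert round_half_up(1.405, 2) == 1.41
    assert round_half_up(1.875, 2) == 1.88
    assert round_half_up(5 / 21, 2) == 0.24
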