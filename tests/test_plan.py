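"""Dose grids, exact DVHs, isodose inversion, shell geometry and plan QA."""

import numpy as np
import pytest

from rbeconv.errors import (
    ConfigurationError,
    DomainError,
    EmptyStructureError,
    GeometryError,
)
from rbeconv.plan import (
    DoseGrid,
    StructureMask,
    compute_cumulative_dvh,
    dose_at_volume_percent,
    dose_max,
    evaluate_plan,
    expand_shell,
)

from conftest import full_mask, random_grid


# --- construction invariants -----------------------------------------------


def test_dose_grid_rejects_bad_values():
    with pytest.raises(DomainError):
        DoseGrid(-np.ones((2, 2, 2)), (1, 1, 1))
    with pytest.raises(DomainError):
        DoseGrid(np.full((2, 2, 2), np.nan), (1, 1, 1))
    with pytest.raises(DomainError):
        DoseGrid(np.ones((2, 2, 2)), (1, 0, 1))
    with pytest.raises(ConfigurationError):
        DoseGrid(np.ones((2, 2, 2)), (1, 1, 1), model_tag="LEM2")


def test_fraction_dose_is_derived():
    grid = DoseGrid(np.full((2, 2, 2), 63.0), (1, 1, 1), n_fractions=21)
    assert np.allclose(grid.fraction_values, 3.0)


# --- cumulative DVH ---------------------------------------------------------


def test_dvh_uniform_structure():
    # 100 voxels of 1 mm^3, all at 3.00 Gy (RBE)
    grid = DoseGrid(np.full((5, 5, 4), 3.0), (1, 1, 1))
    dvh = compute_cumulative_dvh(grid, full_mask((5, 5, 4)))
    assert dvh.total_volume == pytest.approx(0.1)
    assert dvh.volume_at_dose(2.0) == pytest.approx(0.1)
    assert dvh.volume_at_dose(3.0) == pytest.approx(0.1)
    assert dvh.volume_at_dose(3.01) == 0.0
    # uniform dose: any volume within total inverts to the uniform dose
    assert dvh.dose_at_volume(0.05) == pytest.approx(3.0)


def test_dvh_enumerated_grid():
    grid = DoseGrid(np.arange(1.0, 28.0).reshape(3, 3, 3), (1, 1, 1))
    dvh = compute_cumulative_dvh(grid, full_mask((3, 3, 3)))
    assert dvh.volume_at_dose(14.0) == pytest.approx(0.014)  # 14 voxels >= 14
    assert dvh.volume_at_dose(27.0) == pytest.approx(0.001)
    assert dvh.dose_at_volume(0.001) == pytest.approx(27.0)
    assert dvh.dose_at_volume(dvh.total_volume) == pytest.approx(1.0)  # min voxel dose


def test_dvh_matches_bruteforce_count():
    """Exactness: the DVH equals a brute-force voxel count at random queries."""
    rng = np.random.default_rng(11)
    for _ in range(8):
        shape = tuple(rng.integers(2, 17, size=3))
        grid = random_grid(rng, shape=shape, spacing=(1.3, 0.8, 2.1),
                           duplicates=bool(rng.integers(2)))
        mask = StructureMask(rng.random(shape) < 0.7, name="R")
        if mask.is_empty:
            continue
        dvh = compute_cumulative_dvh(grid, mask)
        vcc = grid.voxel_volume_cc
        doses = grid.values[mask.values]
        for q in rng.uniform(-0.0, 65.0, size=50):
            expected = np.count_nonzero(doses >= q) * vcc
            assert dvh.volume_at_dose(float(q)) == pytest.approx(expected, abs=0, rel=1e-12)


def test_dvh_monotone_and_bounded():
    rng = np.random.default_rng(5)
    for _ in range(5):
        grid = random_grid(rng, duplicates=True)
        dvh = compute_cumulative_dvh(grid, full_mask(grid.values.shape))
        assert np.all(np.diff(dvh.volumes) < 0)
        assert dvh.volumes.max() <= dvh.total_volume + 1e-12
        assert dvh.volume_at_dose(0.0) == pytest.approx(dvh.total_volume)


def test_dose_volume_round_trip():
    """For distinct voxel doses, dose_at_volume inverts volume_at_dose exactly."""
    rng = np.random.default_rng(3)
    grid = random_grid(rng, shape=(6, 6, 6))  # continuous draws: all distinct
    dvh = compute_cumulative_dvh(grid, full_mask((6, 6, 6)))
    for d in dvh.dose_levels:
        assert dvh.dose_at_volume(dvh.volume_at_dose(float(d))) == pytest.approx(
            float(d), rel=1e-12
        )


def test_dvh_domain_errors():
    grid = DoseGrid(np.full((2, 2, 2), 3.0), (1, 1, 1))
    dvh = compute_cumulative_dvh(grid, full_mask((2, 2, 2)))
    with pytest.raises(DomainError):
        dvh.volume_at_dose(-1.0)
    for bad_volume in (0.0, -1.0, dvh.total_volume * 1.01):
        with pytest.raises(DomainError):
            dvh.dose_at_volume(bad_volume)


def test_empty_structure_reported_by_name():
    grid = DoseGrid(np.ones((3, 3, 3)), (1, 1, 1))
    empty = StructureMask(np.zeros((3, 3, 3), dtype=bool), name="CTV2")
    with pytest.raises(EmptyStructureError, match="CTV2"):
        compute_cumulative_dvh(grid, empty)


def test_shape_mismatch_is_geometry_error():
    grid = DoseGrid(np.ones((3, 3, 3)), (1, 1, 1))
    with pytest.raises(GeometryError):
        compute_cumulative_dvh(grid, full_mask((4, 3, 3)))


# --- shell expansion --------------------------------------------------------


def test_shell_single_voxel_isotropic():
    """2 mm shell around a central voxel at 1 mm spacing has exactly 32 voxels."""
    mask = np.zeros((7, 7, 7), dtype=bool)
    mask[3, 3, 3] = True
    shell = expand_shell(StructureMask(mask, "CTV"), (1, 1, 1), margin_mm=2.0)
    assert shell.voxel_count == 32  # 6 at d=1, 12 at sqrt(2), 8 at sqrt(3), 6 at 2
    assert not (shell.values & mask).any()


def test_shell_matches_bruteforce_distances():
    rng = np.random.default_rng(9)
    spacing = (1.5, 0.9, 2.2)
    for _ in range(4):
        shape = tuple(rng.integers(4, 13, size=3))
        ctv = rng.random(shape) < 0.08
        if not ctv.any():
            ctv[tuple(s // 2 for s in shape)] = True
        margin = float(rng.uniform(1.0, 4.0))
        shell = expand_shell(StructureMask(ctv, "CTV"), spacing, margin)
        ctv_pts = np.argwhere(ctv) * np.asarray(spacing)
        expected = np.zeros(shape, dtype=bool)
        for idx in np.ndindex(shape):
            if ctv[idx]:
                continue
            p = np.asarray(idx) * np.asarray(spacing)
            d = np.sqrt(((ctv_pts - p) ** 2).sum(axis=1)).min()
            expected[idx] = d <= margin
        assert np.array_equal(shell.values, expected)


def test_shell_degenerate_inputs():
    full = StructureMask(np.ones((3, 3, 3), dtype=bool), "CTV")
    assert expand_shell(full, (1, 1, 1), margin_mm=0.5).voxel_count == 0
    with pytest.raises(EmptyStructureError):
        expand_shell(StructureMask(np.zeros((3, 3, 3), dtype=bool), "CTV"), (1, 1, 1))


# --- plan QA ----------------------------------------------------------------


def test_target_at_prescription_passes():
    grid = DoseGrid(np.full((4, 4, 4), 63.0), (1, 1, 1), n_fractions=21)
    report = evaluate_plan(grid, [(full_mask((4, 4, 4), "CTV1"), 63.0)])
    assert report.all_passed


def test_oar_limit_is_strict():
    shape = (3, 3, 3)
    oar = full_mask(shape, "brain stem")
    for dose, expected in ((44.9, True), (45.0, False)):
        grid = DoseGrid(np.full(shape, dose), (1, 1, 1))
        report = evaluate_plan(grid, [], [(oar, "Dmax", 45.0)])
        assert report.records[0].passed is expected


def test_unknown_metric_rejected():
    grid = DoseGrid(np.ones((2, 2, 2)), (1, 1, 1))
    with pytest.raises(ConfigurationError):
        evaluate_plan(grid, [], [(full_mask((2, 2, 2)), "Dmean", 10.0)])


def test_empty_target_skipped_with_warning(caplog):
    grid = DoseGrid(np.ones((3, 3, 3)), (1, 1, 1))
    empty = StructureMask(np.zeros((3, 3, 3), dtype=bool), name="CTV2")
    with caplog.at_level("WARNING"):
        report = evaluate_plan(grid, [(empty, 63.0)])
    assert len(report.records) == 0
    assert "CTV2" in caplog.text


def test_dvh_point_metrics():
    values = np.zeros((10, 1, 1))
    values[:, 0, 0] = np.arange(1.0, 11.0)
    grid = DoseGrid(values, (1, 1, 1))
    mask = full_mask((10, 1, 1))
    assert dose_max(grid, mask) == 10.0
    # 20% of 10 voxels = 2 voxels covered: the dose level with >= 2 voxels above
    assert dose_at_volume_percent(grid, mask, 20.0) == pytest.approx(9.0)
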