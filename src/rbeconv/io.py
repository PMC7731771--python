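"""NRRD and CSV interchange.

Dose grids and structure masks travel as NRRD volumes (one file each),
with ``n_fractions``, ``model_tag`` and ``patient_id`` carried in header
key-value fields; DVHs, constraint tables and reports travel as CSV.
SimpleITK handles the NRRD encoding; note that SimpleITK orders spacing
(x, y, z) while the in-memory arrays are indexed (z, y, x), so spacing
and origin are reversed on the way in and out.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .constraints import DoseConstraint, NIRSReference
from .errors import ConfigurationError
from .plan import CumulativeDVH, DoseGrid, StructureMask


def write_dose_grid(grid: DoseGrid, path: str | Path) -> None:
    img = sitk.GetImageFromArray(grid.values)
    img.SetSpacing(tuple(reversed(grid.spacing)))
    img.SetOrigin(tuple(reversed(grid.origin)))
    img.SetMetaData("n_fractions", str(grid.n_fractions))
    img.SetMetaData("model_tag", grid.model_tag)
    img.SetMetaData("patient_id", grid.patient_id)
    sitk.WriteImage(img, str(path), useCompression=True)


def read_dose_grid(path: str | Path) -> DoseGrid:
    img = sitk.ReadImage(str(path))
    keys = set(img.GetMetaDataKeys())
    if "model_tag" not in keys or "n_fractions" not in keys:
        raise ConfigurationError(
            f"{path}: NRRD header must carry 'model_tag' and 'n_fractions'"
        )
    return DoseGrid(
        values=sitk.GetArrayFromImage(img).astype(np.float64),
        spacing=tuple(reversed(img.GetSpacing())),
        origin=tuple(reversed(img.GetOrigin())),
        n_fractions=int(img.GetMetaData("n_fractions")),
        model_tag=img.GetMetaData("model_tag"),
        patient_id=img.GetMetaData("patient_id") if "patient_id" in keys else "",
    )


def write_structure_mask(mask: StructureMask, path: str | Path) -> None:
    img = sitk.GetImageFromArray(mask.values.astype(np.uint8))
    img.SetMetaData("structure_name", mask.name)
    sitk.WriteImage(img, str(path), useCompression=True)


def read_structure_mask(path: str | Path) -> StructureMask:
    img = sitk.ReadImage(str(path))
    name = (img.GetMetaData("structure_name")
            if "structure_name" in img.GetMetaDataKeys() else Path(path).stem)
    return StructureMask(sitk.GetArrayFromImage(img) > 0, name=name)


def dvh_to_csv(dvh: CumulativeDVH, path: str | Path) -> None:
    pd.DataFrame(
        {"dose_Gy_RBE": dvh.dose_levels, "volume_cc": dvh.volumes}
    ).to_csv(path, index=False)


def read_dvh_csv(path: str | Path, structure_name: str = "") -> CumulativeDVH:
    df = pd.read_csv(path)
    vols = df["volume_cc"].to_numpy(dtype=float)
    return CumulativeDVH(
        dose_levels=df["dose_Gy_RBE"].to_numpy(dtype=float),
        volumes=vols,
        total_volume=float(vols[0]),
        structure_name=structure_name or Path(path).stem,
    )


def read_constraint_table(path: str | Path, model_tag: str = "LEM") -> list[DoseConstraint]:
    """Read a constraint CSV: organ, metric, total_dose_Gy_RBE, n_fractions."""
    df = pd.read_csv(path)
    return [
        DoseConstraint(
            organ=str(r.organ),
            metric=str(r.metric),
            total_dose=float(r.total_dose_Gy_RBE),
            n_fractions=int(r.n_fractions),
            model_tag=str(getattr(r, "model_tag", model_tag)),
        )
        for r in df.itertuples(index=False)
    ]


def read_reference_table(path: str | Path) -> list[NIRSReference]:
    df = pd.read_csv(path)
    return [
        NIRSReference(
            organ=str(r.organ),
            metric=str(r.metric),
            total_dose=float(r.total_dose_Gy_RBE),
            n_fractions=int(getattr(r, "n_fractions", 16)),
        )
        for r in df.itertuples(index=False)
    ]
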