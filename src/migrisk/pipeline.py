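"""Row-wise prediction over harmonized datasets and inventories.

Glue between the tabular world (:mod:`migrisk.dataset`) and the scalar
predictors: for every row, estimate D_p and K_ms from the material
library, resolve the archetype geometry, run the mechanistic model (or a
regression model), and return per-row rates with diagnostics.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import ProductArchetype, default_archetypes
from .dataset import allocate_product
from .errors import MigriskError
from .mechanistic import MechanisticInputs, migrated_fraction, migration_rate
from .qspr import (
    ChemicalRecord,
    MaterialLibrary,
    MediumSpec,
    default_material_library,
    estimate_dp,
    estimate_kms,
    select_etoh_eq,
)

__all__ = ["mechanistic_predict", "prepare_design", "regression_predict"]

#: Candidate predictors the regression machinery knows how to derive.
CANDIDATE_PREDICTORS = ("log10_c0", "log10_dp", "log10_kow", "log10_kms", "log10_mw")


def _row_chemical(row: Mapping) -> ChemicalRecord:
    return ChemicalRecord(
        name=str(row["chemical_name"]),
        mw=float(row["mw_g_mol"]),
        log_kow=float(row["log_kow"]),
        cas=str(row.get("chemical_cas", "") or ""),
        group=str(row.get("chemical_group", "") or ""),
    )


def _row_medium(row: Mapping, conservative: bool) -> MediumSpec:
    in_vivo = bool(row.get("in_vivo", False))
    agitation = bool(row.get("agitation", False))
    base = MediumSpec(in_vivo=in_vivo, agitation=agitation)
    return MediumSpec(
        etoh_eq=select_etoh_eq(base, conservative=conservative),
        in_vivo=in_vivo,
        agitation=agitation,
    )


def mechanistic_predict(
    df: pd.DataFrame,
    materials: MaterialLibrary | None = None,
    archetypes: Mapping[str, ProductArchetype] | None = None,
    conservative: bool = False,
) -> pd.DataFrame:
    """Mechanistic migration-rate predictions, one row per input row.

    Returns a frame aligned with ``df`` carrying ``rate_pred``, ``f_mgr``,
    ``t_dev_s``, ``regime``, ``dp_cm2_s``, ``kms``, ``n_warnings`` and an
    ``error`` column (empty on success). Failing rows get NaN predictions
    plus the error message — screening never aborts on one bad row.
    """
    materials = materials if materials is not None else default_material_library()
    archetypes = archetypes if archetypes is not None else default_archetypes()
    out = []
    for _, row in df.iterrows():
        rec = {
            "rate_pred": np.nan, "f_mgr": np.nan, "t_dev_s": np.nan,
            "regime": "", "dp_cm2_s": np.nan, "kms": np.nan,
            "n_warnings": 0, "error": "",
        }
        try:
            chem = _row_chemical(row)
            mat = materials.get(str(row["material"]))
            arch = archetypes[
                str(row.get("product_archetype") or allocate_product(str(row["material"])))
            ]
            medium = _row_medium(row, conservative)
            dp = estimate_dp(chem, mat)
            kms = estimate_kms(chem, mat, medium)
            inputs = MechanisticInputs(
                d_p_coeff=float(dp),
                k_pf=float(kms),
                geometry=arch.geometry,
                c0=float(row["c0_ug_g"]),
                duration=float(row["contact_time_min"]) * 60.0,
            )
            result = migrated_fraction(inputs)
            rec.update(
                rate_pred=migration_rate(result, inputs, mat.density),
                f_mgr=result.f_mgr,
                t_dev_s=result.saturation.t_dev,
                regime=result.regime.value,
                dp_cm2_s=float(dp),
                kms=float(kms),
                n_warnings=len(dp.warnings) + len(kms.warnings) + len(result.warnings),
            )
        except (MigriskError, KeyError, ValueError) as exc:
            rec["error"] = str(exc)
        out.append(rec)
    return pd.DataFrame(out, index=df.index)


def prepare_design(
    df: pd.DataFrame,
    materials: MaterialLibrary | None = None,
    conservative: bool = False,
) -> pd.DataFrame:
    """Derive the candidate regression predictors for every row.

    Columns: ``log10_c0``, ``log10_dp``, ``log10_kow``, ``log10_kms``,
    ``log10_mw`` and, when the frame carries observed rates, the response
    ``log10_rate``. D_p and K_ms come from the same QSPRs the mechanistic
    model uses (per-row EtOH-eq policy included).
    """
    materials = materials if materials is not None else default_material_library()
    rows = []
    for _, row in df.iterrows():
        chem = _row_chemical(row)
        mat = materials.get(str(row["material"]))
        medium = _row_medium(row, conservative)
        rec = {
            "log10_c0": np.log10(float(row["c0_ug_g"])),
            "log10_dp": np.log10(float(estimate_dp(chem, mat))),
            "log10_kow": chem.log_kow,
            "log10_kms": np.log10(float(estimate_kms(chem, mat, medium))),
            "log10_mw": np.log10(chem.mw),
        }
        if "rate_ug_per_10cm2_min" in row:
            rate = float(row["rate_ug_per_10cm2_min"])
            rec["log10_rate"] = np.log10(rate) if rate > 0 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows, index=df.index)


def regression_predict(
    df: pd.DataFrame,
    model,
    materials: MaterialLibrary | None = None,
    conservative: bool = False,
) -> pd.Series:
    """Migration rates (µg/10cm²/min) from a fitted regression model."""
    design = prepare_design(df, materials=materials, conservative=conservative)
    return pd.Series(model.predict_rate(design), index=df.index, name="rate_pred")
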