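"""Harmonized migration datasets: reading, validation, standardization,
and synthetic fixture generation.

The harmonized dataset holds one row per experimental observation of a
chemical migrating from a product material into (artificial or real)
saliva, with the migration rate standardized to µg/10cm²/min. The CSV
schema is frozen (UTF-8, comma-separated, snake_case headers with units
embedded) so that round trips are bit-stable:

======================== ======================================================
column                   meaning
======================== ======================================================
chemical_cas             CAS registry number (may be empty)
chemical_name            chemical name (identity key when CAS is empty)
chemical_group           chemical-group label (e.g. "parabens")
mw_g_mol                 molar mass, g/mol
log_kow                  log10 octanol-water partition coefficient
material                 product material (PVC, PP, EVA, silicone, wood, ...)
study_id                 source study identifier
c0_ug_g                  initial concentration in the product, µg/g
rate_ug_per_10cm2_min    standardized migration rate
contact_time_min         contact duration, min
sample_area_cm2          contacted sample area, cm²
sample_thickness_cm      sample thickness, cm
in_vivo                  experiment performed in a mouth (bool)
agitation                mechanical agitation of the sample (bool)
product_archetype        pacifier | doll (blank -> allocated from material)
======================== ======================================================

Rows violating invariants are *collected* as row-numbered diagnostics and
excluded, never fatal; a missing mandatory column is a :class:`SchemaError`.

The synthetic generator emulates the harmonized dataset: chemicals drawn
from group templates, concentrations log-uniform, "true" rates computed by
the mechanistic model with QSPR-estimated D_p/K_ms, and observed rates
equal to the true rate times lognormal (base-10) noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ProductArchetype, default_archetypes
from .errors import DomainError, SchemaError, UnsupportedMaterialError
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

__all__ = [
    "COLUMNS",
    "MANDATORY_COLUMNS",
    "Dataset",
    "GroupTemplate",
    "MigrationObservation",
    "RawExperimentRecord",
    "RowDiagnostic",
    "SyntheticConfig",
    "allocate_product",
    "default_group_templates",
    "generate_synthetic_dataset",
    "read_dataset",
    "standardize_rate",
    "write_dataset",
]

DOLL_MATERIALS = frozenset({"PVC", "PP", "wood"})
PACIFIER_MATERIALS = frozenset({"silicone", "EVA"})

COLUMNS: tuple[str, ...] = (
    "chemical_cas",
    "chemical_name",
    "chemical_group",
    "mw_g_mol",
    "log_kow",
    "material",
    "study_id",
    "c0_ug_g",
    "rate_ug_per_10cm2_min",
    "contact_time_min",
    "sample_area_cm2",
    "sample_thickness_cm",
    "in_vivo",
    "agitation",
    "product_archetype",
)
#: Columns that must be present for the file to parse at all.
MANDATORY_COLUMNS: tuple[str, ...] = tuple(c for c in COLUMNS if c != "product_archetype")

_NUMERIC = ("mw_g_mol", "log_kow", "c0_ug_g", "rate_ug_per_10cm2_min",
            "contact_time_min", "sample_area_cm2", "sample_thickness_cm")


def allocate_product(material: str, override: str | None = None) -> str:
    """Map a material to its product archetype (doll or pacifier).

    PVC, PP and wood observations are modelled as dolls; silicone and EVA
    as pacifiers. An explicit per-record override always wins, including
    for materials the rule does not know.
    """
    if override:
        return override
    if material in DOLL_MATERIALS:
        return "doll"
    if material in PACIFIER_MATERIALS:
        return "pacifier"
    raise UnsupportedMaterialError(material, tuple(DOLL_MATERIALS | PACIFIER_MATERIALS))


@dataclass(frozen=True)
class MigrationObservation:
    """One harmonized experimental data point."""

    chemical: ChemicalRecord
    material: str
    study_id: str
    c0: float  # ug/g
    rate: float  # ug/10cm2/min
    contact_time: float  # min
    sample_area: float  # cm2
    sample_thickness: float  # cm
    in_vivo: bool = False
    agitation: bool = False
    product_archetype: str = ""

    def __post_init__(self) -> None:
        if not (self.c0 > 0):
            raise DomainError(f"c0 must be > 0, got {self.c0}")
        if self.rate < 0:
            raise DomainError(f"rate must be >= 0, got {self.rate}")
        if not (self.contact_time > 0):
            raise DomainError(f"contact_time must be > 0, got {self.contact_time}")
        if not self.product_archetype:
            object.__setattr__(
                self, "product_archetype", allocate_product(self.material)
            )

    @property
    def combination_key(self) -> tuple[str, str]:
        chem_key = self.chemical.cas or self.chemical.name.strip().lower()
        return (chem_key, self.material)


@dataclass(frozen=True)
class RowDiagnostic:
    row: int  # 1-based data row number (header excluded)
    message: str

    def to_json_dict(self) -> dict:
        return {"row": self.row, "message": self.message}


@dataclass
class Dataset:
    """A validated harmonized dataset plus its rejection diagnostics."""

    df: pd.DataFrame
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_chemicals(self) -> int:
        if self.df.empty:
            return 0
        key = self.df["chemical_cas"].where(
            self.df["chemical_cas"].astype(str).str.len() > 0,
            self.df["chemical_name"].astype(str).str.strip().str.lower(),
        )
        return key.nunique()

    @property
    def n_materials(self) -> int:
        return 0 if self.df.empty else self.df["material"].nunique()

    @property
    def n_combinations(self) -> int:
        if self.df.empty:
            return 0
        key = self.df["chemical_cas"].where(
            self.df["chemical_cas"].astype(str).str.len() > 0,
            self.df["chemical_name"].astype(str).str.strip().str.lower(),
        )
        return pd.MultiIndex.from_arrays([key, self.df["material"]]).nunique()

    def summary(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_combinations": self.n_combinations,
            "n_chemicals": self.n_chemicals,
            "n_materials": self.n_materials,
            "n_rejected_rows": len(self.diagnostics),
        }

    def observations(self) -> Iterable[MigrationObservation]:
        for _, r in self.df.iterrows():
            yield MigrationObservation(
                chemical=ChemicalRecord(
                    name=str(r["chemical_name"]),
                    mw=float(r["mw_g_mol"]),
                    log_kow=float(r["log_kow"]),
                    cas=str(r["chemical_cas"]) if r["chemical_cas"] else "",
                    group=str(r["chemical_group"]),
                ),
                material=str(r["material"]),
                study_id=str(r["study_id"]),
                c0=float(r["c0_ug_g"]),
                rate=float(r["rate_ug_per_10cm2_min"]),
                contact_time=float(r["contact_time_min"]),
                sample_area=float(r["sample_area_cm2"]),
                sample_thickness=float(r["sample_thickness_cm"]),
                in_vivo=bool(r["in_vivo"]),
                agitation=bool(r["agitation"]),
                product_archetype=str(r["product_archetype"]),
            )


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise ValueError(f"unparseable boolean in {column}: {value!r}")


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a harmonized-dataset CSV.

    Returns the valid rows as a :class:`Dataset`; rows failing invariants
    are dropped and reported as row-numbered diagnostics. Blank product
    archetypes are filled from the material allocation rule.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty (no header)") from None
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if "product_archetype" not in raw.columns:
        raw["product_archetype"] = ""

    rows: list[dict] = []
    diagnostics: list[RowDiagnostic] = []
    for i, rec in enumerate(raw.to_dict("records"), start=1):
        try:
            row = {c: str(rec[c]).strip() for c in COLUMNS}
            for c in _NUMERIC:
                row[c] = float(row[c])
            for c in ("in_vivo", "agitation"):
                row[c] = _parse_bool(rec[c], c)
            # route through the domain type so every invariant is enforced once
            obs = MigrationObservation(
                chemical=ChemicalRecord(
                    name=row["chemical_name"],
                    mw=row["mw_g_mol"],
                    log_kow=row["log_kow"],
                    cas=row["chemical_cas"],
                    group=row["chemical_group"],
                ),
                material=row["material"],
                study_id=row["study_id"],
                c0=row["c0_ug_g"],
                rate=row["rate_ug_per_10cm2_min"],
                contact_time=row["contact_time_min"],
                sample_area=row["sample_area_cm2"],
                sample_thickness=row["sample_thickness_cm"],
                in_vivo=row["in_vivo"],
                agitation=row["agitation"],
                product_archetype=row["product_archetype"],
            )
            row["product_archetype"] = obs.product_archetype
            rows.append(row)
        except (ValueError, DomainError, UnsupportedMaterialError, KeyError) as exc:
            diagnostics.append(RowDiagnostic(row=i, message=str(exc)))
    df = pd.DataFrame(rows, columns=COLUMNS)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})
    return Dataset(df=df, diagnostics=diagnostics)


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write a harmonized dataset with the frozen column order."""
    extra = [c for c in df.columns if c not in COLUMNS]
    df.loc[:, list(COLUMNS) + extra].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Raw-report standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawExperimentRecord:
    """A migration result as reported by a source study, before
    standardization. Exactly one of the three migration quantities is
    needed: a migrated mass, a migrated fraction (with the initial mass),
    or a final saliva concentration (with the saliva volume)."""

    contact_time_min: float
    sample_area_cm2: float
    migrated_mass_ug: float | None = None
    fraction_migrated: float | None = None
    initial_mass_ug: float | None = None
    final_conc_ug_cm3: float | None = None
    saliva_volume_cm3: float | None = None

    def __post_init__(self) -> None:
        if not (self.contact_time_min > 0):
            raise DomainError("contact_time_min must be > 0")
        if not (self.sample_area_cm2 > 0):
            raise DomainError("sample_area_cm2 must be > 0")
        if (
            self.migrated_mass_ug is None
            and self.fraction_migrated is None
            and self.final_conc_ug_cm3 is None
        ):
            raise DomainError("no migration quantity reported")


def standardize_rate(raw: RawExperimentRecord) -> float:
    """Standardized migration rate, µg per 10 cm² per minute.

    The migrated mass is resolved from whichever representation the study
    reported (mass, fraction × initial mass, or concentration × saliva
    volume) and divided by contact area (in 10 cm² units) and time.
    """
    if raw.migrated_mass_ug is not None:
        mass = raw.migrated_mass_ug
    elif raw.fraction_migrated is not None:
        if raw.initial_mass_ug is None:
            raise DomainError("fraction_migrated needs initial_mass_ug")
        mass = raw.fraction_migrated * raw.initial_mass_ug
    else:
        if raw.saliva_volume_cm3 is None:
            raise DomainError("final_conc_ug_cm3 needs saliva_volume_cm3")
        mass = raw.final_conc_ug_cm3 * raw.saliva_volume_cm3
    if mass < 0:
        raise DomainError(f"migrated mass must be >= 0, got {mass}")
    return mass / (raw.sample_area_cm2 / 10.0) / raw.contact_time_min


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTemplate:
    """MW / log Kow envelope of one chemical group and the materials it
    occurs in (first material is primary, later ones are the alternates a
    minority of chemicals also appear in)."""

    group: str
    materials: tuple[str, ...]
    mw_range: tuple[float, float]
    log_kow_range: tuple[float, float]
    weight: float = 1.0  # share of chemicals allocated to this group


def default_group_templates() -> tuple[GroupTemplate, ...]:
    """Templates mirroring the chemical-group / material combinations of
    the harmonized experimental dataset."""
    return (
        GroupTemplate("phthalates and alternative plasticizers", ("PVC", "PP"),
                      (250.0, 500.0), (4.0, 10.0), weight=0.30),
        GroupTemplate("parabens", ("EVA", "PVC"), (150.0, 200.0), (2.0, 4.0),
                      weight=0.13),
        GroupTemplate("polybrominated diphenyl ethers", ("PP", "PVC"),
                      (400.0, 960.0), (6.0, 10.0), weight=0.17),
        GroupTemplate("methylsiloxanes", ("silicone",), (220.0, 450.0),
                      (4.0, 9.0), weight=0.13),
        GroupTemplate("chlorophenols", ("wood",), (128.0, 270.0), (2.5, 5.5),
                      weight=0.12),
        GroupTemplate("fragrance allergens", ("PP", "wood"), (120.0, 250.0),
                      (1.5, 5.0), weight=0.15),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of the emulated study.

    Defaults reproduce the harmonized dataset's scale: 437 observations of
    60 chemicals in 5 materials (66 chemical–material combinations, 18
    studies), with base-10 lognormal observation noise of 0.79 decades —
    the reported log-scale scatter between model and measurement.
    """

    n_observations: int = 437
    seed: int = 0
    log10_noise_sd: float = 0.79
    c0_range: tuple[float, float] = (10.0, 1.0e5)  # ug/g, log-uniform
    contact_time_range_min: tuple[float, float] = (5.0, 240.0)  # log-uniform
    n_chemicals: int = 60
    n_dual_material: int = 6  # chemicals observed in a second material
    n_studies: int = 18
    p_in_vivo: float = 0.10
    p_agitation: float = 0.30
    templates: tuple[GroupTemplate, ...] = field(default_factory=default_group_templates)

    def __post_init__(self) -> None:
        if self.n_observations <= 0:
            raise DomainError("n_observations must be > 0")
        if self.log10_noise_sd < 0:
            raise DomainError("log10_noise_sd must be >= 0")
        if self.n_chemicals <= 0 or self.n_dual_material < 0:
            raise DomainError("n_chemicals > 0 and n_dual_material >= 0 required")


def _synthetic_cas(rng: np.random.Generator) -> str:
    """A random, checksum-valid CAS-format identifier (synthetic, not a
    registered number)."""
    body = f"{int(rng.integers(10_000, 9_999_999))}{int(rng.integers(0, 100)):02d}"
    check = sum(i * int(d) for i, d in enumerate(reversed(body), start=1)) % 10
    return f"{body[:-2]}-{body[-2:]}-{check}"


def _allocate_counts(weights: Sequence[float], total: int) -> list[int]:
    # largest-remainder apportionment; deterministic
    raw = [w / sum(weights) * total for w in weights]
    counts = [int(x) for x in raw]
    rem = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_synthetic_dataset(
    config: SyntheticConfig,
    materials: MaterialLibrary | None = None,
    archetypes: Mapping[str, ProductArchetype] | None = None,
) -> Dataset:
    """Generate a synthetic harmonized dataset.

    True rates come from the mechanistic model with QSPR-estimated
    D_p/K_ms under the archetype geometry allocated to each material;
    observed rates multiply the true rate by ``10**N(0, log10_noise_sd)``.
    The returned frame carries an extra ``rate_true_ug_per_10cm2_min``
    column so tests can close the loop against the stored truth. Fully
    reproducible from ``config.seed``.
    """
    materials = materials if materials is not None else default_material_library()
    archetypes = archetypes if archetypes is not None else default_archetypes()
    rng = np.random.default_rng(config.seed)

    counts = _allocate_counts([t.weight for t in config.templates], config.n_chemicals)
    chemicals: list[tuple[ChemicalRecord, GroupTemplate]] = []
    for tpl, k in zip(config.templates, counts):
        for j in range(k):
            chem = ChemicalRecord(
                name=f"{tpl.group.split()[0]}-{j + 1:02d}",
                mw=float(rng.uniform(*tpl.mw_range)),
                log_kow=float(rng.uniform(*tpl.log_kow_range)),
                cas=_synthetic_cas(rng),
                group=tpl.group,
            )
            chemicals.append((chem, tpl))

    # chemical-material combinations: every chemical in its primary
    # material; the first n_dual_material chemicals of multi-material
    # groups also appear in their group's alternate material
    combos: list[tuple[ChemicalRecord, str, GroupTemplate]] = [
        (chem, tpl.materials[0], tpl) for chem, tpl in chemicals
    ]
    dual = [(c, t) for c, t in chemicals if len(t.materials) > 1][: config.n_dual_material]
    combos += [(chem, tpl.materials[1], tpl) for chem, tpl in dual]
    study_ids = [f"study-{1 + i % config.n_studies:02d}" for i in range(len(combos))]

    rows = []
    idx = rng.integers(0, len(combos), size=config.n_observations)
    for i in idx:
        chem, material, _tpl = combos[i]
        arch = archetypes[allocate_product(material)]
        geom = arch.geometry
        mat = materials.get(material)
        c0 = 10.0 ** rng.uniform(np.log10(config.c0_range[0]), np.log10(config.c0_range[1]))
        t_min = 10.0 ** rng.uniform(
            np.log10(config.contact_time_range_min[0]),
            np.log10(config.contact_time_range_min[1]),
        )
        in_vivo = bool(rng.random() < config.p_in_vivo)
        agitation = bool((not in_vivo) and rng.random() < config.p_agitation)
        medium = MediumSpec(
            etoh_eq=select_etoh_eq(MediumSpec(in_vivo=in_vivo, agitation=agitation)),
            in_vivo=in_vivo,
            agitation=agitation,
        )
        dp = float(estimate_dp(chem, mat))
        kms = float(estimate_kms(chem, mat, medium))
        inputs = MechanisticInputs(
            d_p_coeff=dp, k_pf=kms, geometry=geom, c0=c0, duration=t_min * 60.0
        )
        result = migrated_fraction(inputs)
        rate_true = migration_rate(result, inputs, mat.density)
        noise = 10.0 ** rng.normal(0.0, config.log10_noise_sd) if config.log10_noise_sd else 1.0
        rows.append({
            "chemical_cas": chem.cas,
            "chemical_name": chem.name,
            "chemical_group": chem.group,
            "mw_g_mol": chem.mw,
            "log_kow": chem.log_kow,
            "material": material,
            "study_id": study_ids[i],
            "c0_ug_g": c0,
            "rate_ug_per_10cm2_min": rate_true * noise,
            "contact_time_min": t_min,
            "sample_area_cm2": geom.a_contact,
            "sample_thickness_cm": geom.d_p,
            "in_vivo": in_vivo,
            "agitation": agitation,
            "product_archetype": arch.name,
            "rate_true_ug_per_10cm2_min": rate_true,
        })
    df = pd.DataFrame(rows, columns=list(COLUMNS) + ["rate_true_ug_per_10cm2_min"])
    return Dataset(df=df, diagnostics=[])
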