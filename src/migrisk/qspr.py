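"""Chemical-in-material property estimation (QSPRs).

The migration model needs two parameters for every chemical–material pair:

* ``D_p`` — the diffusion coefficient of the chemical inside the product
  material (cm²/s), estimated from molar mass and a material-specific
  log-linear regression: ``log10 D_p = a + b·MW`` with ``b ≤ 0``.
* ``K_ms`` — the equilibrium material–saliva partition coefficient
  (dimensionless), estimated from log10 Kow, the material, and the
  ethanol-equivalency (EtOH-eq) of the receiving medium:
  ``log10 K_ms = a + b·log10 Kow − c·(EtOH-eq/100)`` with ``b, c ≥ 0``.
  log10 Kow is capped at 11, the high end of the QSPR applicability domain.

Saliva is treated as a food simulant: an EtOH-eq of 20% proxies saliva in
quiescent in-vitro tests, while 50% (the EtOH-eq of flesh) is used for
in-vivo or mechanically agitated experiments — and as a conservative
choice — because saliva in the mouth exchanges rapidly with surrounding
tissue.

Coefficients are data, not code: they load from a YAML material library
(:class:`MaterialLibrary`), one record per material, so a user can swap in
coefficient sets from any published QSPR without touching the code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import yaml

from .errors import DomainError, UnsupportedMaterialError

__all__ = [
    "LOG_KOW_CAP",
    "ChemicalRecord",
    "MaterialParams",
    "MaterialLibrary",
    "MediumSpec",
    "PropertyEstimate",
    "QSPRSpec",
    "default_material_library",
    "estimate_dp",
    "estimate_kms",
    "select_etoh_eq",
    "validate_cas",
]

#: High-end log10 Kow applicability limit of the partition QSPR; larger
#: values are capped here before evaluation, never rejected.
LOG_KOW_CAP = 11.0


def validate_cas(cas: str) -> bool:
    """Check a CAS registry number's format and checksum digit.

    The CAS check digit is ``(Σ i·d_i) mod 10`` over the non-check digits
    numbered right to left.
    """
    parts = cas.strip().split("-")
    if len(parts) != 3 or not all(p.isdigit() for p in parts):
        return False
    if not (2 <= len(parts[0]) <= 7 and len(parts[1]) == 2 and len(parts[2]) == 1):
        return False
    digits = parts[0] + parts[1]
    check = sum(i * int(d) for i, d in enumerate(reversed(digits), start=1)) % 10
    return check == int(parts[2])


@dataclass(frozen=True)
class ChemicalRecord:
    """Identity and the two chemical properties both predictors consume."""

    name: str
    mw: float  # molar mass, g/mol
    log_kow: float  # log10 octanol-water partition coefficient
    cas: str = ""  # CAS registry number; checksum-validated when non-empty
    group: str = ""  # chemical-group label, e.g. "parabens"

    def __post_init__(self) -> None:
        if not (self.mw > 0):
            raise DomainError(f"mw must be > 0, got {self.mw}")
        if not math.isfinite(self.log_kow):
            raise DomainError(f"log_kow must be finite, got {self.log_kow}")
        if self.cas and not validate_cas(self.cas):
            raise DomainError(f"invalid CAS registry number: {self.cas!r}")


@dataclass(frozen=True)
class MediumSpec:
    """The saliva-side medium: EtOH-eq percent plus experimental-method flags."""

    etoh_eq: float = 20.0  # percent, 0-100
    in_vivo: bool = False
    agitation: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.etoh_eq <= 100.0):
            raise DomainError(f"etoh_eq must be in [0, 100], got {self.etoh_eq}")


def select_etoh_eq(medium: MediumSpec, conservative: bool = False) -> float:
    """EtOH-eq policy: 50% for in-vivo, agitated, or conservative use; else 20%."""
    return 50.0 if (medium.in_vivo or medium.agitation or conservative) else 20.0


@dataclass(frozen=True)
class QSPRSpec:
    """A named functional form plus its coefficient set for one material."""

    name: str
    coefficients: Mapping[str, float]
    mw_domain: tuple[float, float] | None = None  # applicability range, g/mol


@dataclass(frozen=True)
class MaterialParams:
    material: str
    density: float  # g/cm3
    dp_qspr: QSPRSpec
    kms_qspr: QSPRSpec
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (self.density > 0):
            raise DomainError(f"density must be > 0, got {self.density}")
        dp = self.dp_qspr.coefficients
        if dp.get("slope_mw", 0.0) > 0:
            raise DomainError("dp_qspr slope_mw must be <= 0 (D_p non-increasing in MW)")
        km = self.kms_qspr.coefficients
        if km.get("slope_log_kow", 0.0) < 0 or km.get("etoh_sensitivity", 0.0) < 0:
            raise DomainError(
                "kms_qspr requires slope_log_kow >= 0 and etoh_sensitivity >= 0"
            )


@dataclass(frozen=True)
class PropertyEstimate:
    """A QSPR output with any applicability-domain warnings attached.

    Out-of-domain inputs warn rather than fail: the estimate is an
    extrapolation, and screening workflows must not abort on edge rows.
    Supports float() so estimates drop into arithmetic directly.
    """

    value: float
    warnings: tuple[str, ...] = ()

    def __float__(self) -> float:
        return self.value


def estimate_dp(chemical: ChemicalRecord, material: MaterialParams) -> PropertyEstimate:
    """Diffusion coefficient of ``chemical`` inside ``material``, cm²/s.

    Evaluates the material's log-linear QSPR ``log10 D_p = a + b·MW``.
    MW outside the coefficient set's applicability domain attaches a
    warning to the result.
    """
    c = material.dp_qspr.coefficients
    log10_dp = c["intercept"] + c["slope_mw"] * chemical.mw
    warnings: tuple[str, ...] = ()
    dom = material.dp_qspr.mw_domain
    if dom is not None and not (dom[0] <= chemical.mw <= dom[1]):
        warnings = (
            f"MW {chemical.mw:g} g/mol outside D_p QSPR domain "
            f"[{dom[0]:g}, {dom[1]:g}] for {material.material}; extrapolating",
        )
    return PropertyEstimate(10.0 ** log10_dp, warnings)


def estimate_kms(
    chemical: ChemicalRecord, material: MaterialParams, medium: MediumSpec
) -> PropertyEstimate:
    """Material–saliva partition coefficient K_ms, dimensionless.

    log10 Kow is capped at :data:`LOG_KOW_CAP` before evaluation; a capped
    input attaches a warning. K_ms is non-decreasing in log Kow and
    non-increasing in EtOH-eq by construction (coefficient signs are
    validated at load time).
    """
    c = material.kms_qspr.coefficients
    warnings: tuple[str, ...] = ()
    log_kow = chemical.log_kow
    if log_kow > LOG_KOW_CAP:
        warnings = (
            f"log Kow {log_kow:g} above QSPR applicability limit; capped at {LOG_KOW_CAP:g}",
        )
        log_kow = LOG_KOW_CAP
    log10_kms = (
        c["intercept"]
        + c["slope_log_kow"] * log_kow
        - c["etoh_sensitivity"] * (medium.etoh_eq / 100.0)
    )
    return PropertyEstimate(10.0 ** log10_kms, warnings)


class MaterialLibrary:
    """The loaded material coefficient table; maps material name -> MaterialParams."""

    def __init__(self, params: Mapping[str, MaterialParams]):
        self._params = dict(params)

    def __contains__(self, material: str) -> bool:
        return material in self._params

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    @property
    def materials(self) -> tuple[str, ...]:
        return tuple(self._params)

    def get(self, material: str) -> MaterialParams:
        try:
            return self._params[material]
        except KeyError:
            raise UnsupportedMaterialError(material, self.materials) from None

    def with_material(self, params: MaterialParams) -> "MaterialLibrary":
        new = dict(self._params)
        new[params.material] = params
        return MaterialLibrary(new)

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MaterialLibrary":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "MaterialLibrary":
        params = {}
        for name, rec in doc["materials"].items():
            params[name] = MaterialParams(
                material=name,
                density=float(rec["density_g_cm3"]),
                dp_qspr=_qspr_from_dict(rec["dp_qspr"]),
                kms_qspr=_qspr_from_dict(rec["kms_qspr"]),
                provenance=str(rec.get("provenance", "")),
            )
        return cls(params)

    def to_dict(self) -> dict:
        doc: dict = {"materials": {}}
        for name, p in self._params.items():
            doc["materials"][name] = {
                "density_g_cm3": p.density,
                "dp_qspr": _qspr_to_dict(p.dp_qspr),
                "kms_qspr": _qspr_to_dict(p.kms_qspr),
                "provenance": p.provenance,
            }
        return doc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _qspr_from_dict(rec: Mapping) -> QSPRSpec:
    dom = rec.get("mw_domain")
    return QSPRSpec(
        name=str(rec["name"]),
        coefficients={k: float(v) for k, v in rec["coefficients"].items()},
        mw_domain=(float(dom[0]), float(dom[1])) if dom is not None else None,
    )


def _qspr_to_dict(spec: QSPRSpec) -> dict:
    rec: dict = {"name": spec.name, "coefficients": dict(spec.coefficients)}
    if spec.mw_domain is not None:
        rec["mw_domain"] = list(spec.mw_domain)
    return rec


def default_material_library() -> MaterialLibrary:
    """The material library shipped with the package (editable defaults)."""
    ref = resources.files("migrisk.data").joinpath("materials.yaml")
    with resources.as_file(ref) as path:
        return MaterialLibrary.from_yaml(path)
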