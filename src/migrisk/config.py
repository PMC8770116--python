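"""Product archetype geometry configuration.

Every prediction needs a slab/contact geometry. Rather than asking for
four numbers per row, products are grouped into *archetypes* — pacifier
(mouthed long-term) and doll (mouthed occasionally) — each shipping a
default geometry in ``data/archetypes.yaml`` that users can override with
their own YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import DomainError
from .mechanistic import MigrationGeometry

__all__ = ["ProductArchetype", "load_archetypes", "default_archetypes"]


@dataclass(frozen=True)
class ProductArchetype:
    name: str
    d_p_cm: float
    v_p_cm3: float
    v_f_cm3: float
    a_contact_cm2: float
    material_default: str = ""

    def __post_init__(self) -> None:
        for f in ("d_p_cm", "v_p_cm3", "v_f_cm3", "a_contact_cm2"):
            if not (getattr(self, f) > 0):
                raise DomainError(f"{f} must be > 0, got {getattr(self, f)}")

    @property
    def geometry(self) -> MigrationGeometry:
        return MigrationGeometry(
            d_p=self.d_p_cm,
            a_contact=self.a_contact_cm2,
            v_p=self.v_p_cm3,
            v_f=self.v_f_cm3,
        )


def load_archetypes(path: str | Path) -> dict[str, ProductArchetype]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _archetypes_from_dict(doc)


def _archetypes_from_dict(doc: Mapping) -> dict[str, ProductArchetype]:
    out = {}
    for name, rec in doc["archetypes"].items():
        out[name] = ProductArchetype(
            name=name,
            d_p_cm=float(rec["d_p_cm"]),
            v_p_cm3=float(rec["v_p_cm3"]),
            v_f_cm3=float(rec["v_f_cm3"]),
            a_contact_cm2=float(rec["a_contact_cm2"]),
            material_default=str(rec.get("material_default", "")),
        )
    return out


def default_archetypes() -> dict[str, ProductArchetype]:
    ref = resources.files("migrisk.data").joinpath("archetypes.yaml")
    with resources.as_file(ref) as path:
        return load_archetypes(path)
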