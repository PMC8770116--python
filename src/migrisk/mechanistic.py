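"""Mechanistic material–saliva migration model.

A children's product in the mouth is modelled as a one-sided polymer slab
in contact with a finite volume of saliva, the same configuration used for
chemical migration from food-contact packaging into liquid food. Migration
proceeds in two regimes:

* **short-term diffusion** — before the deviation time ``t_dev`` the
  migrated fraction follows the Fickian thin-slab solution
  ``f_ts = (2/d_p)·sqrt(D_p·t/π)`` (√t growth);
* **saturation** — after ``t_dev`` a two-exponential relaxation carries
  the fraction from ``f(t_dev)`` to its partition-limited equilibrium
  ``α/(1+α)``, where ``α = (1/K_pf)·(V_f/V_p)`` is the saliva-side
  capacity relative to the product.

``t_dev``, the rate parameter ``β`` and the exponential weights A, B, C
are empirical functions of ``α`` fitted for this model family; ``log`` in
those expressions is base-10 (one central helper, :func:`_log10`). The
fraction is converted to a migration rate per 10 cm² of mouthed area per
minute of contact.

All time-like inputs are seconds and lengths centimetres internally; the
single unit conversion to µg/10cm²/min happens in :func:`migration_rate`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import DomainError, UndefinedRateError

__all__ = [
    "MigrationGeometry",
    "MechanisticInputs",
    "SaturationParams",
    "MechanisticResult",
    "Regime",
    "capacity_ratio",
    "deviation_time",
    "short_term_fraction",
    "saturation_coefficients",
    "migrated_fraction",
    "migration_rate",
]


def _log10(x: float) -> float:
    # Base-10 is used throughout the empirical α-correlations; centralised
    # so the convention lives in exactly one place.
    return math.log10(x)


class Regime(str, enum.Enum):
    SHORT_TERM_DIFFUSION = "short_term_diffusion"
    SATURATION = "saturation"


@dataclass(frozen=True)
class MigrationGeometry:
    """Slab and contact geometry of the mouthed product."""

    d_p: float  # product wall thickness, cm
    a_contact: float  # mouthing contact area, cm2
    v_p: float  # product volume, cm3
    v_f: float  # saliva volume in contact, cm3

    def __post_init__(self) -> None:
        for name in ("d_p", "a_contact", "v_p", "v_f"):
            if not (getattr(self, name) > 0):
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class MechanisticInputs:
    d_p_coeff: float  # diffusion coefficient D_p, cm2/s
    k_pf: float  # product-saliva partition coefficient K_pf (= K_ms)
    geometry: MigrationGeometry
    c0: float  # initial concentration in product, ug/g
    duration: float  # contact time, s

    def __post_init__(self) -> None:
        if not (self.d_p_coeff > 0):
            raise DomainError(f"d_p_coeff must be > 0, got {self.d_p_coeff}")
        if not (self.k_pf > 0):
            raise DomainError(f"k_pf must be > 0, got {self.k_pf}")
        if self.c0 < 0:
            raise DomainError(f"c0 must be >= 0, got {self.c0}")
        if self.duration < 0:
            raise DomainError(f"duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class SaturationParams:
    """The α-derived quantities of the saturation regime (diagnostics)."""

    alpha: float
    beta: float  # 1/s
    a_coef: float
    b_coef: float
    c_coef: float
    t_dev: float  # s
    f_tdev: float


@dataclass(frozen=True)
class MechanisticResult:
    f_mgr: float  # migrated fraction, dimensionless
    regime: Regime
    saturation: SaturationParams
    warnings: tuple[str, ...] = ()


def capacity_ratio(k_pf: float, v_f: float, v_p: float) -> float:
    """Capacity ratio α = (1/K_pf)·(V_f/V_p); f_mgr saturates at α/(1+α)."""
    if not (k_pf > 0 and v_f > 0 and v_p > 0):
        raise DomainError("capacity_ratio requires k_pf, v_f, v_p > 0")
    return (1.0 / k_pf) * (v_f / v_p)


def deviation_time(d_p: float, dp_coeff: float, alpha: float) -> float:
    """Time at which kinetics leave the pure-diffusion branch, seconds.

    t_dev scales exactly as d_p²/D_p; the dimensionless prefactor is a
    piecewise empirical function of α (logistic above α = 0.2, power law
    below; the two branches agree within a few percent at the boundary).
    """
    if not (d_p > 0 and dp_coeff > 0 and alpha > 0):
        raise DomainError("deviation_time requires d_p, D_p, alpha > 0")
    scale = d_p * d_p / dp_coeff
    if alpha > 0.2:
        pref = 0.3552 / (1.0 + 85.88 * math.exp(-3.506 * _log10(alpha)))
    else:
        pref = 0.0085 * math.exp(4.458 * _log10(alpha))
    return scale * pref


def short_term_fraction(d_p: float, dp_coeff: float, t: float) -> float:
    """Fickian thin-slab migrated fraction f_ts = (2/d_p)·sqrt(D_p·t/π)."""
    if not (d_p > 0 and dp_coeff > 0):
        raise DomainError("short_term_fraction requires d_p, D_p > 0")
    if t < 0:
        raise DomainError(f"t must be >= 0, got {t}")
    return (2.0 / d_p) * math.sqrt(dp_coeff * t / math.pi)


def saturation_coefficients(alpha: float) -> tuple[float, float, float]:
    """Exponential weights (A, B, C) of the saturation branch.

    Each is a clamped power law of α: A in [0.7, 1], B in [0.3, 0.9], and
    C drops to the constant 0.004 below its threshold (0.3) and clamps at
    1 above — the asymmetric C rule is implemented exactly as specified
    for this model family.
    """
    if not (alpha > 0):
        raise DomainError(f"alpha must be > 0, got {alpha}")
    la = _log10(alpha)
    x1 = 10.0 ** (0.12 * la + _log10(0.8))
    x2 = 10.0 ** (0.22 * la + _log10(0.5))
    x3 = 10.0 ** (0.7 * la + _log10(0.08))
    a = 0.7 if x1 < 0.7 else (1.0 if x1 > 1.0 else x1)
    b = 0.3 if x2 < 0.3 else (0.9 if x2 > 0.9 else x2)
    c = 0.004 if x3 < 0.3 else (1.0 if x3 > 1.0 else x3)
    return a, b, c


def _saturation_params(inputs: MechanisticInputs) -> tuple[SaturationParams, tuple[str, ...]]:
    g = inputs.geometry
    alpha = capacity_ratio(inputs.k_pf, g.v_f, g.v_p)
    t_dev = deviation_time(g.d_p, inputs.d_p_coeff, alpha)
    f_tdev = short_term_fraction(g.d_p, inputs.d_p_coeff, t_dev)
    a, b, c = saturation_coefficients(alpha)
    f_inf = alpha / (1.0 + alpha)
    warnings: tuple[str, ...] = ()
    radicand = inputs.d_p_coeff / (math.pi * t_dev) * (f_inf - f_tdev)
    if radicand < 0.0:
        # Pathological geometry: equilibrium capacity below the fraction
        # already migrated at t_dev. β is then meaningless; the fraction
        # is clamped at f_inf downstream.
        warnings = (
            f"equilibrium fraction {f_inf:.3g} below f(t_dev) {f_tdev:.3g}; "
            "migrated fraction clamped at alpha/(1+alpha)",
        )
        beta = 0.0
    else:
        beta = (1.0 / g.d_p) * math.sqrt(radicand)
    return SaturationParams(alpha, beta, a, b, c, t_dev, f_tdev), warnings


def migrated_fraction(inputs: MechanisticInputs) -> MechanisticResult:
    """Fraction of the chemical in the contacted slab migrated after ``duration``.

    Dispatches on the deviation time: the Fickian branch for
    ``t <= t_dev``, the two-exponential saturation branch after. The
    result always satisfies ``0 <= f_mgr <= α/(1+α)``; inputs that would
    violate the bound are clamped with a warning instead of failing, so
    screening runs survive edge rows.
    """
    sat, warnings = _saturation_params(inputs)
    g = inputs.geometry
    t = inputs.duration
    f_inf = sat.alpha / (1.0 + sat.alpha)
    if t <= sat.t_dev:
        f = short_term_fraction(g.d_p, inputs.d_p_coeff, t)
        regime = Regime.SHORT_TERM_DIFFUSION
    else:
        dt = t - sat.t_dev
        relax = sat.a_coef * (1.0 - math.exp(-sat.b_coef * sat.beta * dt)) + (
            1.0 - sat.a_coef
        ) * (1.0 - math.exp(-sat.c_coef * sat.beta * dt))
        f = sat.f_tdev + (f_inf - sat.f_tdev) * relax
        regime = Regime.SATURATION
    if f > f_inf:
        warnings = warnings + (
            f"migrated fraction {f:.3g} clamped at equilibrium {f_inf:.3g}",
        )
        f = f_inf
    return MechanisticResult(f_mgr=f, regime=regime, saturation=sat, warnings=warnings)


def migration_rate(
    result: MechanisticResult, inputs: MechanisticInputs, material_density: float
) -> float:
    """Convert a migrated fraction to a rate, µg per 10 cm² per minute.

    The initial mass m₀ refers to the one-sided slab engaged in migration
    under the mouthed area: m₀ = C₀ × density × (A_contact × d_p), so the
    rate is independent of total product size and linear in C₀.
    """
    if not (material_density > 0):
        raise DomainError(f"material_density must be > 0, got {material_density}")
    if inputs.duration <= 0:
        raise UndefinedRateError("migration rate undefined for zero contact time")
    g = inputs.geometry
    m0 = inputs.c0 * material_density * g.a_contact * g.d_p  # ug
    t_min = inputs.duration / 60.0
    return result.f_mgr * m0 / ((g.a_contact / 10.0) * t_min)
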