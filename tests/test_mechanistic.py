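"""Migration kinetics: deviation time, Fickian short-term branch,
two-exponential saturation, and the rate conversion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from migrisk import (
    MechanisticInputs,
    MigrationGeometry,
    Regime,
    capacity_ratio,
    deviation_time,
    migrated_fraction,
    migration_rate,
    saturation_coefficients,
    short_term_fraction,
)
from migrisk.errors import DomainError, UndefinedRateError


def oracle_fraction(dp_c, kpf, d, vp, vf, t):
    """Independent single-expression re-evaluation of the migration model.

    Written straight from the closed-form definitions, organized completely
    differently from the implementation, as an oracle for equivalence tests.
    """
    a = (1.0 / kpf) * (vf / vp)
    la = math.log10(a)
    pref = (
        0.3552 / (1.0 + 85.88 * math.exp(-3.506 * la))
        if a > 0.2
        else 0.0085 * math.exp(4.458 * la)
    )
    td = d * d / dp_c * pref
    if t <= td:
        return min((2.0 / d) * math.sqrt(dp_c * t / math.pi), a / (1.0 + a))
    ftd = (2.0 / d) * math.sqrt(dp_c * td / math.pi)
    A = min(max(10.0 ** (0.12 * la + math.log10(0.8)), 0.7), 1.0)
    B = min(max(10.0 ** (0.22 * la + math.log10(0.5)), 0.3), 0.9)
    x3 = 10.0 ** (0.7 * la + math.log10(0.08))
    C = 0.004 if x3 < 0.3 else (1.0 if x3 > 1.0 else x3)
    finf = a / (1.0 + a)
    beta = (1.0 / d) * math.sqrt(dp_c / (math.pi * td) * max(finf - ftd, 0.0))
    f = ftd + (finf - ftd) * (
        A * (1.0 - math.exp(-B * beta * (t - td)))
        + (1.0 - A) * (1.0 - math.exp(-C * beta * (t - td)))
    )
    return min(f, finf)


def make_inputs(dp_c=1e-10, kpf=10.0, d=0.1, vp=50.0, vf=5.0, c0=1000.0, t=3600.0):
    geom = MigrationGeometry(d_p=d, a_contact=10.0, v_p=vp, v_f=vf)
    return MechanisticInputs(d_p_coeff=dp_c, k_pf=kpf, geometry=geom, c0=c0, duration=t)


def random_inputs(rng):
    return make_inputs(
        dp_c=10.0 ** rng.uniform(-14, -6),
        kpf=10.0 ** rng.uniform(-2, 8),
        d=rng.uniform(0.05, 1.0),
        vp=10.0 ** rng.uniform(0, 2),
        vf=10.0 ** rng.uniform(0, 1),
        c0=10.0 ** rng.uniform(1, 5),
        t=10.0 ** rng.uniform(0, 7),
    )


class TestCapacityRatio:
    @pytest.mark.parametrize(
        "kpf,vf,vp,expected",
        [(1.0, 1.0, 1.0, 1.0), (10.0, 5.0, 1.0, 0.5), (1e6, 1.0, 1.0, 1e-6)],
    )
    def test_values(self, kpf, vf, vp, expected):
        assert capacity_ratio(kpf, vf, vp) == pytest.approx(expected, rel=1e-14)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            capacity_ratio(0.0, 1.0, 1.0)


class TestDeviationTime:
    def test_large_alpha_limit(self):
        # the logistic term vanishes, leaving 0.3552 d²/D_p
        t = deviation_time(0.1, 1e-10, 1e12)
        assert t == pytest.approx(0.3552 * 0.01 / 1e-10, rel=1e-6)

    def test_alpha_one_closed_form(self):
        t = deviation_time(0.1, 1e-10, 1.0)
        assert t == pytest.approx((0.01 / 1e-10) * 0.3552 / (1.0 + 85.88), rel=1e-13)

    def test_branches_agree_near_boundary(self):
        # the two empirical branches nearly match at α = 0.2 (log10 reading)
        d, dp_c = 0.2, 1e-9
        scale = d * d / dp_c
        upper = 0.3552 / (1.0 + 85.88 * math.exp(-3.506 * math.log10(0.2))) * scale
        lower = deviation_time(d, dp_c, 0.2)  # α ≤ 0.2 branch
        assert abs(upper - lower) / lower < 0.10

    @given(
        st.floats(min_value=0.05, max_value=1.0),
        st.floats(min_value=-14, max_value=-6),
        st.floats(min_value=-6, max_value=6),
    )
    def test_scale_invariance(self, d, log_dp, log_alpha):
        # t_dev·D_p/d_p² is a function of α alone
        dp_c = 10.0 ** log_dp
        alpha = 10.0 ** log_alpha
        ref = deviation_time(1.0, 1.0, alpha)
        assert deviation_time(d, dp_c, alpha) * dp_c / d**2 == pytest.approx(
            ref, rel=1e-12
        )


class TestShortTermFraction:
    def test_zero_time(self):
        assert short_term_fraction(0.1, 1e-10, 0.0) == 0.0

    def test_sqrt_time_scaling(self):
        f1 = short_term_fraction(0.1, 1e-10, 250.0)
        f4 = short_term_fraction(0.1, 1e-10, 1000.0)
        assert f4 == pytest.approx(2.0 * f1, rel=1e-13)

    def test_worked_value(self):
        # (2/0.1)·sqrt(1e-10·3600/π)
        got = short_term_fraction(0.1, 1e-10, 3600.0)
        assert got == pytest.approx(20.0 * math.sqrt(3.6e-7 / math.pi), rel=1e-13)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            short_term_fraction(0.1, 1e-10, -1.0)


class TestSaturationCoefficients:
    def test_alpha_one_exact(self):
        a, b, c = saturation_coefficients(1.0)
        assert (a, b) == (pytest.approx(0.8, abs=1e-14), pytest.approx(0.5, abs=1e-14))
        assert c == 0.004  # x3 = 0.08 < 0.3 triggers the constant

    def test_upper_clamp(self):
        a, b, c = saturation_coefficients(1e10)
        assert (a, b, c) == (1.0, 0.9, 1.0)

    def test_lower_clamp(self):
        a, b, c = saturation_coefficients(1e-10)
        assert (a, b, c) == (0.7, 0.3, 0.004)

    @given(st.floats(min_value=-12, max_value=12))
    def test_ranges(self, log_alpha):
        a, b, c = saturation_coefficients(10.0 ** log_alpha)
        assert 0.7 <= a <= 1.0
        assert 0.3 <= b <= 0.9
        assert c == 0.004 or 0.3 <= c <= 1.0


class TestMigratedFraction:
    def test_zero_time_gives_zero(self):
        res = migrated_fraction(make_inputs(t=0.0))
        assert res.f_mgr == 0.0
        assert res.regime is Regime.SHORT_TERM_DIFFUSION

    def test_infinite_time_approaches_equilibrium(self):
        inp = make_inputs(kpf=2.0, t=1e15, dp_c=1e-8)
        res = migrated_fraction(inp)
        alpha = res.saturation.alpha
        assert res.regime is Regime.SATURATION
        assert res.f_mgr == pytest.approx(alpha / (1.0 + alpha), rel=1e-9)

    def test_branch_continuity_at_t_dev(self):
        inp = make_inputs()
        t_dev = migrated_fraction(inp).saturation.t_dev
        below = migrated_fraction(make_inputs(t=t_dev))
        above = migrated_fraction(make_inputs(t=t_dev * (1 + 1e-12)))
        assert below.regime is Regime.SHORT_TERM_DIFFUSION
        assert above.regime is Regime.SATURATION
        assert abs(below.f_mgr - above.f_mgr) < 1e-12

    def test_oracle_equivalence_on_random_grid(self):
        # independent single-expression re-evaluation, 1000 random inputs
        rng = np.random.default_rng(20240901)
        worst = 0.0
        for _ in range(1000):
            inp = random_inputs(rng)
            got = migrated_fraction(inp).f_mgr
            want = oracle_fraction(
                inp.d_p_coeff, inp.k_pf, inp.geometry.d_p,
                inp.geometry.v_p, inp.geometry.v_f, inp.duration,
            )
            denom = max(abs(want), 1e-300)
            worst = max(worst, abs(got - want) / denom)
        assert worst < 1e-12

    def test_bounds_and_monotonicity_in_time(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            base = random_inputs(rng)
            alpha = capacity_ratio(base.k_pf, base.geometry.v_f, base.geometry.v_p)
            cap = alpha / (1.0 + alpha)
            times = np.sort(10.0 ** rng.uniform(0, 7, size=5))
            prev = -1.0
            for t in times:
                f = migrated_fraction(make_inputs(
                    dp_c=base.d_p_coeff, kpf=base.k_pf, d=base.geometry.d_p,
                    vp=base.geometry.v_p, vf=base.geometry.v_f, t=float(t),
                )).f_mgr
                assert 0.0 <= f <= cap + 1e-15
                assert f >= prev - 1e-12
                prev = f

    def test_monotone_in_diffusivity_short_term(self):
        lo = migrated_fraction(make_inputs(dp_c=1e-12, t=10.0))
        hi = migrated_fraction(make_inputs(dp_c=1e-11, t=10.0))
        assert lo.regime is Regime.SHORT_TERM_DIFFUSION
        assert hi.f_mgr >= lo.f_mgr

    def test_pathological_geometry_clamps_with_warning(self):
        # absurdly small α makes f(t_dev) exceed the equilibrium fraction
        inp = make_inputs(kpf=1e38, vp=100.0, vf=1.0, t=1e-3)
        res = migrated_fraction(inp)
        alpha = res.saturation.alpha
        assert res.f_mgr <= alpha / (1.0 + alpha)
        assert res.warnings


class TestMigrationRate:
    def test_zero_fraction_zero_rate(self):
        inp = make_inputs(t=3600.0, c0=0.0)
        res = migrated_fraction(inp)
        assert migration_rate(res, inp, 1.0) == 0.0

    def test_linear_in_initial_concentration(self):
        a = make_inputs(c0=100.0)
        b = make_inputs(c0=200.0)
        ra = migration_rate(migrated_fraction(a), a, 1.3)
        rb = migration_rate(migrated_fraction(b), b, 1.3)
        assert rb == pytest.approx(2.0 * ra, rel=1e-13)

    def test_worked_unit_conversion(self):
        # f=0.01, m0 = 500 µg/g × 1 g/cm³ × (10 cm² × 0.2 cm) = 1000 µg,
        # A=10 cm², t=60 min → 0.01·1000/(1·60) µg/10cm²/min
        import dataclasses

        inp = make_inputs(d=0.2, c0=500.0, t=3600.0)
        res = dataclasses.replace(migrated_fraction(inp), f_mgr=0.01)
        assert migration_rate(res, inp, 1.0) == pytest.approx(0.01 * 1000.0 / 60.0, rel=1e-13)

    def test_zero_time_rate_undefined_fraction_defined(self):
        inp = make_inputs(t=0.0)
        res = migrated_fraction(inp)
        assert res.f_mgr == 0.0
        with pytest.raises(UndefinedRateError):
            migration_rate(res, inp, 1.0)
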