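"""Mouthing scenarios, daily exposure doses, hazard quotients, and
inventory screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from migrisk import MouthingScenario, builtin_scenarios, daily_exposure, hazard_quotient
from migrisk.dataset import COLUMNS
from migrisk.errors import DomainError
from migrisk.exposure import (
    AgeGroup,
    Percentile,
    load_rfd_table,
    load_scenarios,
    risk_summary,
    screen_inventory,
)


def scenario(bw=10.0, pac=1.0, doll=1.0, active=24.0,
             age=AgeGroup.M3_TO_6, pct=Percentile.AVERAGE):
    return MouthingScenario(age_group=age, percentile=pct, bw=bw,
                            duration_pacifier=pac, duration_doll=doll,
                            active_hours_per_day=active)


class TestBuiltinScenarios:
    @pytest.mark.parametrize("age,pct,bw,pac,doll", [
        (AgeGroup.M3_TO_6, Percentile.AVERAGE, 7.4, 3.4, 0.5),
        (AgeGroup.M3_TO_6, Percentile.P99, 7.4, 37.3, 2.5),
        (AgeGroup.Y2_TO_3, Percentile.AVERAGE, 13.8, 1.8, 0.4),
        (AgeGroup.Y2_TO_3, Percentile.P99, 13.8, 46.3, 2.9),
    ])
    def test_preset_values(self, age, pct, bw, pac, doll):
        match = [s for s in builtin_scenarios()
                 if s.age_group is age and s.percentile is pct]
        assert len(match) == 1
        s = match[0]
        assert (s.bw, s.duration_pacifier, s.duration_doll) == (bw, pac, doll)

    def test_all_presets_positive(self):
        for s in builtin_scenarios():
            assert s.bw > 0 and s.duration_pacifier > 0 and s.duration_doll > 0


class TestDailyExposure:
    def test_zero_rate_zero_dose(self):
        assert daily_exposure(0.0, scenario(), "doll").e_mouthing == 0.0

    def test_worked_unit_example(self):
        # Δt = 2.5 min/h × 24 h/d = 60 min/d; A = 10 cm²; BW = 10 kg;
        # rate 1 µg/10cm²/min → 6 µg/kg_BW/d
        est = daily_exposure(1.0, scenario(doll=2.5), "doll", a_contact=10.0)
        assert est.e_mouthing == pytest.approx(6.0, rel=1e-13)

    def test_dose_scales_with_duration_ratio(self):
        avg = daily_exposure(0.3, scenario(pac=3.4), "pacifier")
        p99 = daily_exposure(0.3, scenario(pac=37.3), "pacifier")
        assert p99.e_mouthing == pytest.approx(avg.e_mouthing * 37.3 / 3.4, rel=1e-12)

    @given(
        st.floats(min_value=1e-6, max_value=1e3),
        st.floats(min_value=0.1, max_value=40.0),
        st.floats(min_value=1.0, max_value=30.0),
        st.floats(min_value=1.0, max_value=100.0),
    )
    def test_linearity_and_bw_inverse(self, rate, dur, bw, area):
        base = daily_exposure(rate, scenario(bw=bw, doll=dur), "doll", a_contact=area)
        double_rate = daily_exposure(2 * rate, scenario(bw=bw, doll=dur), "doll",
                                     a_contact=area)
        double_bw = daily_exposure(rate, scenario(bw=2 * bw, doll=dur), "doll",
                                   a_contact=area)
        assert double_rate.e_mouthing == pytest.approx(2 * base.e_mouthing, rel=1e-12)
        assert double_bw.e_mouthing == pytest.approx(base.e_mouthing / 2, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            daily_exposure(-1.0, scenario(), "doll")


class TestHazardQuotient:
    def test_exposure_equal_to_rfd_is_threshold(self):
        assert hazard_quotient(5.0, 5.0).hq == 1.0

    def test_zero_exposure(self):
        assert hazard_quotient(0.0, 5.0).hq == 0.0

    def test_simple_ratio(self):
        assert hazard_quotient(2.5, 5.0).hq == 0.5

    def test_nonpositive_rfd_rejected(self):
        with pytest.raises(DomainError):
            hazard_quotient(1.0, 0.0)


def inventory_df(rows):
    base = {c: "" for c in COLUMNS}
    out = []
    for r in rows:
        rec = dict(base)
        rec.update({
            "chemical_cas": "", "chemical_name": r.get("name", "chem"),
            "material": r.get("material", "PVC"),
            "product_archetype": r.get("archetype", "doll"),
            "rate_ug_per_10cm2_min": r["rate"],
            "sample_area_cm2": r.get("area", 10.0),
        })
        out.append(rec)
    return pd.DataFrame(out)


def rfd_df(entries):
    return pd.DataFrame(
        [{"chemical_key": k, "rfd_ug_per_kg_d": v, "rfd_source": "experimental"}
         for k, v in entries.items()]
    )


class TestScreenInventory:
    def test_cardinality_rows_times_scenarios(self):
        df = inventory_df([{"name": "a", "rate": 0.1}, {"name": "b", "rate": 0.2}])
        risk = screen_inventory(df, rfd_df({"a": 1.0, "b": 1.0}))
        assert len(risk) == 8

    def test_p99_hq_at_least_average(self):
        rng = np.random.default_rng(0)
        rows = [{"name": f"c{i}", "rate": float(10.0 ** rng.uniform(-5, 1)),
                 "material": rng.choice(["PVC", "EVA"]),
                 "archetype": rng.choice(["doll", "pacifier"])}
                for i in range(20)]
        risk = screen_inventory(
            df := inventory_df(rows),
            rfd_df({f"c{i}": 10.0 for i in range(20)}),
        )
        for (row_id, age), grp in risk.groupby(["row_id", "age_group"]):
            avg = grp.loc[grp["percentile"] == "average", "hq"].iloc[0]
            p99 = grp.loc[grp["percentile"] == "p99", "hq"].iloc[0]
            assert p99 >= avg

    def test_engineered_hq_fixed_point(self):
        # rate chosen so E equals the RfD in the 3-6 month average doll
        # scenario: Δt = 0.5×24 = 12 min/d, BW 7.4 → E = 12·rate/7.4
        rfd = 5.0
        rate = rfd * 7.4 / 12.0
        df = inventory_df([{"name": "fix", "rate": rate}])
        risk = screen_inventory(df, rfd_df({"fix": rfd}))
        rec = risk[(risk["percentile"] == "average")
                   & (risk["age_group"] == AgeGroup.M3_TO_6.value)]
        assert rec["hq"].iloc[0] == pytest.approx(1.0, rel=1e-12)
        # exactly at threshold: not classified above it
        assert rec["concern"].iloc[0] in ("none", "upper_bound_only")

    def test_upper_bound_only_classification(self):
        # HQ < 1 on average but > 1 at the 99th percentile
        df = inventory_df([{"name": "ub", "rate": 1.0}])
        # avg doll 3-6m: E = 12·1/7.4 = 1.62; pick RfD between avg and p99 doses
        risk = screen_inventory(df, rfd_df({"ub": 3.0}))
        m36 = risk[risk["age_group"] == AgeGroup.M3_TO_6.value]
        assert (m36["concern"] == "upper_bound_only").all()

    def test_missing_rfd_flagged_not_dropped(self):
        df = inventory_df([{"name": "known", "rate": 0.1},
                           {"name": "unknown", "rate": 0.1}])
        risk = screen_inventory(df, rfd_df({"known": 1.0}))
        assert len(risk) == 8
        missing = risk[risk["chemical_key"] == "unknown"]
        assert missing["hq"].isna().all()
        assert (missing["flags"] == "missing_rfd").all()

    def test_summary_counts_exceedances(self):
        df = inventory_df([{"name": "hot", "rate": 100.0},
                           {"name": "cold", "rate": 1e-6}])
        risk = screen_inventory(df, rfd_df({"hot": 1.0, "cold": 1.0}))
        s = risk_summary(risk)
        assert s["n_records"] == 8
        assert sum(s["exceedances_per_scenario"].values()) == int((risk["hq"] > 1).sum())
        assert s["top_hq"][0]["chemical_key"] == "hot"


def test_scenario_yaml_round_trip(tmp_path):
    import yaml

    doc = {"scenarios": [
        {"age_group": s.age_group.value, "percentile": s.percentile.value,
         "bw_kg": s.bw, "duration_pacifier_min_h": s.duration_pacifier,
         "duration_doll_min_h": s.duration_doll}
        for s in builtin_scenarios()
    ]}
    path = tmp_path / "scenarios.yaml"
    path.write_text(yaml.safe_dump(doc))
    loaded = load_scenarios(path)
    assert loaded == builtin_scenarios()


def test_rfd_table_requires_columns(tmp_path):
    path = tmp_path / "rfd.csv"
    pd.DataFrame({"chemical_key": ["a"]}).to_csv(path, index=False)
    with pytest.raises(DomainError):
        load_rfd_table(path)
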