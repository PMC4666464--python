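"""Allometry, CPUE arithmetic, optimal mesh and trend tests."""

import numpy as np
import pandas as pd
import pytest

import gillnetkit as g
from gillnetkit.monitoring import panel_cpue_table

from conftest import set_cpue_frame


def catch_frame(lengths, weights):
    return pd.DataFrame(
        {
            "set_id": "s1",
            "mesh_cm": 2.54,
            "species": "grayling",
            "length_mm": lengths,
            "weight_g": weights,
        }
    )


class TestLengthWeight:
    def test_exact_cubic_recovery(self):
        L = np.array([150.0, 220.0, 300.0, 410.0])
        rec = catch_frame(L, 1e-5 * L**3)
        lw = g.fit_length_weight(rec)
        assert lw.b == pytest.approx(3.0, abs=1e-10)
        assert lw.a == pytest.approx(1e-5, rel=1e-8)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 200
        for _ in range(reps):
            L = rng.uniform(120, 450, size=500)
            w = 2e-5 * L**3.1 * rng.lognormal(0.0, 0.1, size=500)
            lw = g.fit_length_weight(catch_frame(L, w))
            hits += abs(lw.b - 3.1) <= 0.05
        assert hits / reps >= 0.90

    def test_fewer_than_three_weights_rejected(self):
        rec = catch_frame([200.0, 300.0], [80.0, 270.0])
        with pytest.raises(ValueError, match=">= 3"):
            g.fit_length_weight(rec)


class TestImputeWeights:
    def test_complete_weights_untouched(self):
        rec = catch_frame([200.0, 250.0, 300.0], [80.0, 160.0, 270.0])
        lw = g.fit_length_weight(rec)
        out = g.impute_weights(rec, {"grayling": lw})
        pd.testing.assert_series_equal(out["weight_g"], rec["weight_g"])
        assert not out["weight_imputed"].any()

    def test_allometric_fill(self):
        rec = catch_frame([300.0], [np.nan])
        params = {"grayling": g.LWParams(a=1e-5, b=3.0, n=10, log_resid_sd=0.0)}
        out = g.impute_weights(rec, params)
        assert out.loc[0, "weight_g"] == pytest.approx(270.0)
        assert out.loc[0, "weight_imputed"]
        assert (out["weight_g"] > 0).all()

    def test_missing_species_params_rejected(self):
        rec = catch_frame([300.0], [np.nan])
        with pytest.raises(KeyError, match="grayling"):
            g.impute_weights(rec, {})


class TestCpue:
    def test_empty_panel(self):
        empty = catch_frame([], [])
        assert g.panel_cpue(empty, panel_length_m=4.0) == (0.0, 0.0)

    def test_panel_scaling(self):
        rec = catch_frame([200.0, 250.0, 300.0], [400.0, 400.0, 400.0])
        count, kg = g.panel_cpue(rec, panel_length_m=4.0, nights=1)
        assert count == pytest.approx(7.5)
        assert kg == pytest.approx(3.0)

    def test_effort_is_nights_not_hours(self):
        """An overnight set is one night of effort whether it soaked 8.5 or
        10.5 hours."""
        rec = catch_frame([200.0], [100.0])
        assert g.panel_cpue(rec, 4.0, nights=1) == g.panel_cpue(rec, 4.0, nights=1)
        # nights is the only effort divisor
        c1, _ = g.panel_cpue(rec, 4.0, nights=1)
        c2, _ = g.panel_cpue(rec, 4.0, nights=2)
        assert c2 == pytest.approx(c1 / 2)

    def test_set_cpue_additive_over_panels(self):
        rec = catch_frame([200.0] * 5, [200.0] * 5)
        count, kg = g.set_cpue(rec, nights=1)
        assert count == 5.0
        assert kg == pytest.approx(1.0)

    def test_cpue_linear_in_catch(self, small_survey):
        catch, sets, panels = small_survey
        t1 = panel_cpue_table(catch, sets, panels)
        t2 = panel_cpue_table(pd.concat([catch, catch]), sets, panels)
        np.testing.assert_allclose(t2["cpue_count"], 2 * t1["cpue_count"])
        np.testing.assert_allclose(t2["cpue_kg"], 2 * t1["cpue_kg"])

    def test_set_equals_weighted_panel_aggregation(self, small_survey):
        catch, sets, panels = small_survey
        table = panel_cpue_table(catch, sets, panels)
        sid = sets["set_id"].iloc[0]
        sub = table[table["set_id"] == sid]
        # panel CPUE x panel length / 10 summed over panels = set count
        total = float((sub["cpue_count"] * sub["length_m"] / 10.0).sum())
        count, _ = g.set_cpue(catch[catch["set_id"] == sid], nights=1)
        assert total == pytest.approx(count)

    def test_zero_length_panel_rejected(self):
        with pytest.raises(ValueError, match="panel length"):
            g.panel_cpue(catch_frame([], []), panel_length_m=0.0)


class TestOptimalMesh:
    def _table(self, cpue_by_mesh):
        rows = []
        for mesh, vals in cpue_by_mesh.items():
            for v in vals:
                rows.append(
                    {"mesh_cm": mesh, "cpue_count": v, "cpue_kg": v / 2}
                )
        return pd.DataFrame(rows)

    def test_small_mesh_wins_for_abundant_small_species(self):
        """A fishery selecting on a small-bodied abundant species peaks at
        the smallest mesh by count."""
        design = g.SurveyDesign()
        comm = g.CommunityTrendConfig(
            species=(g.SpeciesTrend(name="grayling", mean_length_mm=250.0),)
        )
        catch, sets, panels = g.simulate_catch_survey(design, comm, seed=21)
        table = panel_cpue_table(catch, sets, panels)
        assert g.optimal_mesh(table, "count") == 2.54

    def test_tie_breaks_to_smaller_mesh(self):
        table = self._table({3.81: [2.0, 2.0], 2.54: [2.0, 2.0]})
        assert g.optimal_mesh(table, "count") == 2.54

    def test_biomass_criterion_prefers_mid_mesh_for_large_species(self):
        design = g.SurveyDesign()
        comm = g.CommunityTrendConfig(
            species=(
                g.SpeciesTrend(name="grayling", mean_length_mm=250.0),
                g.SpeciesTrend(
                    name="lenok", mean_length_mm=420.0,
                    log_cpue_intercept=np.log(4.0), lw_a=1.2e-5,
                ),
            )
        )
        catch, sets, panels = g.simulate_catch_survey(design, comm, seed=22)
        table = panel_cpue_table(catch, sets, panels)
        assert g.optimal_mesh(table, "biomass") in (3.81, 5.08)

    def test_single_mesh_rejected(self):
        table = self._table({2.54: [1.0]})
        with pytest.raises(ValueError, match="mesh"):
            g.optimal_mesh(table, "count")


class TestTrendTest:
    def _survey_cpue(self, slope, seed, nets=2):
        design = g.SurveyDesign(nets_per_site=nets)
        comm = g.CommunityTrendConfig(
            species=(g.SpeciesTrend(name="grayling", year_slope=slope),)
        )
        catch, sets, _ = g.simulate_catch_survey(design, comm, seed=seed)
        return set_cpue_frame(catch, sets)

    def test_constant_response_null_result(self):
        d = pd.DataFrame(
            {"y": 3.0, "year": [2009, 2011] * 6, "site": list("AABBCC") * 2}
        )
        r = g.trend_test(d, "y")
        assert (r.slope, r.lr_stat, r.p_value) == (0.0, 0.0, 1.0)

    def test_slope_invariant_to_year_centring(self):
        d = self._survey_cpue(slope=-0.1, seed=3)
        r1 = g.trend_test(d, "cpue")
        d2 = d.assign(year=d["year"] - 2000)
        r2 = g.trend_test(d2, "cpue")
        assert r1.slope == pytest.approx(r2.slope, rel=1e-6)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-6)

    def test_slope_recovery_and_coverage(self):
        """95% Wald intervals on the year slope cover the truth at roughly
        the nominal rate under the stated design (Gaussian response)."""
        rng = np.random.default_rng(8)
        cover = 0
        reps = 200
        for _ in range(reps):
            rows = []
            for si in range(7):
                u = rng.normal(0, 0.2)
                for yr in (2009, 2011, 2012, 2013):
                    for _net in range(2):
                        rows.append(
                            {
                                "site": f"s{si}",
                                "year": yr,
                                "y": 5.0 - 0.10 * (yr - 2009) + u + rng.normal(0, 0.3),
                            }
                        )
            r = g.trend_test(pd.DataFrame(rows), "y")
            cover += abs(r.slope - (-0.10)) <= 1.96 * r.slope_se
        assert cover / reps == pytest.approx(0.95, abs=0.04)

    def test_declining_body_size_detected(self):
        design = g.SurveyDesign(nets_per_site=4)
        comm = g.CommunityTrendConfig(
            species=(g.SpeciesTrend(name="grayling", length_year_slope=-0.05),)
        )
        catch, sets, _ = g.simulate_catch_survey(design, comm, seed=17)
        d = catch.merge(sets[["set_id", "site", "year"]], on="set_id")
        r = g.trend_test(d, "length_mm")
        assert r.slope < 0
        assert r.p_value < 0.01

    def test_single_year_rejected(self):
        d = pd.DataFrame({"y": [1.0, 2.0], "year": [2009, 2009], "site": ["A", "B"]})
        with pytest.raises(ValueError, match="years"):
            g.trend_test(d, "y")

    def test_single_site_falls_back_to_ols(self, caplog):
        rng = np.random.default_rng(0)
        d = pd.DataFrame(
            {
                "y": rng.normal(size=12),
                "year": [2009, 2011, 2012, 2013] * 3,
                "site": "only",
            }
        )
        with caplog.at_level("WARNING"):
            r = g.trend_test(d, "y")
        assert r.site_sd == 0.0
        assert "single site" in caplog.text
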