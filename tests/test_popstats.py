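from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from otoshape.datasets import load_gillnet_catches
from otoshape.popstats import (
    compare_meristics,
    cpue_standardize,
    maturity_trend,
    mixing_proportions,
    spearman_months,
    vs_environment_trend,
)


def make_records(rows):
    defaults = {
        "id": "x", "date": "2012-03-15", "location": "Landvikvannet",
        "population": "LV", "length": 28.0, "weight": 150.0, "sex": "F",
        "maturity": 5, "age": 3, "vs": 56,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestCpue:
    def test_survey_table_examples(self):
        t = cpue_standardize(load_gillnet_catches())
        row = t[(t["date"] == "2012-03-20") & (t["location"] == "Landvikvannet")]
        assert row["cpue"].iloc[0] == pytest.approx(47 / 3)
        row = t[(t["date"] == "2012-05-14") & (t["location"] == "Landvikvannet")]
        assert row["cpue"].iloc[0] == pytest.approx(177.0)

    def test_zero_catch_zero_cpue(self):
        t = cpue_standardize(
            pd.DataFrame({"catch": [0], "nets": [1]})
        )
        assert t["cpue"].iloc[0] == 0.0

    def test_catch_without_nets_rejected(self):
        with pytest.raises(ValueError, match="no gillnets"):
            cpue_standardize(pd.DataFrame({"catch": [10], "nets": [0]}))


class TestMixingProportions:
    def catch_for(self, records, nets=1):
        c = records.groupby(["date", "location"]).size().reset_index(name="catch")
        c["nets"] = nets
        return c

    def test_single_population_gives_one(self):
        rec = make_records([{"id": str(i)} for i in range(20)])
        out = mixing_proportions(rec, self.catch_for(rec))
        assert np.allclose(out["proportion"], 1.0)

    def test_equal_cpue_two_sources_fifty_fifty(self):
        rec = make_records(
            [{"id": str(i), "location": "Landvikvannet", "population": "A"}
             for i in range(10)]
            + [{"id": str(i + 10), "location": "Bufjorden", "population": "B"}
               for i in range(10)]
        )
        out = mixing_proportions(rec, self.catch_for(rec))
        by_pop = out.set_index("population")["proportion"]
        assert by_pop["A"] == pytest.approx(0.5)
        assert by_pop["B"] == pytest.approx(0.5)

    def test_proportions_sum_to_one_and_net_scaling_invariant(self, records_catch):
        records, catch = records_catch
        out = mixing_proportions(records, catch)
        sums = out.groupby("month")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)
        catch10 = catch.assign(nets=catch["nets"] * 10)
        out10 = mixing_proportions(records, catch10)
        merged = out.merge(out10, on=["month", "population"])
        assert np.allclose(merged["proportion_x"], merged["proportion_y"])

    def test_orphan_sample_raises_with_keys(self):
        rec = make_records([{"id": "a"}])
        catch = pd.DataFrame(
            {"date": ["2012-04-15"], "location": ["Bufjorden"],
             "catch": [5], "nets": [1]}
        )
        with pytest.raises(ValueError, match="Landvikvannet"):
            mixing_proportions(rec, catch)

    def test_spawning_variant_excludes_early_stages(self):
        rec = make_records(
            [{"id": str(i), "population": "A", "maturity": 6} for i in range(5)]
            + [{"id": str(i + 5), "population": "B", "maturity": 3}
               for i in range(5)]
        )
        out = mixing_proportions(rec, self.catch_for(rec), spawning_only=True)
        by_pop = out.set_index("population")["proportion"]
        assert by_pop["A"] == pytest.approx(0.5)  # 5 spawning of 10 caught
        assert "B" not in by_pop.index

    def test_lake_lv_share_rises_late_season(self):
        # mirrors the study's seasonal pattern: the lake population arrives
        # in May-June
        from otoshape.synthdata import default_config, generate_fish_records

        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            records, catch = generate_fish_records(
                default_config(seed=300 + seed, n_scale=0.5)
            )
            out = mixing_proportions(records, catch, by_habitat=True)
            lake = out[
                (out["habitat"] == "Landvikvannet") & (out["population"] == "LV")
            ].set_index("month")["proportion"]
            early = lake.reindex([3, 4]).mean()
            late = lake.reindex([5, 6]).mean()
            hits += late > early
        assert hits >= 0.95 * n_rep


class TestCompareMeristics:
    def make_three_pops(self, rng, means, n=200, sd=0.6):
        rows = []
        for pop, mu in means.items():
            for i in range(n):
                rows.append(
                    {
                        "id": f"{pop}{i}",
                        "population": pop,
                        "vs": int(np.clip(round(rng.normal(mu, sd)), 50, 62)),
                        "length": float(rng.normal(28, 2)),
                        "age": int(rng.integers(2, 9)),
                    }
                )
        return make_records(rows)

    def test_separated_vs_means_all_pairwise_significant(self):
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            rec = self.make_three_pops(
                rng, {"LV": 55.7, "CSS": 56.7, "NSS": 57.5}
            )
            out = compare_meristics(rec, "vs")
            ok = out["p"] < 0.001 and (out["pairwise"]["p_bonferroni"] < 0.001).all()
            hits += ok
        assert hits >= n_rep - 1

    def test_identical_groups_null_calibrated(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(500 + seed)
            rec = self.make_three_pops(rng, {"a": 56.0, "b": 56.0, "c": 56.0}, n=50)
            ps.append(compare_meristics(rec, "vs")["p"])
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_kruskal_matches_hand_ranking(self):
        rec = make_records(
            [{"id": str(i), "population": "a", "length": float(v)}
             for i, v in enumerate([1, 2, 3])]
            + [{"id": str(i + 3), "population": "b", "length": float(v)}
               for i, v in enumerate([4, 5, 6])]
        )
        out = compare_meristics(rec, "length", min_n=1)
        # hand computation: ranks 1..6, R1=6, R2=15
        h = 12 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 3 * 7
        assert out["stat"] == pytest.approx(h)

    def test_small_samples_excluded(self):
        rec = make_records(
            [{"id": str(i), "population": "a"} for i in range(10)]
            + [{"id": "tiny", "population": "b", "date": "2012-05-15"}]
            + [{"id": f"b{i}", "population": "b"} for i in range(6)]
        )
        with pytest.warns(UserWarning, match="N < 5"):
            out = compare_meristics(rec, "vs")
        assert set(out["groups"]) == {"a", "b"}

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="variable"):
            compare_meristics(make_records([{}] * 10), "weight")


class TestMaturityTrend:
    def test_strictly_increasing_rho_one(self):
        rows = []
        for m, stage in [(3, 3), (4, 4), (5, 5), (6, 6)]:
            rows += [
                {"id": f"{m}{i}", "date": f"2012-{m:02d}-15", "maturity": stage}
                for i in range(5)
            ]
        out = maturity_trend(make_records(rows))
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_null_rho_small(self, rng):
        rows = [
            {"id": str(i), "date": f"2012-{rng.integers(3, 7):02d}-15",
             "maturity": int(rng.integers(3, 9))}
            for i in range(300)
        ]
        out = maturity_trend(make_records(rows))
        assert abs(out["rho"].iloc[0]) < 0.15

    def test_constant_maturity_is_na(self):
        rows = [
            {"id": f"{m}{i}", "date": f"2012-{m:02d}-15", "maturity": 5}
            for m in (3, 4, 5) for i in range(3)
        ]
        out = maturity_trend(make_records(rows))
        assert np.isnan(out["rho"].iloc[0])

    def test_exact_permutation_p_matches_enumeration(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        rho, p = spearman_months(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(stats.spearmanr(x, y).statistic)
        count = 0
        for perm in permutations(ry):
            r = stats.pearsonr(rx, np.asarray(perm)).statistic
            count += abs(r) >= obs - 1e-12
        assert p == pytest.approx(count / 120)


class TestVsEnvironment:
    def env_table(self, temp_slope=1.5, sal_slope=0.0):
        rows = []
        for hab in ("Landvikvannet", "Inner Strandfjorden"):
            for m in (3, 4, 5, 6):
                for depth in (1.0, 3.0, 5.0, 10.0):
                    rows.append(
                        {
                            "habitat": hab, "month": m, "depth": depth,
                            "temperature": 5 + temp_slope * (m - 3) + 0.1 * depth,
                            "salinity": 20 + sal_slope * (m - 3),
                        }
                    )
        return pd.DataFrame(rows)

    def test_constant_vs_zero_slope(self):
        rows = [
            {"id": f"{m}{i}", "date": f"2012-{m:02d}-15", "vs": 56}
            for m in (3, 4, 5) for i in range(5)
        ]
        out = vs_environment_trend(make_records(rows), self.env_table())
        assert out["vs_trend"]["slope"].iloc[0] == 0.0

    def test_decreasing_vs_detected(self):
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            rows = []
            for m in (3, 4, 5, 6):
                for i in range(100):
                    rows.append(
                        {
                            "id": f"{m}-{i}", "date": f"2012-{m:02d}-15",
                            "vs": int(round(rng.normal(56.5 - 0.2 * (m - 3), 0.6))),
                        }
                    )
            out = vs_environment_trend(make_records(rows), self.env_table())
            t = out["vs_trend"].iloc[0]
            hits += (t["slope"] < 0) and (t["p"] < 0.05)
        assert hits >= 0.90 * n_rep

    def test_flat_salinity_not_significant_while_temp_is(self):
        rows = [
            {"id": f"{m}{i}", "date": f"2012-{m:02d}-15",
             "vs": 56 + (1 if m < 5 else 0)}
            for m in (3, 4, 5, 6) for i in range(10)
        ]
        out = vs_environment_trend(
            make_records(rows), self.env_table(temp_slope=1.5, sal_slope=0.0)
        )
        env = out["env_trend"].set_index(["habitat", "variable"])
        lake_t = env.loc[("Landvikvannet", "temperature")]
        lake_s = env.loc[("Landvikvannet", "salinity")]
        assert lake_t["p"] < 0.05
        assert np.isnan(lake_s["p"]) or lake_s["p"] > 0.05

    def test_spawn_depth_nearest_depth_used(self):
        out = vs_environment_trend(
            make_records([{"id": str(i), "date": "2012-03-15"} for i in range(5)]),
            self.env_table(),
        )
        env = out["env_trend"]
        lake = env[env["habitat"] == "Landvikvannet"]
        assert (lake["depth"] == 3.0).all()

    def test_missing_env_month_warns(self):
        rows = [
            {"id": f"{m}{i}", "date": f"2012-{m:02d}-15", "vs": 55 + m % 2}
            for m in (2, 3, 4) for i in range(4)
        ]
        env = self.env_table()  # covers months 3-6 only
        with pytest.warns(UserWarning, match="without environmental"):
            vs_environment_trend(make_records(rows), env)
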