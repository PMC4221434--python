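import subprocess
import sys
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from otoshape.ordination import (
    cap_fit,
    factorial_cap,
    pairwise_cap,
    permutation_test,
    seasonal_can_trend,
)


def two_group_data(rng, n=40, p=5, shift=0.0):
    X = rng.normal(size=(n, p))
    X[: n // 2, 0] += shift
    g = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    return X, g


class TestCapFit:
    def test_hand_computed_sums_of_squares(self):
        # groups {0,0,0} and {1,1,1}: between-group SS = 3*(0.5)^2 * 2 = 1.5,
        # residual 0, one canonical axis
        res = cap_fit(np.array([0.0, 0, 0, 1, 1, 1]), np.array(list("aaabbb")))
        assert res.total_inertia == pytest.approx(1.5, abs=1e-12)
        assert res.constrained_inertia == pytest.approx(1.5, abs=1e-12)
        assert res.residual_inertia == pytest.approx(0.0, abs=1e-12)
        assert res.scores.shape[1] == 1

    def test_pseudo_f_equals_anova_f(self, rng):
        x = np.concatenate([rng.normal(0, 1, 25), rng.normal(0.8, 1, 30)])
        g = np.array(["a"] * 25 + ["b"] * 30)
        res = cap_fit(x, g)
        f_classic = stats.f_oneway(x[:25], x[25:]).statistic
        assert abs(res.f_statistic - f_classic) < 1e-10

    def test_inertia_partition_conserved(self, rng):
        for _ in range(5):
            X, g = two_group_data(rng, shift=rng.uniform(0, 2))
            res = cap_fit(X, g)
            assert res.constrained_inertia + res.residual_inertia == pytest.approx(
                res.total_inertia, abs=1e-8
            )

    def test_null_constrained_fraction_small(self):
        fracs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 10))
            g = np.array(["a"] * 50 + ["b"] * 50)
            res = cap_fit(X, g)
            fracs.append(res.constrained_inertia / res.total_inertia)
        assert np.mean(fracs) < 0.05  # expectation ~ 1/(n-1) per df

    def test_axes_bounded_by_groups_minus_one(self, rng):
        X = rng.normal(size=(60, 8))
        g = np.repeat(["a", "b", "c"], 20)
        res = cap_fit(X, g)
        assert res.scores.shape[1] <= 2

    def test_scores_invariant_to_rotation_up_to_sign(self, rng):
        X, g = two_group_data(rng, shift=1.0)
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        s1 = cap_fit(X, g).scores.to_numpy()
        s2 = cap_fit(X @ Q, g).scores.to_numpy()
        for j in range(s1.shape[1]):
            assert np.allclose(np.abs(s1[:, j]), np.abs(s2[:, j]), atol=1e-8)

    def test_three_population_centroid_ordering(self):
        # monotone windowed shape effects order group centroids on CAN1
        from otoshape.outline import normalize_area, sample_radii
        from otoshape.synthdata import default_populations, generate_outline
        from otoshape.waveshape import descriptor_matrix, dwt_radii

        rng = np.random.default_rng(21)
        rows, labels = [], []
        for spec in default_populations():
            for _ in range(25):
                o = generate_outline(spec, 29.0, rng, n_points=1024, noise_sd=0.02)
                rows.append(dwt_radii(sample_radii(normalize_area(o), n=128)))
                labels.append(spec.name)
        X = descriptor_matrix(rows).iloc[:, :32]
        res = cap_fit(X, np.array(labels))
        cent = res.scores["CAN1"].groupby(np.array(labels)).mean()
        assert cent["LV"] < cent["CSS"] < cent["NSS"]

    def test_matches_vegan_rda(self, tmp_path):
        # independent oracle: vegan's rda/anova on the same data
        rng = np.random.default_rng(7)
        n = 30
        X = rng.normal(size=(n, 4))
        X[:15] += [0.8, 0, 0.3, 0]
        g = np.array(["a"] * 15 + ["b"] * 15)
        pd.DataFrame(X, columns=list("wxyz")).to_csv(tmp_path / "X.csv", index=False)
        pd.DataFrame({"g": g}).to_csv(tmp_path / "g.csv", index=False)
        script = (
            'suppressMessages(library(vegan));'
            f'X <- read.csv("{tmp_path}/X.csv");'
            f'g <- factor(read.csv("{tmp_path}/g.csv")$g);'
            'm <- rda(X ~ g);'
            'cat(sprintf("%.12f %.12f", m$CCA$tot.chi / m$tot.chi,'
            ' anova(m, permutations=99)$F[1]))'
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True,
                timeout=120, check=True,
            ).stdout.split()
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("Rscript/vegan unavailable")
        frac_vegan, f_vegan = map(float, out)
        res = cap_fit(X, g)
        assert res.constrained_inertia / res.total_inertia == pytest.approx(
            frac_vegan, abs=1e-9
        )
        assert res.f_statistic == pytest.approx(f_vegan, abs=1e-8)


class TestPermutationTest:
    def test_fully_separated_gives_minimum_p(self, rng):
        X, g = two_group_data(rng, n=30, shift=50.0)
        f, p = permutation_test(X, g, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=6)
        g = np.array(list("aaabbb"))

        def f_of(labels):
            a = x[labels == "a"]
            b = x[labels == "b"]
            ssb = 3 * (a.mean() - x.mean()) ** 2 + 3 * (b.mean() - x.mean()) ** 2
            ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            return (ssb / 1) / (ssw / 4)

        f_obs = f_of(g)
        count = total = 0
        for idx in combinations(range(6), 3):
            labels = np.array(["b"] * 6)
            labels[list(idx)] = "a"
            total += 1
            count += f_of(labels) >= f_obs - 1e-12
        p_exact = count / total
        _, p_mc = permutation_test(x, g, n_perm=20000, seed=5)
        assert abs(p_mc - p_exact) < 0.01

    def test_min_permutations_enforced(self, rng):
        X, g = two_group_data(rng)
        res = cap_fit(X, g)
        with pytest.raises(ValueError, match="99"):
            res.permutation_test(n_perm=10)

    def test_seed_reproducible(self, rng):
        X, g = two_group_data(rng, shift=0.5)
        assert permutation_test(X, g, n_perm=199, seed=42) == permutation_test(
            X, g, n_perm=199, seed=42
        )


class TestPairwise:
    def test_identical_groups_p_adjusted_one(self):
        x = np.array([1.0, 2, 3, 1, 2, 3])
        g = np.array(list("aaabbb"))
        out = pairwise_cap(x, g, n_perm=199, seed=0)
        assert out["p_bonferroni"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_arithmetic(self, rng):
        X = rng.normal(size=(80, 3))
        g = np.repeat(list("abcd"), 20)
        out = pairwise_cap(X, g, n_perm=99, seed=1)
        assert len(out) == 6
        assert np.allclose(
            out["p_bonferroni"], np.minimum(1.0, out["p"] * 6)
        )
        assert (out["p_bonferroni"] >= out["p"]).all()

    def test_same_distribution_subgroups_rarely_significant(self):
        # split one homogeneous population in two: the contrast should be
        # non-significant in the vast majority of replicates
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 4))
            g = np.array(["inside"] * 20 + ["outside"] * 20)
            out = pairwise_cap(X, g, n_perm=99, seed=seed)
            hits += out["p"].iloc[0] > 0.05
        assert hits >= 0.94 * n_rep - 2  # binomial slack on 60 draws

    def test_small_pair_skipped_with_warning(self, rng):
        X = rng.normal(size=(24, 2))
        g = np.array(["a"] * 20 + ["b"] * 3 + ["c"])  # c: one fish only
        with pytest.warns(UserWarning, match="skipped"):
            out = pairwise_cap(X, g, n_perm=99, seed=0)
        assert not any("c" in p for p in out["pair"])


class TestSeasonalTrend:
    def test_constant_scores_flat(self):
        out = seasonal_can_trend(np.ones(30), np.repeat([3, 4, 5], 10))
        assert out["slope"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_negative_trend(self):
        month = np.repeat([2, 3, 4, 5], 5).astype(float)
        out = seasonal_can_trend(-month, month)
        assert out["slope"].iloc[0] == pytest.approx(-1.0)
        assert out["p"].iloc[0] < 1e-10

    def test_single_month_is_na(self):
        out = seasonal_can_trend(np.arange(5.0), np.full(5, 4))
        assert np.isnan(out["slope"].iloc[0])

    def test_mixing_mechanism_recovers_negative_trend(self):
        # rising share of a low-scoring population in later months drags the
        # pooled mean score down
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            months = np.repeat([3, 4, 5, 6], 40)
            frac_lv = (months - 2) / 5.0
            is_lv = rng.uniform(size=len(months)) < frac_lv
            scores = np.where(is_lv, -1.0, 0.5) + rng.normal(0, 0.5, len(months))
            out = seasonal_can_trend(scores, months)
            hits += (out["slope"].iloc[0] < 0) and (out["p"].iloc[0] < 0.05)
        assert hits >= 0.95 * n_rep


class TestFactorialModel:
    def test_null_interaction_dropped_strong_interaction_kept(self, rng):
        n = 120
        pop = np.repeat(["a", "b"], n // 2)
        month = np.tile(np.repeat([3, 4, 5], n // 6), 2).astype(float)
        X_null = (
            (pop == "a")[:, None] * 1.0
            + month[:, None] * 0.3
            + rng.normal(size=(n, 3))
        )
        _, rep = factorial_cap(
            X_null, pd.DataFrame({"pop": pop, "month": month}), n_perm=199, seed=0
        )
        inter = rep[rep["term"] == "pop:month"].iloc[0]
        assert not inter["retained"]
        X_int = X_null + ((pop == "a") * month * 1.5)[:, None]
        _, rep2 = factorial_cap(
            X_int, pd.DataFrame({"pop": pop, "month": month}), n_perm=199, seed=0
        )
        assert rep2[rep2["term"] == "pop:month"]["retained"].iloc[0]
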