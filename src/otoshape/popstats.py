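"""Meristic, maturity and catch statistics for mixed-population samples.

Covers the survey-style comparisons that accompany the shape analysis:
catch-per-unit-effort standardisation of gillnet catches, CPUE-weighted
monthly mixing proportions of the populations, vertebral-count / length /
age comparisons with Bonferroni-corrected pairwise contrasts, maturity
seasonality (Spearman), and the vertebral-count-versus-environment trend
at the assumed spawning depth of each habitat.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "cpue_standardize",
    "mixing_proportions",
    "compare_meristics",
    "maturity_trend",
    "vs_environment_trend",
    "SPAWN_DEPTH_DEFAULTS",
]

# Assumed spawning depth (m) per habitat: shallow in the brackish lake
# (oxygen depletion below ~3 m), deeper in the fjord.
SPAWN_DEPTH_DEFAULTS = {
    "Landvikvannet": 3.0,
    "Inner Strandfjorden": 5.0,
    "Outer Strandfjorden": 5.0,
    "Bufjorden": 5.0,
}


def cpue_standardize(catch: pd.DataFrame) -> pd.DataFrame:
    """Add catch-per-gillnet (CPUE) to a catch table.

    Expects columns ``catch`` and ``nets``; rows with a positive catch must
    have at least one net.
    """
    t = catch.copy()
    bad = (t["nets"] <= 0) & (t["catch"] > 0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} rows have catch > 0 with no gillnets"
        )
    t["cpue"] = np.where(t["nets"] > 0, t["catch"] / t["nets"], 0.0)
    return t


def _month(dates: pd.Series) -> pd.Series:
    return pd.to_datetime(dates).dt.month


def mixing_proportions(
    records: pd.DataFrame,
    catch: pd.DataFrame,
    spawning_only: bool = False,
    by_habitat: bool = False,
) -> pd.DataFrame:
    """CPUE-weighted population composition by month (and habitat).

    Each sample's (date x location) analysed composition is scaled by that
    sample's catch per gillnet, then aggregated. Proportions per month sum
    to one; with ``spawning_only`` the numerator is restricted to spawning
    and spent fish (maturity stage >= 6) while the denominator keeps all
    stages, so proportions then quantify the spawning fraction per
    population.
    """
    catch = cpue_standardize(catch)
    keymap = catch.set_index(["date", "location"])["cpue"]
    sample_keys = records.groupby(["date", "location"]).size()
    orphans = [k for k in sample_keys.index if k not in keymap.index]
    if orphans:
        raise ValueError(f"records without a catch row for samples: {orphans}")

    rec = records.copy()
    rec["month"] = _month(rec["date"])
    rows = []
    for (date, loc), sample in rec.groupby(["date", "location"]):
        cpue = keymap[(date, loc)]
        n_tot = len(sample)
        numer = sample[sample["maturity"] >= 6] if spawning_only else sample
        for pop, n_pop in numer.groupby("population").size().items():
            rows.append(
                {
                    "month": sample["month"].iloc[0],
                    "habitat": loc,
                    "population": pop,
                    "weight": cpue * n_pop / n_tot,
                }
            )
        rows.append(
            {
                "month": sample["month"].iloc[0],
                "habitat": loc,
                "population": "_total",
                "weight": cpue,
            }
        )
    w = pd.DataFrame(rows)
    keys = ["month", "habitat"] if by_habitat else ["month"]
    agg = w.groupby(keys + ["population"], as_index=False)["weight"].sum()
    totals = (
        agg[agg["population"] == "_total"]
        .set_index(keys)["weight"]
        .rename("total")
    )
    out = agg[agg["population"] != "_total"].join(totals, on=keys)
    out["proportion"] = out["weight"] / out["total"]
    return out[keys + ["population", "proportion"]].reset_index(drop=True)


def _apply_min_n(records: pd.DataFrame, by: str, min_n: int) -> pd.DataFrame:
    """Drop samples (date x location x group) with fewer than `min_n` fish."""
    key = ["date", "location", by]
    counts = records.groupby(key).size().rename("_n")
    merged = records.join(counts, on=key)
    small = merged["_n"] < min_n
    if small.any():
        warnings.warn(
            f"excluded {int(small.sum())} fish from samples with N < {min_n}"
        )
    return merged.loc[~small].drop(columns="_n")


def compare_meristics(
    records: pd.DataFrame,
    variable: str,
    by: str = "population",
    min_n: int = 5,
) -> dict:
    """Compare a biological character among populations.

    Vertebral counts (approximately normal) get a one-way ANOVA with
    pairwise Welch t-tests; length and age (skewed) get a Kruskal-Wallis
    test with pairwise Mann-Whitney contrasts. All pairwise p-values are
    Bonferroni-corrected. A sex-difference ANCOVA (character ~ sex +
    length) is run first; pooling of sexes is justified when it is
    non-significant. Samples with fewer than ``min_n`` fish are excluded.
    """
    if variable not in {"vs", "length", "age"}:
        raise ValueError("variable must be one of 'vs', 'length', 'age'")
    rec = _apply_min_n(records, by, min_n)
    groups = sorted(rec[by].unique())
    data = {g: rec.loc[rec[by] == g, variable].to_numpy(dtype=float)
            for g in groups}
    dropped = [g for g in groups if len(data[g]) < min_n]
    if dropped:
        warnings.warn(f"groups below minimum n dropped: {dropped}")
        groups = [g for g in groups if g not in dropped]
    if len(groups) < 2:
        raise ValueError("need at least two groups after exclusions")

    # sex pre-test: does the character differ between sexes given length?
    p_sex = np.nan
    if "sex" in rec.columns and rec["sex"].nunique() > 1:
        d = pd.DataFrame(
            {"y": rec[variable], "sex": rec["sex"], "length": rec["length"]}
        )
        formula = "y ~ C(sex)" if variable == "length" else "y ~ C(sex) + length"
        tab = anova_lm(ols(formula, data=d).fit(), typ=2)
        p_sex = float(tab.loc["C(sex)", "PR(>F)"])

    samples = [data[g] for g in groups]
    if variable == "vs":
        stat, p = stats.f_oneway(*samples)
        test = "anova"
    else:
        stat, p = stats.kruskal(*samples)
        test = "kruskal"

    pairs = list(combinations(groups, 2))
    rows = []
    for a, b in pairs:
        if variable == "vs":
            s, pp = stats.ttest_ind(data[a], data[b], equal_var=False)
            ptest = "welch-t"
        else:
            s, pp = stats.mannwhitneyu(data[a], data[b], alternative="two-sided")
            ptest = "mann-whitney"
        rows.append({"pair": f"{a} vs {b}", "test": ptest,
                     "stat": float(s), "p": float(pp)})
    pw = pd.DataFrame(rows)
    if len(pw):
        pw["p_bonferroni"] = np.minimum(1.0, pw["p"] * len(pairs))
    return {
        "variable": variable,
        "test": test,
        "stat": float(stat),
        "p": float(p),
        "pairwise": pw,
        "p_sex": p_sex,
        "groups": groups,
    }


def spearman_months(x, y) -> tuple[float, float]:
    """Spearman rho with midrank ties; exact permutation p for n <= 9.

    For small samples the two-sided p is computed by enumerating all
    pairings of the ranks (the t-approximation is unreliable there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, p = stats.spearmanr(x, y)
    n = len(x)
    if n <= 9:
        from itertools import permutations

        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx_c = rx - rx.mean()
        obs = abs(rho)
        count = total = 0
        for perm in permutations(ry):
            r = np.asarray(perm) - ry.mean()
            rho_p = float(rx_c @ r) / np.sqrt((rx_c @ rx_c) * (r @ r))
            total += 1
            count += abs(rho_p) >= obs - 1e-12
        p = count / total
    return float(rho), float(p)


def maturity_trend(records: pd.DataFrame, by: str = "population") -> pd.DataFrame:
    """Spearman rank correlation of maturity stage with month, per group."""
    rec = records.copy()
    rec["month"] = _month(rec["date"])
    rows = []
    for g, sub in rec.groupby(by):
        if sub["month"].nunique() < 3:
            rows.append({by: g, "n": len(sub), "rho": np.nan, "p": np.nan})
            continue
        if sub["maturity"].nunique() < 2:
            rows.append({by: g, "n": len(sub), "rho": np.nan, "p": np.nan})
            continue
        rho, p = spearman_months(sub["month"], sub["maturity"])
        rows.append({by: g, "n": len(sub), "rho": rho, "p": p})
    return pd.DataFrame(rows)


def vs_environment_trend(
    records: pd.DataFrame,
    env: pd.DataFrame,
    spawn_depth: dict | None = None,
    by: str = "population",
) -> dict:
    """Seasonal vertebral-count trend alongside the spawning-depth environment.

    Per group: linear regression of vertebral count on month. Per habitat:
    linear regressions of temperature and salinity on month at that
    habitat's assumed spawning depth (nearest available depth in ``env``).
    ``env`` needs columns habitat, month, depth, temperature, salinity.
    Record months missing from the environment table are excluded with a
    warning from the environment pairing (not from the VS regression).
    """
    spawn_depth = dict(SPAWN_DEPTH_DEFAULTS, **(spawn_depth or {}))
    rec = records.copy()
    rec["month"] = _month(rec["date"])

    vs_rows = []
    for g, sub in rec.groupby(by):
        if sub["month"].nunique() < 2:
            vs_rows.append({by: g, "slope": np.nan, "p": np.nan, "n": len(sub)})
            continue
        if sub["vs"].nunique() < 2:
            vs_rows.append({by: g, "slope": 0.0, "p": 1.0, "n": len(sub)})
            continue
        lr = stats.linregress(sub["month"], sub["vs"])
        vs_rows.append({by: g, "slope": lr.slope, "p": lr.pvalue, "n": len(sub)})
    vs_trend = pd.DataFrame(vs_rows)

    missing = sorted(set(rec["month"]) - set(env["month"]))
    if missing:
        warnings.warn(f"months without environmental data excluded: {missing}")

    env_rows = []
    for hab, sub in env.groupby("habitat"):
        depth = spawn_depth.get(hab)
        if depth is None:
            continue
        # nearest measured depth to the assumed spawning depth
        d_near = sub.loc[(sub["depth"] - depth).abs().idxmin(), "depth"]
        at = sub[sub["depth"] == d_near]
        for var in ("temperature", "salinity"):
            if at["month"].nunique() < 3 or at[var].nunique() < 2:
                env_rows.append({"habitat": hab, "depth": d_near, "variable": var,
                                 "slope": np.nan, "p": np.nan})
                continue
            lr = stats.linregress(at["month"], at[var])
            env_rows.append({"habitat": hab, "depth": d_near, "variable": var,
                             "slope": lr.slope, "p": lr.pvalue})
    return {"vs_trend": vs_trend, "env_trend": pd.DataFrame(env_rows)}
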