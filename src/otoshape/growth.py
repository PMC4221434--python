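"""von Bertalanffy growth modelling of length-at-age data.

The growth curve L(t) = Linf * (1 - exp(-K * (t - t0))) is fitted to
individual length-at-age observations by nonlinear least squares with
multi-start initialisation. Several groups (populations) can be fitted
jointly with any subset of {Linf, K, t0} constrained equal across groups —
e.g. a common age intercept t0 with population-specific Linf and K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "vbgm_predict",
    "VonBertalanffy",
    "VonBertalanffyResults",
    "vbgm_fit",
    "compare_growth",
]

_PARAMS = ("Linf", "K", "t0")


def vbgm_predict(params, age) -> np.ndarray:
    """Length at age from von Bertalanffy parameters (Linf, K, t0)."""
    linf, k, t0 = (
        (params["Linf"], params["K"], params["t0"])
        if isinstance(params, (dict, pd.Series))
        else params
    )
    return linf * (1.0 - np.exp(-k * (np.asarray(age, dtype=float) - t0)))


class VonBertalanffy:
    """Growth model for one or several groups of fish.

    Parameters
    ----------
    length, age : array-like
        Individual lengths (cm) and ages (yr).
    groups : array-like, optional
        Group label per fish; omitted = single group.
    shared : iterable of {"Linf", "K", "t0"}
        Parameters constrained equal across groups in a joint fit.
    """

    def __init__(self, length, age, groups=None, shared=()):
        self.length = np.asarray(length, dtype=float)
        self.age = np.asarray(age, dtype=float)
        if np.any(self.length <= 0):
            raise ValueError("lengths must be positive")
        if groups is None:
            groups = np.zeros(len(self.length), dtype=int)
        self.groups = np.asarray(groups)
        if not (len(self.length) == len(self.age) == len(self.groups)):
            raise ValueError("length, age and groups must have equal length")
        self.levels = np.unique(self.groups)
        for lev in self.levels:
            m = self.groups == lev
            if len(np.unique(self.age[m])) < 4:
                raise ValueError(f"group {lev!r} has < 4 distinct ages")
        shared = tuple(shared)
        bad = set(shared) - set(_PARAMS)
        if bad:
            raise ValueError(f"unknown shared parameters: {sorted(bad)}")
        self.shared = shared
        self._index = self._build_index()

    def _build_index(self) -> dict:
        """Map (group, param) -> position in the packed parameter vector."""
        idx, pos = {}, 0
        for name in _PARAMS:
            if name in self.shared:
                for g in self.levels:
                    idx[(g, name)] = pos
                pos += 1
            else:
                for g in self.levels:
                    idx[(g, name)] = pos
                    pos += 1
        self._n_free = pos
        return idx

    def _unpack(self, theta: np.ndarray, g) -> tuple[float, float, float]:
        return tuple(theta[self._index[(g, name)]] for name in _PARAMS)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        r = np.empty(len(self.length))
        for g in self.levels:
            m = self.groups == g
            r[m] = self.length[m] - vbgm_predict(self._unpack(theta, g), self.age[m])
        return r

    def _starts(self):
        linf0 = {g: 1.1 * self.length[self.groups == g].max() for g in self.levels}
        for k0 in (0.1, 0.3, 0.6):
            for t00 in (-2.0, 0.0):
                theta = np.empty(self._n_free)
                for (g, name), pos in self._index.items():
                    theta[pos] = {"Linf": linf0[g], "K": k0, "t0": t00}[name]
                yield theta

    def fit(self) -> "VonBertalanffyResults":
        """Nonlinear least squares with multi-start initialisation."""
        lo = np.full(self._n_free, -np.inf)
        hi = np.full(self._n_free, np.inf)
        for (g, name), pos in self._index.items():
            if name in ("Linf", "K"):
                lo[pos] = 1e-8
        best = None
        for theta0 in self._starts():
            try:
                sol = least_squares(
                    self._residuals, theta0, bounds=(lo, hi), method="trf"
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError(
                "von Bertalanffy fit did not converge from any start"
            )
        theta = best.x
        # parameter covariance from the Jacobian at the optimum
        n, p = len(self.length), self._n_free
        rss = 2.0 * best.cost
        dof = max(n - p, 1)
        J = best.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / dof)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)

        rows, bse_rows = [], []
        for g in self.levels:
            m = self.groups == g
            pars = self._unpack(theta, g)
            resid = self.length[m] - vbgm_predict(pars, self.age[m])
            rows.append(
                {
                    "group": g,
                    "Linf": pars[0],
                    "K": pars[1],
                    "t0": pars[2],
                    "resid_sd": float(np.std(resid, ddof=1)),
                    "n": int(m.sum()),
                    "converged": True,
                }
            )
            bse_rows.append(
                {
                    "group": g,
                    **{
                        name: se[self._index[(g, name)]]
                        for name in _PARAMS
                    },
                }
            )
        params = pd.DataFrame(rows).set_index("group")
        bse = pd.DataFrame(bse_rows).set_index("group")
        return VonBertalanffyResults(self, params, bse, rss=rss)


@dataclass
class VonBertalanffyResults:
    """Fitted growth curves: per-group parameters and standard errors."""

    model: VonBertalanffy
    params: pd.DataFrame
    bse: pd.DataFrame
    rss: float

    def predict(self, age, group=None) -> np.ndarray:
        if group is None:
            group = self.params.index[0]
        row = self.params.loc[group]
        return vbgm_predict((row["Linf"], row["K"], row["t0"]), age)

    def summary(self) -> str:
        lines = [
            "von Bertalanffy growth model"
            + (f"  (shared: {', '.join(self.model.shared)})"
               if self.model.shared else ""),
            f"{'group':<10}{'Linf':>9}{'(se)':>8}{'K':>8}{'(se)':>8}"
            f"{'t0':>8}{'(se)':>8}{'sd':>7}{'n':>6}",
        ]
        for g, row in self.params.iterrows():
            se = self.bse.loc[g]
            lines.append(
                f"{str(g):<10}{row.Linf:>9.2f}{se.Linf:>8.3f}"
                f"{row.K:>8.3f}{se.K:>8.4f}{row.t0:>8.2f}{se.t0:>8.3f}"
                f"{row.resid_sd:>7.2f}{int(row.n):>6d}"
            )
        return "\n".join(lines)


def vbgm_fit(
    records: pd.DataFrame,
    by: str | None = None,
    shared=(),
    length_col: str = "length",
    age_col: str = "age",
) -> VonBertalanffyResults:
    """Fit growth curves from a fish-record table.

    ``by`` names the grouping column (e.g. "population"); ``shared`` lists
    parameters constrained equal across groups.
    """
    groups = records[by].to_numpy() if by else None
    return VonBertalanffy(
        records[length_col], records[age_col], groups=groups, shared=shared
    ).fit()


def compare_growth(
    records: pd.DataFrame,
    by: str = "population",
    length_col: str = "length",
    age_col: str = "age",
) -> dict:
    """ANOVA comparison of length-at-age between groups.

    Length is modelled on group and age (both as factors); pairwise group
    contrasts are refitted per pair and Bonferroni-corrected. Requires
    overlapping age ranges between the groups.
    """
    df = records[[by, length_col, age_col]].rename(
        columns={by: "grp", length_col: "length", age_col: "age"}
    )
    levels = sorted(df["grp"].unique())
    common = None
    for g in levels:
        ages = set(df.loc[df["grp"] == g, "age"])
        common = ages if common is None else common & ages
    if not common:
        warnings.warn("no overlapping ages between groups; comparison is NA")
        return {"anova": None, "pairwise": None}

    fit = ols("length ~ C(grp) + C(age)", data=df).fit()
    table = anova_lm(fit, typ=2)

    rows = []
    from itertools import combinations

    pairs = list(combinations(levels, 2))
    for a, b in pairs:
        sub = df[df["grp"].isin([a, b])]
        t = anova_lm(ols("length ~ C(grp) + C(age)", data=sub).fit(), typ=2)
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "F": t.loc["C(grp)", "F"],
                "p": t.loc["C(grp)", "PR(>F)"],
            }
        )
    pw = pd.DataFrame(rows)
    pw["p_bonferroni"] = np.minimum(1.0, pw["p"] * len(pairs))
    return {"anova": table, "pairwise": pw}
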