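"""Canonical analysis of principal coordinates (constrained ordination).

With Euclidean distances on the scaled wavelet coefficients, canonical
analysis of principal coordinates reduces to redundancy analysis: the
column-centred response matrix is projected onto the span of the group
(and covariate) design, the fitted part is eigen-decomposed into canonical
axes, and the variance explained by the constraints is tested with an
ANOVA-like permutation pseudo-F.

Inertia is reported as raw sums of squares, so the partition
``constrained + residual = total`` holds exactly and the pseudo-F

    F = (constrained / df_constraints) / (residual / df_residual)

equals the classical one-way ANOVA F in the one-variable, two-group case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CAP",
    "CAPResults",
    "cap_fit",
    "permutation_test",
    "pairwise_cap",
    "seasonal_can_trend",
    "factorial_cap",
]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _design_from_groups(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centred dummy design for the group factor (full rank, g-1 columns)."""
    levels, codes = np.unique(groups, return_inverse=True)
    g = len(levels)
    D = np.zeros((len(groups), g))
    D[np.arange(len(groups)), codes] = 1.0
    D = D[:, 1:]  # drop first level: reference coding
    return D - D.mean(axis=0), levels


def _orthonormal_basis(Z: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space, aliased directions dropped."""
    if Z.shape[1] == 0:
        return np.zeros((Z.shape[0], 0))
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    keep = s > 1e-9 * max(1.0, s[0])
    if keep.sum() < Z.shape[1]:
        warnings.warn(
            "rank-deficient design: aliased columns dropped", stacklevel=3
        )
    return U[:, keep]


class CAP:
    """Constrained ordination of a response matrix on a grouping factor.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Response matrix (e.g. scaled wavelet coefficients, possibly with
        vertebral count and length appended); columns are centred
        internally.
    groups : length-n sequence
        Population labels constraining the ordination.
    covariates : (n, q) array or DataFrame, optional
        Additional explanatory variables (e.g. month, age).
    condition : bool
        If False (default) covariates enter as additional constraints; if
        True they are partialled out of both the response and the group
        design before the constrained analysis.
    """

    def __init__(self, X, groups, covariates=None, condition: bool = False):
        self.X, self.var_names = _as_matrix(X)
        self.groups = np.asarray(groups)
        if len(self.groups) != len(self.X):
            raise ValueError("groups length does not match X rows")
        self.levels = np.unique(self.groups)
        if len(self.X) <= len(self.levels):
            raise ValueError("need more observations than groups")
        self.condition = condition
        if covariates is None:
            self.C = None
        else:
            self.C, _ = _as_matrix(covariates)
            if len(self.C) != len(self.X):
                raise ValueError("covariates length does not match X rows")

    def _build(self):
        Xc = self.X - self.X.mean(axis=0)
        D, _ = _design_from_groups(self.groups)
        if self.C is not None:
            Cc = self.C - self.C.mean(axis=0)
            if self.condition:
                Qc = _orthonormal_basis(Cc)
                Xc = Xc - Qc @ (Qc.T @ Xc)
                D = D - Qc @ (Qc.T @ D)
                Z = D
            else:
                Z = np.column_stack([D, Cc])
        else:
            Z = D
        return Xc, Z

    def fit(self) -> "CAPResults":
        Xc, Z = self._build()
        n = len(Xc)
        Q = _orthonormal_basis(Z)
        rank = Q.shape[1]
        B = Q.T @ Xc
        fitted = Q @ B
        total = float(np.sum(Xc**2))
        constrained = float(np.sum(B**2))
        residual = total - constrained
        # canonical axes from the fitted matrix
        U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
        pos = s > 1e-10 * (s[0] if s.size and s[0] > 0 else 1.0)
        s, Vt = s[pos], Vt[pos]
        n_axes = min(len(s), rank)
        s, Vt = s[:n_axes], Vt[:n_axes]
        scores = Xc @ Vt.T
        # axis sign convention: first (alphabetical) group mean >= 0
        first = self.groups == self.levels[0]
        for j in range(scores.shape[1]):
            if scores[first, j].mean() < 0:
                scores[:, j] *= -1.0
                Vt[j] *= -1.0
        df_resid = n - 1 - rank
        return CAPResults(
            model=self,
            scores=pd.DataFrame(
                scores, columns=[f"CAN{j + 1}" for j in range(n_axes)]
            ),
            eigenvalues=s**2,
            loadings=Vt.T,
            total_inertia=total,
            constrained_inertia=constrained,
            residual_inertia=residual,
            df_constraints=rank,
            df_residual=df_resid,
            _Q=Q,
            _Xc=Xc,
        )


@dataclass
class CAPResults:
    """Fitted constrained ordination.

    ``scores`` holds per-fish canonical axis scores (CAN1, CAN2, ...);
    the inertia partition satisfies constrained + residual = total.
    ``permutation_test`` populates ``pseudo_f``, ``p_value``.
    """

    model: CAP
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    loadings: np.ndarray
    total_inertia: float
    constrained_inertia: float
    residual_inertia: float
    df_constraints: int
    df_residual: int
    _Q: np.ndarray = field(repr=False, default=None)
    _Xc: np.ndarray = field(repr=False, default=None)
    pseudo_f: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    @property
    def f_statistic(self) -> float:
        """Observed pseudo-F for the constraints (inf if residual is zero)."""
        resid = self.residual_inertia
        if resid <= 1e-12 * max(self.total_inertia, 1e-300):
            return np.inf
        return (self.constrained_inertia / self.df_constraints) / (
            resid / self.df_residual
        )

    def permutation_test(self, n_perm: int = 5000, seed: int | None = None):
        """ANOVA-like permutation test of the constraints.

        Rows of the (centred, possibly residualised) response are permuted
        against the fixed design; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
        """
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        Q, Xc = self._Q, self._Xc
        total = self.total_inertia
        f_obs = self.f_statistic
        dfc, dfr = self.df_constraints, self.df_residual
        count = 0
        n = len(Xc)
        for _ in range(n_perm):
            idx = rng.permutation(n)
            B = Q.T @ Xc[idx]
            cons = float(np.sum(B**2))
            resid = total - cons
            if resid <= 1e-12 * max(total, 1e-300):
                f_perm = np.inf
            else:
                f_perm = (cons / dfc) / (resid / dfr)
            if f_perm >= f_obs * (1 - 1e-12) - 1e-12:
                count += 1
        self.pseudo_f = f_obs
        self.p_value = (1 + count) / (1 + n_perm)
        self.n_permutations = n_perm
        self.seed = seed
        return self.pseudo_f, self.p_value

    def group_centroids(self) -> pd.DataFrame:
        g = pd.Series(self.model.groups, name="group")
        return self.scores.groupby(g).mean()

    def summary(self) -> str:
        lines = [
            "Canonical Analysis of Principal Coordinates (Euclidean)",
            f"n obs: {len(self.scores)}   groups: {len(self.model.levels)}"
            f"   canonical axes: {self.scores.shape[1]}",
            f"Inertia  total: {self.total_inertia:.4f}"
            f"  constrained: {self.constrained_inertia:.4f}"
            f" ({100 * self.constrained_inertia / self.total_inertia:.1f}%)"
            f"  residual: {self.residual_inertia:.4f}",
            f"df constraints: {self.df_constraints}   df residual: {self.df_residual}",
            f"pseudo-F: {self.f_statistic:.4f}",
        ]
        if self.p_value is not None:
            lines.append(
                f"permutation p: {self.p_value:.4g} "
                f"({self.n_permutations} permutations)"
            )
        return "\n".join(lines)


def cap_fit(X, groups, covariates=None, condition: bool = False) -> CAPResults:
    """Fit a constrained ordination; see :class:`CAP`."""
    return CAP(X, groups, covariates=covariates, condition=condition).fit()


def permutation_test(
    X, groups, covariates=None, n_perm: int = 5000,
    seed: int | None = None, condition: bool = False,
) -> tuple[float, float]:
    """Pseudo-F and permutation p for the group constraints."""
    res = cap_fit(X, groups, covariates=covariates, condition=condition)
    return res.permutation_test(n_perm=n_perm, seed=seed)


def pairwise_cap(
    X, groups, pairs=None, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Posteriori pairwise contrasts with Bonferroni correction.

    Each pair is refitted and permutation-tested on its own subset;
    adjusted p = min(1, p * number of pairs). Pairs with fewer than three
    fish in either group are skipped with a warning.
    """
    X, _ = _as_matrix(X)
    groups = np.asarray(groups)
    if pairs is None:
        pairs = list(combinations(sorted(np.unique(groups)), 2))
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(pairs))
    for (a, b), sub_seed in zip(pairs, child_seeds):
        mask = (groups == a) | (groups == b)
        if min((groups == a).sum(), (groups == b).sum()) < 3:
            warnings.warn(f"pair ({a}, {b}) has < 3 fish per group; skipped")
            continue
        res = cap_fit(X[mask], groups[mask])
        f, p = res.permutation_test(n_perm=n_perm, seed=int(sub_seed))
        rows.append({"pair": f"{a} vs {b}", "n": int(mask.sum()),
                     "df": res.df_constraints, "F": f, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out


def seasonal_can_trend(scores, month, groups=None) -> pd.DataFrame:
    """Linear trend of canonical scores over the season, per group.

    Ordinary least-squares regression of CAN1 on calendar month within each
    group; with data from fewer than three distinct months the slope and p
    are reported as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    month = np.asarray(month, dtype=float)
    groups = np.asarray(["all"] * len(scores) if groups is None else groups)
    rows = []
    for g in np.unique(groups):
        m = groups == g
        if len(np.unique(month[m])) < 3:
            rows.append({"group": g, "n": int(m.sum()), "slope": np.nan,
                         "p": np.nan})
            continue
        if np.allclose(scores[m], scores[m][0]):
            rows.append({"group": g, "n": int(m.sum()), "slope": 0.0, "p": 1.0})
            continue
        lr = stats.linregress(month[m], scores[m])
        rows.append({"group": g, "n": int(m.sum()), "slope": lr.slope,
                     "p": lr.pvalue})
    return pd.DataFrame(rows)


# --- factorial model with permutation-based term dropping ----------------


def _term_design(values: np.ndarray) -> np.ndarray:
    """Centred design block for one factor (dummies) or numeric column."""
    if values.dtype.kind in "OUSb":
        D, _ = _design_from_groups(values)
        return D
    v = values.astype(float)
    return (v - v.mean())[:, None]


def _interaction(blocks: list[np.ndarray]) -> np.ndarray:
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, b).reshape(len(out), -1)
    return out - out.mean(axis=0)


def factorial_cap(
    X,
    factors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[CAPResults, pd.DataFrame]:
    """Full-factorial constrained ordination with backward term selection.

    Builds main effects plus all interactions of the supplied factors,
    permutation-tests each interaction marginally (extra inertia over the
    model without it), removes interactions with p > alpha from the highest
    order down, and refits. Returns the final fit (on the retained design)
    together with the per-term test table.
    """
    Xm, _ = _as_matrix(X)
    Xc = Xm - Xm.mean(axis=0)
    n = len(Xc)
    total = float(np.sum(Xc**2))
    names = list(factors.columns)
    blocks = {name: _term_design(factors[name].to_numpy()) for name in names}
    terms: dict[tuple[str, ...], np.ndarray] = {
        (name,): blocks[name] for name in names
    }
    for order in range(2, len(names) + 1):
        for combo in combinations(names, order):
            terms[combo] = _interaction([blocks[c] for c in combo])

    rng = np.random.default_rng(seed)

    def marginal_test(active: list[tuple[str, ...]], term):
        full = _orthonormal_basis(np.column_stack([terms[t] for t in active]))
        others = [t for t in active if t != term]
        red = (
            _orthonormal_basis(np.column_stack([terms[t] for t in others]))
            if others
            else np.zeros((n, 0))
        )
        df_t = full.shape[1] - red.shape[1]
        df_r = n - 1 - full.shape[1]
        if df_t <= 0 or df_r <= 0:
            return np.nan, np.nan

        def f_of(Xp):
            extra = float(np.sum((full.T @ Xp) ** 2)) - float(
                np.sum((red.T @ Xp) ** 2)
            )
            resid = total - float(np.sum((full.T @ Xp) ** 2))
            return (extra / df_t) / (resid / df_r)

        f_obs = f_of(Xc)
        count = sum(
            f_of(Xc[rng.permutation(n)]) >= f_obs - 1e-12 for _ in range(n_perm)
        )
        return f_obs, (1 + count) / (1 + n_perm)

    active = list(terms)
    report = []
    for order in sorted({len(t) for t in terms if len(t) > 1}, reverse=True):
        for term in [t for t in active if len(t) == order]:
            f, p = marginal_test(active, term)
            keep = bool(p <= alpha) if np.isfinite(p) else False
            report.append(
                {"term": ":".join(term), "order": order, "F": f, "p": p,
                 "retained": keep}
            )
            if not keep:
                active.remove(term)
    for term in [t for t in active if len(t) == 1]:
        f, p = marginal_test(active, term)
        report.append(
            {"term": ":".join(term), "order": 1, "F": f, "p": p, "retained": True}
        )

    # final fit: first factor as the constraining group, remaining retained
    # design columns as covariates
    main = names[0]
    covar_terms = [t for t in active if t != (main,)]
    covariates = (
        np.column_stack([terms[t] for t in covar_terms]) if covar_terms else None
    )
    res = cap_fit(Xm, factors[main].to_numpy(), covariates=covariates)
    res.permutation_test(n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
    return res, pd.DataFrame(report)
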