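"""Figure helpers: mean shapes, growth curves, mixing proportions, trends."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_mean_shapes",
    "plot_growth_curves",
    "plot_mixing_proportions",
    "plot_deviation_table",
]


def plot_mean_shapes(shapes: dict, ax=None):
    """Overlay per-group mean otolith outlines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, outline in shapes.items():
        pts = np.vstack([outline.points, outline.points[:1]])
        ax.plot(pts[:, 0], pts[:, 1], label=name)
    ax.set_aspect("equal")
    ax.legend()
    ax.set_title("Mean otolith shape by population")
    return ax


def plot_growth_curves(results, records: pd.DataFrame | None = None, ax=None):
    """Fitted von Bertalanffy curves with mean +- SE length-at-age overlay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ages = np.linspace(2, 12, 100)
    for g in results.params.index:
        (line,) = ax.plot(ages, results.predict(ages, g), label=str(g))
        if records is not None:
            sub = records[records["population"] == g]
            m = sub.groupby("age")["length"].agg(["mean", "sem"])
            ax.errorbar(
                m.index, m["mean"], yerr=m["sem"], fmt="o", ms=3,
                color=line.get_color(), alpha=0.7,
            )
    ax.set_xlabel("age (yr)")
    ax.set_ylabel("length (cm)")
    ax.legend()
    return ax


def plot_mixing_proportions(props: pd.DataFrame, habitat: str | None = None, ax=None):
    """Stacked monthly population proportions (CPUE-standardised)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    d = props
    if habitat is not None and "habitat" in d.columns:
        d = d[d["habitat"] == habitat]
        d = d.groupby(["month", "population"], as_index=False)["proportion"].sum()
    wide = d.pivot_table(
        index="month", columns="population", values="proportion", fill_value=0.0
    )
    wide.plot.bar(stacked=True, ax=ax)
    ax.set_ylabel("proportion (CPUE-weighted)")
    if habitat:
        ax.set_title(habitat)
    return ax


def plot_deviation_table(table: pd.DataFrame, tol: float = 0.01, ax=None):
    """Reconstruction deviation against retained wavelet depth."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.semilogy(table["keep_levels"], np.maximum(table["deviation"], 1e-17), "o-")
    ax.axhline(tol, ls="--", color="grey")
    ax.set_xlabel("detail levels kept")
    ax.set_ylabel("mean |relative deviation|")
    return ax
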