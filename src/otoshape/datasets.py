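"""Packaged survey tables from the 2012 Landvikvannet herring study.

Three small tables ship with the package:

* ``gillnet_catches_2012`` — per-sample gillnet catches (date, location,
  total catch, number of nets) over the February-June spawning season;
* ``analyzed_counts_2012`` — number of fish analysed per month for the
  three putative populations (NSS, CSS, LV), with the NSS subset caught
  inside the lake;
* ``karmoy_landings_2005_2012`` — commercial herring landings (tonnes live
  weight) off Karmøy by month and year.

The aggregators below reproduce the tables' marginal totals and are used
throughout the examples and the report generation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_gillnet_catches",
    "load_analyzed_counts",
    "load_commercial_landings",
    "catch_totals_by_location",
    "analyzed_totals_by_population",
    "landings_totals_by_year",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("otoshape.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_gillnet_catches() -> pd.DataFrame:
    """Gillnet catch table: date, location, catch, nets."""
    return _read("gillnet_catches_2012.csv")


def load_analyzed_counts() -> pd.DataFrame:
    """Fish analysed per month and population (NSS, CSS, LV)."""
    return _read("analyzed_counts_2012.csv")


def load_commercial_landings() -> pd.DataFrame:
    """Commercial landings off Karmøy (tonnes) by year and month."""
    return _read("karmoy_landings_2005_2012.csv")


def catch_totals_by_location(catch: pd.DataFrame | None = None) -> pd.Series:
    """Season totals of the gillnet catch per sampling location."""
    t = load_gillnet_catches() if catch is None else catch
    return t.groupby("location")["catch"].sum()


def analyzed_totals_by_population(counts: pd.DataFrame | None = None) -> pd.Series:
    """Season totals of fish analysed per population."""
    t = load_analyzed_counts() if counts is None else counts
    return t[["NSS", "CSS", "LV"]].sum()


def landings_totals_by_year(landings: pd.DataFrame | None = None) -> pd.Series:
    """Annual totals (tonnes) of the commercial landings."""
    t = load_commercial_landings() if landings is None else landings
    return t.groupby("year")["tonnes"].sum()
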