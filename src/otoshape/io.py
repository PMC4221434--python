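"""File formats and run manifests.

All tables are plain CSV (UTF-8, comma separated, "." decimal, ISO-8601
dates); outlines are two-column x,y CSV; configurations are JSON. A
:class:`RunManifest` records everything needed to reproduce a pipeline run
bit-identically: the configuration hash, the master seed, the package
version and every stage parameter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .outline import Outline
from .synthdata import PopulationSpec, SynthConfig

__all__ = [
    "read_records",
    "read_catch",
    "read_env",
    "write_outline",
    "read_outline",
    "config_to_json",
    "config_from_json",
    "RunManifest",
]

RECORD_COLUMNS = [
    "id", "date", "location", "population", "length", "weight",
    "sex", "maturity", "age", "vs",
]


def read_records(path) -> pd.DataFrame:
    """Read a fish-record CSV, validating schema and ranges."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table {path}: missing columns {missing}")
    bad = df[(df["maturity"] < 1) | (df["maturity"] > 8)]
    if len(bad):
        raise ValueError(
            f"record table {path}: maturity outside 1..8 in rows "
            f"{bad.index[:5].tolist()}"
        )
    bad = df[(df["vs"] < 50) | (df["vs"] > 62)]
    if len(bad):
        raise ValueError(
            f"record table {path}: vertebral count outside 50..62 in rows "
            f"{bad.index[:5].tolist()}"
        )
    return df


def read_catch(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("date", "location", "catch", "nets") if c not in df.columns]
    if missing:
        raise ValueError(f"catch table {path}: missing columns {missing}")
    return df


def read_env(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = ("habitat", "month", "depth", "temperature", "salinity")
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"environment table {path}: missing columns {missing}")
    if (df["depth"] < 0).any():
        raise ValueError(f"environment table {path}: negative depths")
    if ((df["salinity"] < 0) | (df["salinity"] > 40)).any():
        raise ValueError(f"environment table {path}: salinity outside [0, 40]")
    return df


def write_outline(o: Outline, path) -> None:
    pd.DataFrame(o.points, columns=["x", "y"]).to_csv(path, index=False)


def read_outline(path) -> Outline:
    df = pd.read_csv(path)
    return Outline(df[["x", "y"]].to_numpy(dtype=float))


# --- configuration ------------------------------------------------------


def config_to_json(cfg: SynthConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["populations"] = [dataclasses.asdict(p) for p in cfg.populations]
    return json.dumps(d, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, np.ndarray)):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _tuplify(x):
    if isinstance(x, list):
        return tuple(_tuplify(v) for v in x)
    return x


def config_from_json(text: str) -> SynthConfig:
    d = json.loads(text)
    pops = []
    for p in d.pop("populations"):
        p["vbgm"] = tuple(p["vbgm"])
        p["shape_effect"] = _tuplify(p.get("shape_effect", ()))
        pref = p.get("habitat_pref")
        if isinstance(pref, dict):
            p["habitat_pref"] = {int(k): tuple(v) for k, v in pref.items()}
        elif pref is not None:
            p["habitat_pref"] = tuple(pref)
        pops.append(PopulationSpec(**p))
    d["populations"] = tuple(pops)
    d["months"] = tuple(d.get("months", (2, 3, 4, 5, 6)))
    n = d.get("n_fish")
    if isinstance(n, dict):
        d["n_fish"] = {
            pop: {int(m): int(v) for m, v in months.items()}
            for pop, months in n.items()
        }
    return SynthConfig(**d)


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    seed: int
    config_hash: str
    version: str
    parameters: dict
    input_digests: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def create(cls, cfg: SynthConfig, parameters: dict, inputs: dict | None = None):
        from . import __version__

        cfg_json = config_to_json(cfg)
        digest = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
        input_digests = {}
        for name, path in (inputs or {}).items():
            h = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
            input_digests[name] = h
        return cls(
            seed=cfg.seed,
            config_hash=digest,
            version=__version__,
            parameters=parameters,
            input_digests=input_digests,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())
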