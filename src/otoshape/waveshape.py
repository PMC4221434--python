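"""Dyadic wavelet descriptors of otolith radii profiles.

A radii profile of length ``n = 2^k`` is decomposed to full dyadic depth
with an orthonormal discrete wavelet transform (periodic boundary), giving
exactly ``n`` coefficients: one scaling coefficient plus detail bands at
levels 1 (coarsest) .. k (finest). Shape is summarised by keeping the
coarse bands; the number of bands retained is chosen from the deviation of
the reconstructed outline from the original.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .outline import Outline, RadiiProfile

__all__ = [
    "WaveletDescriptor",
    "dwt_radii",
    "reconstruct",
    "select_levels",
    "mean_shape",
    "descriptor_matrix",
]

DEFAULT_WAVELET = "sym10"  # least-asymmetric orthogonal, order 10
_MODE = "periodization"


@dataclass(frozen=True)
class WaveletDescriptor:
    """Full multiresolution decomposition of one radii profile.

    ``coeffs`` follows the coarse-to-fine layout: ``[cA, cD_1, ..., cD_k]``
    where ``cA`` is the single scaling coefficient and ``cD_j`` has
    ``2^(j-1)`` entries. The total count equals the input length and the
    inverse transform of the full set reproduces the input exactly.
    """

    coeffs: tuple
    wavelet: str = DEFAULT_WAVELET
    centroid: tuple[float, float] = (0.0, 0.0)

    @property
    def n(self) -> int:
        return sum(len(c) for c in self.coeffs)

    @property
    def max_level(self) -> int:
        return len(self.coeffs) - 1

    def flatten(self) -> np.ndarray:
        return np.concatenate(self.coeffs)

    @classmethod
    def from_flat(
        cls, flat: np.ndarray, wavelet: str = DEFAULT_WAVELET,
        centroid: tuple[float, float] = (0.0, 0.0),
    ) -> "WaveletDescriptor":
        flat = np.asarray(flat, dtype=float)
        n = len(flat)
        k = int(np.log2(n))
        if 2**k != n:
            raise ValueError(f"flat length {n} is not a power of two")
        sizes = [1] + [2**j for j in range(k)]
        coeffs, pos = [], 0
        for s in sizes:
            coeffs.append(flat[pos : pos + s].copy())
            pos += s
        return cls(tuple(coeffs), wavelet=wavelet, centroid=centroid)

    @staticmethod
    def column_names(n: int) -> list[str]:
        """Level-tagged names for the flattened coefficient vector."""
        k = int(np.log2(n))
        names = ["s0"]
        for j in range(1, k + 1):
            names += [f"d{j}_{i}" for i in range(2 ** (j - 1))]
        return names


def dwt_radii(
    r: RadiiProfile | np.ndarray, wavelet: str = DEFAULT_WAVELET
) -> WaveletDescriptor:
    """Orthonormal full-depth DWT of a radii profile.

    Energy is preserved (Parseval) and the transform is exactly invertible
    for any orthogonal family under the periodic boundary rule.
    """
    if isinstance(r, RadiiProfile):
        x, centroid = r.radii, r.centroid
    else:
        x, centroid = np.asarray(r, dtype=float), (0.0, 0.0)
    n = len(x)
    k = int(np.log2(n))
    if 2**k != n or k < 4:
        raise ValueError(f"profile length must be 2^k with k >= 4, got {n}")
    with warnings.catch_warnings():
        # full-depth decomposition is intentional; pywt warns above its
        # boundary-effect heuristic but periodization stays orthonormal
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode=_MODE, level=k)
    return WaveletDescriptor(tuple(coeffs), wavelet=wavelet, centroid=centroid)


def reconstruct(w: WaveletDescriptor, keep_levels: int | None = None) -> np.ndarray:
    """Inverse transform keeping the coarsest ``keep_levels`` detail bands.

    ``keep_levels = 0`` gives the constant mean; ``keep_levels = k`` (or
    None) reproduces the input exactly.
    """
    k = w.max_level
    if keep_levels is None:
        keep_levels = k
    if not 0 <= keep_levels <= k:
        raise ValueError(f"keep_levels must be in [0, {k}]")
    coeffs = [w.coeffs[0].copy()]
    for j in range(1, k + 1):
        c = w.coeffs[j]
        coeffs.append(c.copy() if j <= keep_levels else np.zeros_like(c))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pywt.waverec(coeffs, w.wavelet, mode=_MODE)


def select_levels(
    r: RadiiProfile | np.ndarray,
    tol: float = 0.01,
    wavelet: str = DEFAULT_WAVELET,
    metric: str = "mad",
) -> tuple[int, pd.DataFrame]:
    """Smallest number of detail bands reproducing the profile within `tol`.

    The deviation of the reconstruction from the original is evaluated at
    each candidate depth; ``metric="mad"`` is the mean absolute relative
    deviation ``mean(|recon - r| / r)``, ``metric="rms"`` the relative RMS.
    Returns the chosen depth and the full deviation-vs-level table.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    x = r.radii if isinstance(r, RadiiProfile) else np.asarray(r, dtype=float)
    w = dwt_radii(r, wavelet=wavelet)
    k = w.max_level
    rows = []
    chosen = k
    for j in range(k + 1):
        recon = reconstruct(w, j)
        if metric == "mad":
            dev = float(np.mean(np.abs(recon - x) / x))
        elif metric == "rms":
            dev = float(np.sqrt(np.mean(((recon - x) / x) ** 2)))
        else:
            raise ValueError(f"unknown metric {metric!r}")
        rows.append({"keep_levels": j, "n_coeffs": 2**j, "deviation": dev})
    table = pd.DataFrame(rows)
    hits = table.index[table["deviation"] < tol]
    chosen = int(table.loc[hits[0], "keep_levels"]) if len(hits) else k
    return chosen, table


def mean_shape(
    groups: dict[str, list[WaveletDescriptor]],
    keep_levels: int | None = None,
) -> dict[str, Outline]:
    """Per-group mean otolith shape.

    Descriptors are averaged coefficient-wise (the transform is linear, so
    this equals the transform of the mean profile), reconstructed at the
    requested depth, and converted back to (x, y) outlines.
    """
    out = {}
    for name, descs in groups.items():
        if len(descs) == 0:
            raise ValueError(f"group {name!r} is empty")
        flat = np.mean([d.flatten() for d in descs], axis=0)
        w = WaveletDescriptor.from_flat(flat, wavelet=descs[0].wavelet)
        radii = reconstruct(w, keep_levels)
        out[name] = RadiiProfile(radii).to_outline()
    return out


def descriptor_matrix(descriptors: list[WaveletDescriptor]) -> pd.DataFrame:
    """Stack descriptors into a fish x coefficient DataFrame."""
    if not descriptors:
        raise ValueError("no descriptors")
    flat = np.vstack([d.flatten() for d in descriptors])
    return pd.DataFrame(flat, columns=WaveletDescriptor.column_names(flat.shape[1]))
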