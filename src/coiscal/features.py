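"""S / Z / V / V-complement feature vectors from a scalogram and its COI.

All four representations are flat row-major concatenations of scalogram
entries; they differ only in which (band, time) positions survive:

* S    — every position (length J*N);
* Z    — every position, out-of-COI values forced to zero (length J*N);
* V    — in-COI positions only (length sum of per-band Nf);
* Vbar — out-of-COI positions only (the complement of V).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .wavelet import COIBoundary, Scalogram

__all__ = [
    "Approach",
    "FeatureVector",
    "coi_mask",
    "s_vector",
    "z_vector",
    "v_vector",
    "vbar_vector",
    "extract",
    "APPROACHES",
]

Approach = Literal["S", "Z", "V", "Vbar"]
APPROACHES: tuple[Approach, ...] = ("S", "Z", "V", "Vbar")


@dataclass(frozen=True)
class FeatureVector:
    """Flat feature values plus their (band, time) provenance."""

    values: np.ndarray
    layout: np.ndarray  # (len, 2) int array of (band f, time n) pairs
    approach: Approach

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        layout = np.asarray(self.layout, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "layout", layout)
        if layout.shape != (values.size, 2):
            raise ValueError("layout must pair every value with (f, n)")

    def __len__(self) -> int:
        return int(self.values.size)


def coi_mask(coi: COIBoundary) -> np.ndarray:
    """Binary J x N matrix, 1 at in-COI positions."""
    return coi.mask()


def _grid_layout(J: int, N: int) -> np.ndarray:
    f, n = np.meshgrid(np.arange(J), np.arange(N), indexing="ij")
    return np.column_stack([f.ravel(), n.ravel()])


def _as_matrix(G: Scalogram | np.ndarray) -> np.ndarray:
    return G.G if isinstance(G, Scalogram) else np.asarray(G, dtype=float)


def _check_shapes(mat: np.ndarray, coi: COIBoundary) -> None:
    if mat.shape != (coi.J, coi.N):
        raise ValueError(
            f"scalogram shape {mat.shape} does not match COI ({coi.J}, {coi.N})"
        )


def s_vector(G: Scalogram | np.ndarray) -> FeatureVector:
    """Row-major concatenation of the whole scalogram (row 0 first)."""
    mat = _as_matrix(G)
    return FeatureVector(mat.ravel(), _grid_layout(*mat.shape), "S")


def z_vector(G: Scalogram | np.ndarray, coi: COIBoundary) -> FeatureVector:
    """S-vector with out-of-COI entries forced to exactly zero."""
    mat = _as_matrix(G)
    _check_shapes(mat, coi)
    masked = mat * coi.mask()
    return FeatureVector(masked.ravel(), _grid_layout(*mat.shape), "Z")


def v_vector(G: Scalogram | np.ndarray, coi: COIBoundary) -> FeatureVector:
    """Concatenation of each row's in-COI segment; length sum(Nf)."""
    mat = _as_matrix(G)
    _check_shapes(mat, coi)
    if coi.n_valid == 0:
        raise ValueError("COI is empty: no in-COI features exist")
    inside = coi.mask().astype(bool)
    layout = _grid_layout(*mat.shape)[inside.ravel()]
    return FeatureVector(mat[inside], layout, "V")


def vbar_vector(G: Scalogram | np.ndarray, coi: COIBoundary) -> FeatureVector:
    """Concatenation of out-of-COI values, row-major; the V complement."""
    mat = _as_matrix(G)
    _check_shapes(mat, coi)
    outside = ~coi.mask().astype(bool)
    if not outside.any():
        raise ValueError("COI covers the whole scalogram: complement is empty")
    layout = _grid_layout(*mat.shape)[outside.ravel()]
    return FeatureVector(mat[outside], layout, "Vbar")


def extract(
    G: Scalogram | np.ndarray, coi: COIBoundary, approach: Approach
) -> FeatureVector:
    """Dispatch to the requested representation."""
    if approach == "S":
        return s_vector(G)
    if approach == "Z":
        return z_vector(G, coi)
    if approach == "V":
        return v_vector(G, coi)
    if approach == "Vbar":
        return vbar_vector(G, coi)
    raise ValueError(f"unknown approach: {approach!r}")
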