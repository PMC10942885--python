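"""Singular-value-decomposition denoising of the predictor matrix.

The plots x bands table is viewed as a matrix M with m rows = spectral
predictors and n columns = biomass sample plots.  A thin SVD
M = U S V^T separates laterally coherent structure (large singular
values) from incoherent noise (small ones); truncating the expansion to
the retained components and re-synthesizing gives the denoised
predictor table.  Component retention combines a loading criterion
(maximum absolute entry of the unit-norm left singular vector at least
``threshold``, default 0.5) with a singular-value floor
(sigma_i / sigma_1 >= ``sv_floor``); the leading component is always
kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import SpectralTable


@dataclass
class SpectralMatrix:
    """m x n matrix: rows = spectral predictors, columns = sample plots."""

    M: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] < 1 or self.M.shape[1] < 1:
            raise ValueError("M must be a non-empty 2-D matrix")
        if self.M.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels must match matrix shape")

    @classmethod
    def from_table(cls, table: SpectralTable) -> "SpectralMatrix":
        return cls(
            table.bands.to_numpy().T,
            tuple(table.bands.columns),
            tuple(table.bands.index),
        )


@dataclass
class SVDResult:
    """Thin SVD of a :class:`SpectralMatrix`.

    ``loadings`` reports, per component, the absolute left-singular-vector
    entries rescaled so each component's maximum is 1 (a reporting
    convention; selection uses the raw unit-norm vectors).
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    loadings: pd.DataFrame
    row_labels: tuple[str, ...]
    col_labels: tuple


def decompose(matrix: SpectralMatrix) -> SVDResult:
    """Thin SVD with a deterministic sign convention.

    Each left singular vector is oriented so its largest-magnitude entry
    is non-negative (the matching right vector is flipped with it), which
    makes results reproducible across BLAS implementations.
    """
    M = matrix.M
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    V = Vt.T
    for c in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, c])))
        if U[i, c] < 0:
            U[:, c] = -U[:, c]
            V[:, c] = -V[:, c]
    absU = np.abs(U)
    scale = absU.max(axis=0)
    scale[scale == 0] = 1.0
    loadings = pd.DataFrame(
        absU / scale,
        index=list(matrix.row_labels),
        columns=[f"c{i + 1}" for i in range(U.shape[1])],
    )
    return SVDResult(U, S, V, loadings, matrix.row_labels, matrix.col_labels)


def select_components(
    result: SVDResult, threshold: float = 0.5, sv_floor: float = 0.01
) -> list[int]:
    """Indices (0-based) of retained components.

    A component is retained when the maximum absolute entry of its
    unit-norm left singular vector reaches ``threshold`` and its singular
    value is at least ``sv_floor`` of the leading one.  The leading
    component is always retained, so the set is never empty.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    s1 = result.S[0] if result.S[0] > 0 else 1.0
    keep = [
        c
        for c in range(len(result.S))
        if np.abs(result.U[:, c]).max() >= threshold
        and result.S[c] / s1 >= sv_floor
    ]
    if 0 not in keep:
        keep.insert(0, 0)
    return keep


def denoise(matrix: SpectralMatrix, components: list[int]) -> SpectralMatrix:
    """Re-synthesize M from the selected components only."""
    if not components:
        raise ValueError("component set must be non-empty")
    res = decompose(matrix)
    idx = np.asarray(sorted(set(components)), dtype=int)
    if idx.min() < 0 or idx.max() >= len(res.S):
        raise ValueError("component index out of range")
    M = (res.U[:, idx] * res.S[idx]) @ res.V[:, idx].T
    return SpectralMatrix(M, matrix.row_labels, matrix.col_labels)


def denoise_table(
    table: SpectralTable,
    threshold: float = 0.5,
    sv_floor: float = 0.01,
    center: bool = False,
) -> tuple[SpectralTable, SVDResult, list[int]]:
    """Denoise a plots x bands table; returns (table', svd, retained).

    ``center`` subtracts per-predictor means before the decomposition and
    adds them back afterwards (off by default; the method as used here
    factorizes the raw matrix).
    """
    mat = SpectralMatrix.from_table(table)
    offset = np.zeros((mat.M.shape[0], 1))
    if center:
        offset = mat.M.mean(axis=1, keepdims=True)
        mat = SpectralMatrix(mat.M - offset, mat.row_labels, mat.col_labels)
    res = decompose(mat)
    keep = select_components(res, threshold=threshold, sv_floor=sv_floor)
    out = denoise(mat, keep)
    bands = pd.DataFrame(
        (out.M + offset).T,
        index=list(table.bands.index),
        columns=list(table.bands.columns),
    )
    bands.index.name = table.bands.index.name
    return SpectralTable(bands, table.agb), res, keep


def diagnostics_frame(res: SVDResult, retained: list[int]) -> pd.DataFrame:
    """Singular values, share of the leading one, and retention flags."""
    s1 = res.S[0] if res.S[0] > 0 else 1.0
    return pd.DataFrame(
        {
            "component": [f"c{i + 1}" for i in range(len(res.S))],
            "singular_value": res.S,
            "share_of_leading": res.S / s1,
            "max_abs_loading": np.abs(res.U).max(axis=0),
            "retained": [i in retained for i in range(len(res.S))],
        }
    )
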