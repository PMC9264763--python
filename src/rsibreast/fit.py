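"""Voxel-wise fixed-spectrum model fitting and derived maps.

The signal model is a linear combination of three exponential decays with
fixed diffusivities,

    S(b) = C1 + C2 exp(-b * 1.5e-3) + C3 exp(-b * 10.8e-3),

fitted per voxel by non-negative least squares (Lawson--Hanson active set,
exact and deterministic) over the shell-averaged signal-versus-b curve.
Derived outputs are the product map C1*C2, its square root (which puts the
product on the same scale as the individual compartment maps), and the
conventional mono-exponential ADC computed from shells with b <= 1500 s/mm^2
on data *without* noise correction.  Voxels with non-positive signal on any
shell used for ADC, or with a negative fitted decay rate, are marked
invalid and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .dwi import ShellAveragedDwi
from .protocol import BREAST_SPECTRUM, DiffusionSpectrum

__all__ = [
    "CompartmentMaps",
    "DerivedMaps",
    "build_design_matrix",
    "fit_nnls_voxel",
    "fit_volume",
    "derive_product_maps",
    "compute_adc_map",
]


@dataclass
class CompartmentMaps:
    """Voxel-wise non-negative signal contributions C1, C2, C3 plus residual.

    Voxels outside the fitted mask hold NaN.
    """

    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    residual: np.ndarray
    b_values: np.ndarray
    mask: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.c1.shape

    def stack(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of the three compartment maps."""
        return np.stack([self.c1, self.c2, self.c3], axis=-1)


@dataclass
class DerivedMaps:
    """Combination maps (C1*C2, sqrt(C1*C2)) and/or ADC with validity mask."""

    product: np.ndarray | None = None
    root_product: np.ndarray | None = None
    adc: np.ndarray | None = None
    adc_valid: np.ndarray | None = None


def build_design_matrix(
    b_values: np.ndarray, spectrum: DiffusionSpectrum = BREAST_SPECTRUM
) -> np.ndarray:
    """Design matrix with entry (j, i) = exp(-b_j * D_i).

    The D1 = 0 column is all ones; with >= 3 distinct b-values and distinct
    diffusivities the matrix has full column rank.
    """
    b = np.asarray(b_values, dtype=float).ravel()
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if np.unique(b).size != b.size:
        raise ValueError("b-values must be distinct")
    D = np.asarray(spectrum.diffusivities, dtype=float)
    return np.exp(-np.outer(b, D))


def fit_nnls_voxel(signal: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares fit of one voxel's signal-versus-b curve.

    Returns ``(C, residual_norm)`` where ``C`` minimizes
    ``||design @ C - signal||_2`` subject to ``C >= 0``.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size != design.shape[0]:
        raise ValueError("signal length does not match design matrix rows")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    coeffs, rnorm = nnls(design, signal)
    return coeffs, float(rnorm)


def fit_volume(
    avg: ShellAveragedDwi,
    spectrum: DiffusionSpectrum = BREAST_SPECTRUM,
    mask: np.ndarray | None = None,
) -> CompartmentMaps:
    """Fit the fixed-spectrum model in every voxel (or inside ``mask``).

    Requires at least three shells (the three-component spectrum is
    under-determined otherwise).  Voxels outside the mask are set to NaN.
    """
    if avg.n_shells < 3:
        raise ValueError(
            f"need >= 3 shells for the 3-component spectrum, got {avg.n_shells}"
        )
    design = build_design_matrix(avg.bvals, spectrum)
    grid = avg.grid_shape
    if mask is None:
        mask_arr = np.ones(grid, dtype=bool)
    else:
        mask_arr = np.asarray(mask, dtype=bool)
        if mask_arr.shape != grid:
            raise ValueError("mask grid does not match data grid")

    flat = avg.data.reshape(-1, avg.n_shells)
    sel = mask_arr.ravel()
    out = np.full((flat.shape[0], 3), np.nan)
    res = np.full(flat.shape[0], np.nan)
    idx = np.nonzero(sel)[0]
    for k in idx:
        y = flat[k]
        if not y.any():  # background voxel: exact zero signal
            out[k] = 0.0
            res[k] = 0.0
            continue
        out[k], res[k] = fit_nnls_voxel(y, design)
    maps = out.reshape(grid + (3,))
    return CompartmentMaps(
        c1=maps[..., 0],
        c2=maps[..., 1],
        c3=maps[..., 2],
        residual=res.reshape(grid),
        b_values=avg.bvals.copy(),
        mask=mask_arr,
    )


def derive_product_maps(maps: CompartmentMaps) -> DerivedMaps:
    """Voxel-wise C1*C2 and sqrt(C1*C2) combination maps."""
    product = maps.c1 * maps.c2
    return DerivedMaps(product=product, root_product=np.sqrt(product))


def compute_adc_map(
    avg_raw: ShellAveragedDwi,
    b_max: float = 1500.0,
    mode: str = "ols",
) -> DerivedMaps:
    """Mono-exponential ADC from shells with b <= ``b_max``.

    ``mode='ols'`` fits the ordinary least-squares slope of -ln(S) versus b
    over all usable shells; ``mode='two_point'`` uses only b = 0 and the
    largest usable b.  A voxel is invalid when any used signal is
    non-positive or the fitted ADC is negative; invalid voxels hold NaN.
    """
    if mode not in ("ols", "two_point"):
        raise ValueError(f"unknown ADC mode {mode!r}")
    use = avg_raw.bvals <= b_max
    b = avg_raw.bvals[use]
    if b.size < 2 or 0.0 not in b:
        raise ValueError(
            f"need >= 2 shells with b <= {b_max} including b = 0 for ADC"
        )
    if mode == "two_point":
        keep = np.isin(b, [0.0, b.max()])
        b = b[keep]
        data = avg_raw.data[..., use][..., keep]
    else:
        data = avg_raw.data[..., use]

    valid = np.all(data > 0, axis=-1)
    logs = np.full(data.shape, np.nan)
    np.log(data, out=logs, where=data > 0)

    bc = b - b.mean()
    denom = float((bc**2).sum())
    slope = np.einsum("...k,k->...", np.nan_to_num(logs), bc) / denom
    adc = -slope
    valid &= adc >= 0
    adc = np.where(valid, adc, np.nan)
    return DerivedMaps(adc=adc, adc_valid=valid)
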