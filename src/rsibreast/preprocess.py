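"""Preprocessing chain for multi-shell breast DWI.

The chain runs, in order: noise-floor estimation -> noise-floor
subtraction -> per-shell direction averaging -> normalization by the 98th
percentile of the b = 0 volume.  Distortion and eddy-current correction are
exposed as identity pass-through hooks so that users of real scanner data
can substitute external tools; the synthetic phantoms contain neither
artifact.

Noise-floor estimation follows the histogram convention for magnitude MRI:
the background (air) voxels form the low-intensity mode of the intensity
histogram, and the floor is their mean signal.  By default the histogram is
built from the mean b = 0 volume with 256 bins and the background is every
voxel below the first local minimum after the low-intensity mode.
"""

from __future__ import annotations

import numpy as np

from .dwi import DwiSeries, ShellAveragedDwi

__all__ = [
    "PreprocessError",
    "estimate_noise_floor",
    "subtract_noise_floor",
    "average_shells",
    "normalize_to_b0_percentile",
    "correct_distortion",
    "correct_eddy",
    "preprocess",
]


class PreprocessError(RuntimeError):
    """Raised when a preprocessing stage cannot be applied."""


def _mean_b0(dwi: DwiSeries) -> np.ndarray:
    idx = np.nonzero(dwi.bvals == 0.0)[0]
    if idx.size == 0:
        raise PreprocessError("no b = 0 acquisitions present")
    return dwi.data[..., idx].mean(axis=3)


def estimate_noise_floor(
    dwi: DwiSeries,
    background_mask: np.ndarray | None = None,
    bins: int = 256,
) -> float:
    """Estimate the magnitude-MRI noise floor as the mean background signal.

    Background voxels are either the supplied ``background_mask`` or, by
    default, the voxels of the mean b = 0 volume lying below the first local
    minimum after the low-intensity mode of its ``bins``-bin histogram.
    """
    vol = _mean_b0(dwi)
    if background_mask is not None:
        background_mask = np.asarray(background_mask, dtype=bool)
        if background_mask.shape != vol.shape:
            raise PreprocessError("background mask grid does not match DWI grid")
        if not background_mask.any():
            raise PreprocessError("background mask covers zero voxels")
        return float(vol[background_mask].mean())

    counts, edges = np.histogram(vol.ravel(), bins=bins)
    mode = int(np.argmax(counts))
    cut = None
    for i in range(mode + 1, bins - 1):
        if counts[i] < counts[i - 1] and counts[i] <= counts[i + 1]:
            cut = edges[i]
            break
    if cut is None:
        raise PreprocessError(
            "no background found: histogram has no local minimum after the "
            "low-intensity mode"
        )
    background = vol < cut
    if not background.any():
        raise PreprocessError("no background found below the histogram minimum")
    return float(vol[background].mean())


def subtract_noise_floor(dwi: DwiSeries, floor: float) -> DwiSeries:
    """Subtract the noise floor from every voxel, clipping at zero."""
    if floor < 0:
        raise ValueError("noise floor must be non-negative")
    return DwiSeries(
        np.clip(dwi.data - floor, 0.0, None), dwi.bvals.copy(), dwi.voxel_size_mm
    )


def average_shells(dwi: DwiSeries) -> ShellAveragedDwi:
    """Average all acquisitions (diffusion directions) within each shell.

    Output shells are sorted ascending by b-value.
    """
    bvals = np.unique(dwi.bvals)
    out = np.empty(dwi.grid_shape + (bvals.size,))
    for j, b in enumerate(bvals):
        out[..., j] = dwi.data[..., dwi.bvals == b].mean(axis=3)
    return ShellAveragedDwi(out, bvals, dwi.voxel_size_mm, norm_factor=None)


def normalize_to_b0_percentile(avg: ShellAveragedDwi, q: float = 98.0) -> ShellAveragedDwi:
    """Divide every shell volume by the q-th percentile of the b = 0 volume.

    The percentile uses linear interpolation between order statistics and is
    computed over the full b = 0 volume (no mask).  After normalization the
    q-th percentile of the b = 0 volume equals 1, which makes the operation
    idempotent.
    """
    scale = float(np.percentile(avg.b0_volume(), q))
    if scale <= 0:
        raise PreprocessError(
            f"cannot normalize: {q}th percentile of the b = 0 volume is {scale}"
        )
    prior = avg.norm_factor or 1.0
    return ShellAveragedDwi(
        avg.data / scale, avg.bvals.copy(), avg.voxel_size_mm, norm_factor=prior * scale
    )


def correct_distortion(dwi: DwiSeries) -> DwiSeries:
    """Identity hook for reverse-polarity-gradient distortion correction."""
    return dwi


def correct_eddy(dwi: DwiSeries) -> DwiSeries:
    """Identity hook for eddy-current correction."""
    return dwi


def preprocess(
    dwi: DwiSeries,
    q: float = 98.0,
    bins: int = 256,
    background_mask: np.ndarray | None = None,
) -> tuple[ShellAveragedDwi, dict]:
    """Run the full preprocessing chain in its fixed order.

    Returns the normalized shell-averaged series and a report recording the
    estimated noise floor and the normalization factor.
    """
    dwi = correct_distortion(dwi)
    floor = estimate_noise_floor(dwi, background_mask=background_mask, bins=bins)
    corrected = subtract_noise_floor(dwi, floor)
    corrected = correct_eddy(corrected)
    avg = average_shells(corrected)
    norm = normalize_to_b0_percentile(avg, q=q)
    report = {
        "noise_floor": floor,
        "norm_factor": norm.norm_factor,
        "percentile_q": q,
        "n_shells": int(norm.n_shells),
        "stage_order": [
            "distortion_hook",
            "noise_floor_subtraction",
            "eddy_hook",
            "shell_averaging",
            "b0_percentile_normalization",
        ],
    }
    return norm, report
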