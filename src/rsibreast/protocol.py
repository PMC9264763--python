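"""Acquisition protocol and fixed diffusion spectrum.

The breast RSI model decomposes the diffusion-weighted signal into three
compartments with *fixed* apparent diffusivities:

* D1 = 0 mm^2/s        -- restricted diffusion (intracellular-like water),
* D2 = 1.5e-3 mm^2/s   -- hindered diffusion (extracellular-like water),
* D3 = 10.8e-3 mm^2/s  -- pseudo-diffusion (flow-like water).

Because the diffusivities are fixed, only the non-negative signal
contributions C1, C2, C3 are estimated per voxel, which makes the fit a
linear non-negative least-squares problem and the maps comparable across
voxels and patients.

The default multi-shell protocol uses b = 0, 500, 1500 and 4000 s/mm^2 with
2, 6, 6 and 15 acquisitions respectively (the two b=0 volumes correspond to
opposite phase-encode polarities acquired for distortion correction, which
is out of scope here and treated as two ordinary acquisitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionSpectrum",
    "AcquisitionProtocol",
    "BREAST_SPECTRUM",
    "BREAST_PROTOCOL",
]


@dataclass(frozen=True)
class DiffusionSpectrum:
    """Ordered fixed diffusivities (D1, D2, D3) in mm^2/s."""

    diffusivities: tuple[float, float, float] = (0.0, 1.5e-3, 10.8e-3)

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.diffusivities)
        if len(d) != 3:
            raise ValueError("the breast model uses exactly three diffusivities")
        if any(x < 0 for x in d):
            raise ValueError("diffusivities must be non-negative")
        if not (d[0] < d[1] < d[2]):
            raise ValueError("diffusivities must be strictly increasing")
        object.__setattr__(self, "diffusivities", d)

    @property
    def n_components(self) -> int:
        return len(self.diffusivities)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-shell DWI protocol: per-shell b-values and acquisition counts.

    ``shells`` is a sequence of ``(b_value_s_per_mm2, n_acquisitions)``
    pairs.  Timing/geometry metadata (TE, TR, gradient pulse duration delta,
    gradient interval Delta, voxel size) is carried along for provenance but
    does not enter the fixed-spectrum signal model.
    """

    shells: tuple[tuple[float, int], ...] = (
        (0.0, 2),
        (500.0, 6),
        (1500.0, 6),
        (4000.0, 15),
    )
    te_ms: float = 82.0
    tr_ms: float = 9000.0
    delta_ms: float = 29.34
    Delta_ms: float = 37.67
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 5.0)

    def __post_init__(self) -> None:
        shells = tuple((float(b), int(n)) for b, n in self.shells)
        if not shells:
            raise ValueError("protocol must define at least one shell")
        bvals = [b for b, _ in shells]
        if any(b < 0 for b in bvals):
            raise ValueError("b-values must be non-negative")
        if len(set(bvals)) != len(bvals):
            raise ValueError("duplicate b-value shells are not allowed")
        if 0.0 not in bvals:
            raise ValueError("a b = 0 shell is required")
        if any(n < 1 for _, n in shells):
            raise ValueError("every shell needs at least one acquisition")
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError("voxel dimensions must be three positive lengths")
        object.__setattr__(self, "shells", tuple(sorted(shells)))
        object.__setattr__(self, "voxel_size_mm", vox)

    @property
    def shell_bvals(self) -> np.ndarray:
        """Distinct b-values, ascending (s/mm^2)."""
        return np.array([b for b, _ in self.shells], dtype=float)

    @property
    def acquisition_bvals(self) -> np.ndarray:
        """One b-value label per acquisition volume, shell order."""
        out: list[float] = []
        for b, n in self.shells:
            out.extend([b] * n)
        return np.array(out, dtype=float)

    @property
    def n_acquisitions(self) -> int:
        return int(sum(n for _, n in self.shells))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


#: Fixed three-compartment breast spectrum (restricted/hindered/pseudo-diffusion).
BREAST_SPECTRUM = DiffusionSpectrum()

#: Default multi-shell breast protocol (29 acquisition volumes).
BREAST_PROTOCOL = AcquisitionProtocol()
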