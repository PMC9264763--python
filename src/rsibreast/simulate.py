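"""Synthetic multi-shell breast DWI phantoms with known compartment maps.

The generator emulates a paired cohort in which every patient carries one
malignant lesion, at least one biopsy-proven benign lesion, and healthy
fibroglandular background, all on the same voxel grid.  Ground-truth
compartment fractions (C1, C2, C3) are drawn per tissue from log-normal
distributions parameterized by a target median and interquartile range
(IQR), which guarantees non-negativity and reproduces the reported
median/IQR tissue contrast (malignant lesions high C1; benign lesions and
healthy tissue low C1).

Randomness is hierarchical: for each patient and tissue a patient-level
median is drawn first (between-patient variability carries most of the
configured IQR), then voxel values scatter log-normally around it
(within-lesion heterogeneity, a configurable fraction of the total spread).
Magnitude noise is Rician, sqrt((s + g1)^2 + g2^2) with iid zero-mean
Gaussians g1, g2, which naturally produces the nonzero background noise
floor of magnitude MRI.  All randomness flows from one master seed through
``numpy.random.SeedSequence`` children (one per patient).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np

from .dwi import DwiSeries, save_mask
from .protocol import BREAST_PROTOCOL, BREAST_SPECTRUM, AcquisitionProtocol, DiffusionSpectrum

__all__ = [
    "TissueParams",
    "PhantomConfig",
    "PatientPhantom",
    "MALIGNANT",
    "BENIGN",
    "HEALTHY",
    "sample_compartment_fractions",
    "sample_patient_medians",
    "synthesize_voxel_signal",
    "add_rician_noise",
    "generate_patient_phantom",
    "generate_cohort",
    "write_phantom",
]

# 75th percentile of the standard normal; converts an IQR ratio into the
# log-normal sigma: IQR/median = 2*sinh(z75*sigma).
_Z75 = 0.6744897501960817


class PhantomConfigError(ValueError):
    """Phantom geometry cannot be realized on the requested grid."""


@dataclass(frozen=True)
class TissueParams:
    """Target distribution of compartment fractions for one tissue type.

    ``medians`` and ``iqrs`` are the across-cohort median and IQR of
    (C1, C2, C3) in normalized signal units.  ``axis_ranges_mm`` bounds the
    full axis lengths of the ellipsoidal lesion (``None`` for the healthy
    background, which fills the breast).  ``within_lesion_fraction`` is the
    share of the total log-scale spread assigned to voxel-level
    heterogeneity inside a lesion.
    """

    label: str
    medians: tuple[float, float, float]
    iqrs: tuple[float, float, float]
    axis_ranges_mm: tuple[tuple[float, float], ...] | None = None
    within_lesion_fraction: float = 0.3

    def __post_init__(self) -> None:
        med = tuple(float(m) for m in self.medians)
        iqr = tuple(float(q) for q in self.iqrs)
        if any(m < 0 for m in med):
            raise ValueError("target medians must be non-negative")
        if any(q < 0 for q in iqr):
            raise ValueError("target dispersions (IQRs) must be non-negative")
        if any(m == 0 and q > 0 for m, q in zip(med, iqr)):
            raise ValueError("zero median with positive IQR is not representable")
        if not 0.0 <= self.within_lesion_fraction < 1.0:
            raise ValueError("within_lesion_fraction must be in [0, 1)")
        object.__setattr__(self, "medians", med)
        object.__setattr__(self, "iqrs", iqr)

    def log_sigmas(self) -> np.ndarray:
        """Total log-normal sigma per component (0 where median is 0)."""
        out = np.zeros(3)
        for i, (m, q) in enumerate(zip(self.medians, self.iqrs)):
            if m > 0 and q > 0:
                out[i] = np.arcsinh(q / (2.0 * m)) / _Z75
        return out


#: Malignant-lesion targets (median/IQR of C1, C2, C3) and size range.
MALIGNANT = TissueParams(
    "malignant",
    medians=(0.32, 2.6, 0.13),
    iqrs=(0.18, 1.7, 0.40),
    axis_ranges_mm=((21.0, 50.0), (19.0, 40.0), (10.0, 25.0)),
)

#: Benign-lesion targets; benign lesions are small and thin.
BENIGN = TissueParams(
    "benign",
    medians=(0.05, 1.6, 0.34),
    iqrs=(0.12, 1.5, 0.70),
    axis_ranges_mm=((8.0, 35.0), (5.0, 14.0), (5.0, 14.0)),
)

#: Healthy fibroglandular/fat background targets.
HEALTHY = TissueParams(
    "healthy",
    medians=(0.08, 0.90, 0.34),
    iqrs=(0.13, 0.73, 0.43),
)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, protocol and noise configuration of one phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    protocol: AcquisitionProtocol = BREAST_PROTOCOL
    spectrum: DiffusionSpectrum = BREAST_SPECTRUM
    malignant: TissueParams = MALIGNANT
    benign: TissueParams = BENIGN
    healthy: TissueParams = HEALTHY
    noise_sigma: float = 0.02
    breast_semiaxes_frac: tuple[float, float, float] = (0.44, 0.41, 0.44)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        object.__setattr__(self, "grid_shape", tuple(int(g) for g in self.grid_shape))


@dataclass
class PatientPhantom:
    """One simulated patient: DWI series, tissue masks and ground truth."""

    patient_id: str
    dwi: DwiSeries
    breast_mask: np.ndarray
    malignant_mask: np.ndarray
    benign_masks: tuple[np.ndarray, ...]
    truth: np.ndarray  # (nx, ny, nz, 3) ground-truth C1, C2, C3; 0 outside breast
    noise_sigma: float
    seed_entropy: int

    @property
    def lesion_mask(self) -> np.ndarray:
        m = self.malignant_mask.copy()
        for b in self.benign_masks:
            m |= b
        return m


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def sample_compartment_fractions(
    params: TissueParams, n: int, seed
) -> np.ndarray:
    """Draw ``n`` iid (C1, C2, C3) triples from the tissue distribution.

    Each component is log-normal with the configured median and IQR
    (degenerate at the median when the IQR is zero).  Returns an ``(n, 3)``
    array; reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    sig = params.log_sigmas()
    out = np.empty((int(n), 3))
    for i, m in enumerate(params.medians):
        if m == 0:
            out[:, i] = 0.0
        elif sig[i] == 0:
            out[:, i] = m
        else:
            out[:, i] = np.exp(np.log(m) + sig[i] * rng.standard_normal(int(n)))
    return out


def sample_patient_medians(
    params: TissueParams, n_patients: int, seed
) -> np.ndarray:
    """Draw per-patient tissue medians (the between-patient layer).

    The between-patient log-sigma is ``sqrt(1 - f^2)`` times the total
    log-sigma, where ``f`` is ``within_lesion_fraction``; voxel-level
    scatter supplies the remaining spread so that the voxel marginal keeps
    the configured median and (approximately) the configured IQR.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = _rng(seed)
    f = params.within_lesion_fraction
    sig_b = params.log_sigmas() * np.sqrt(1.0 - f * f)
    out = np.empty((int(n_patients), 3))
    for i, m in enumerate(params.medians):
        if m == 0:
            out[:, i] = 0.0
        elif sig_b[i] == 0:
            out[:, i] = m
        else:
            out[:, i] = np.exp(np.log(m) + sig_b[i] * rng.standard_normal(int(n_patients)))
    return out


def synthesize_voxel_signal(
    C: Sequence[float],
    protocol: AcquisitionProtocol = BREAST_PROTOCOL,
    spectrum: DiffusionSpectrum = BREAST_SPECTRUM,
) -> np.ndarray:
    """Noiseless tri-exponential signal, one value per acquisition.

    ``S(b) = C1 + C2 exp(-b D2) + C3 exp(-b D3)`` evaluated at every
    acquisition's b-value (identical within a shell).
    """
    C = np.asarray(C, dtype=float)
    if C.shape != (3,):
        raise ValueError("C must be a triple (C1, C2, C3)")
    if np.any(C < 0):
        raise ValueError("compartment contributions must be non-negative")
    b = protocol.acquisition_bvals
    D = np.asarray(spectrum.diffusivities)
    return np.exp(-np.outer(b, D)) @ C


def add_rician_noise(signal: np.ndarray, sigma: float, seed) -> np.ndarray:
    """Corrupt a magnitude signal with Rician noise.

    Each value ``s`` becomes ``sqrt((s + g1)^2 + g2^2)`` with ``g1, g2``
    iid N(0, sigma^2).  ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = _rng(seed)
    g1 = rng.normal(0.0, sigma, size=signal.shape)
    g2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + g1) ** 2 + g2**2)


def _ellipsoid_mask(
    grid: tuple[int, int, int],
    center: Sequence[float],
    semiaxes_vox: Sequence[float],
) -> np.ndarray:
    idx = np.indices(grid, dtype=float)
    r2 = np.zeros(grid)
    for ax in range(3):
        r2 += ((idx[ax] - center[ax]) / max(semiaxes_vox[ax], 1e-9)) ** 2
    return r2 <= 1.0


def _sample_lesion_mask(
    rng: np.random.Generator,
    config: PhantomConfig,
    params: TissueParams,
    breast: np.ndarray,
    forbidden: np.ndarray,
    min_voxels: int = 4,
    max_tries: int = 200,
) -> np.ndarray:
    """Place an ellipsoidal lesion in the ipsilateral (low-x) half."""
    nx, ny, nz = config.grid_shape
    vox = config.protocol.voxel_size_mm
    assert params.axis_ranges_mm is not None
    for _ in range(max_tries):
        semi = [
            rng.uniform(lo, hi) / 2.0 / vox[ax]
            for ax, (lo, hi) in enumerate(params.axis_ranges_mm)
        ]
        center = (
            rng.uniform(0.12 * nx, 0.38 * nx),
            rng.uniform(0.25 * ny, 0.75 * ny),
            rng.uniform(0.30 * nz, 0.70 * nz),
        )
        mask = _ellipsoid_mask(config.grid_shape, center, semi) & breast
        if mask.sum() >= min_voxels and not np.any(mask & forbidden):
            return mask
    raise PhantomConfigError(
        f"could not place a {params.label} lesion of axes {params.axis_ranges_mm} mm "
        f"on grid {config.grid_shape} after {max_tries} attempts"
    )


def _fill_voxels(
    rng: np.random.Generator,
    params: TissueParams,
    patient_median: np.ndarray,
    n_voxels: int,
) -> np.ndarray:
    """Voxel-level (n, 3) draws around a patient-level median."""
    sig_w = params.log_sigmas() * params.within_lesion_fraction
    out = np.empty((n_voxels, 3))
    for i in range(3):
        m = patient_median[i]
        if m == 0:
            out[:, i] = 0.0
        elif sig_w[i] == 0:
            out[:, i] = m
        else:
            out[:, i] = np.exp(np.log(m) + sig_w[i] * rng.standard_normal(n_voxels))
    return out


def generate_patient_phantom(
    config: PhantomConfig,
    seed,
    patient_id: str = "p00",
    n_benign: int = 1,
) -> PatientPhantom:
    """Simulate one patient: breast, lesions, ground truth and noisy DWI.

    With ``noise_sigma = 0`` every voxel's signal equals the forward model
    of the stored ground truth exactly.
    """
    if n_benign < 1:
        raise ValueError("each patient needs at least one benign lesion")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = _rng(ss)
    grid = config.grid_shape
    nx, ny, nz = grid

    center = (nx / 2.0, ny / 2.0, nz / 2.0)
    semi = tuple(f * g for f, g in zip(config.breast_semiaxes_frac, grid))
    breast = _ellipsoid_mask(grid, center, semi)

    mal_mask = _sample_lesion_mask(rng, config, config.malignant, breast, np.zeros(grid, bool))
    forbidden = mal_mask.copy()
    benign_masks = []
    for _ in range(n_benign):
        m = _sample_lesion_mask(rng, config, config.benign, breast, forbidden)
        benign_masks.append(m)
        forbidden |= m

    # Patient-level medians, then voxel-level heterogeneity.
    truth = np.zeros(grid + (3,))
    healthy_med = sample_patient_medians(config.healthy, 1, rng)[0]
    healthy_vox = breast & ~forbidden
    truth[healthy_vox] = _fill_voxels(rng, config.healthy, healthy_med, int(healthy_vox.sum()))
    mal_med = sample_patient_medians(config.malignant, 1, rng)[0]
    truth[mal_mask] = _fill_voxels(rng, config.malignant, mal_med, int(mal_mask.sum()))
    for m in benign_masks:
        ben_med = sample_patient_medians(config.benign, 1, rng)[0]
        truth[m] = _fill_voxels(rng, config.benign, ben_med, int(m.sum()))

    b = config.protocol.acquisition_bvals
    D = np.asarray(config.spectrum.diffusivities)
    decay = np.exp(-np.outer(b, D))  # (n_acq, 3)
    signal = truth.reshape(-1, 3) @ decay.T  # (n_vox, n_acq)
    signal = signal.reshape(grid + (b.size,))
    noisy = add_rician_noise(signal, config.noise_sigma, rng) if config.noise_sigma > 0 else signal

    dwi = DwiSeries(noisy, b, config.protocol.voxel_size_mm)
    return PatientPhantom(
        patient_id=patient_id,
        dwi=dwi,
        breast_mask=breast,
        malignant_mask=mal_mask,
        benign_masks=tuple(benign_masks),
        truth=truth,
        noise_sigma=config.noise_sigma,
        seed_entropy=int(np.asarray(ss.entropy).ravel()[0]) if ss.entropy is not None else 0,
    )


def generate_cohort(
    n_patients: int = 12,
    config: PhantomConfig | None = None,
    seed=0,
) -> list[PatientPhantom]:
    """Simulate a paired cohort of patient phantoms.

    Every patient has exactly one malignant and at least one benign lesion;
    the first two patients carry a second benign lesion, so the default
    12-patient cohort holds 12 malignant and 14 benign lesions.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    config = config or PhantomConfig()
    master = np.random.SeedSequence(seed)
    children = master.spawn(int(n_patients))
    phantoms = []
    for i, child in enumerate(children):
        n_benign = 2 if i < 2 else 1
        phantoms.append(
            generate_patient_phantom(config, child, patient_id=f"p{i:02d}", n_benign=n_benign)
        )
    return phantoms


def write_phantom(phantom: PatientPhantom, outdir: str | Path) -> dict[str, str]:
    """Externalize one phantom as NIfTI + sidecars; return name -> path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vox = phantom.dwi.voxel_size_mm
    written: dict[str, str] = {}
    for p in phantom.dwi.save(outdir / "dwi"):
        written[p.name] = str(p)
    p = save_mask(phantom.breast_mask, outdir / "mask_breast.nii", vox)
    written[p.name] = str(p)
    p = save_mask(phantom.malignant_mask, outdir / "mask_malignant.nii", vox)
    written[p.name] = str(p)
    for j, m in enumerate(phantom.benign_masks):
        p = save_mask(m, outdir / f"mask_benign_{j:02d}.nii", vox)
        written[p.name] = str(p)
    import nibabel as nib

    from .dwi import _affine

    truth_path = outdir / "truth_c.nii"
    nib.save(nib.Nifti1Image(phantom.truth, _affine(vox)), truth_path)
    written[truth_path.name] = str(truth_path)
    meta = {
        "patient_id": phantom.patient_id,
        "noise_sigma": phantom.noise_sigma,
        "n_benign": len(phantom.benign_masks),
    }
    meta_path = outdir / "phantom.json"
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    written[meta_path.name] = str(meta_path)
    return written
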