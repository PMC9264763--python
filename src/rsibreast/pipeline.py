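"""End-to-end pipeline: simulate -> preprocess -> fit -> ROI -> statistics.

Every stage externalizes its outputs in standard formats (NIfTI volumes,
FSL-style ``.bval`` sidecars, CSV tables, JSON reports) and the run writes
a manifest of SHA-256 checksums, so identical configuration and seed yield
identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .preprocess import average_shells, preprocess as preprocess_dwi
from .dwi import DwiSeries, ShellAveragedDwi, load_mask, save_mask
from .fit import compute_adc_map, derive_product_maps, fit_volume
from .protocol import AcquisitionProtocol, DiffusionSpectrum
from .roi import (
    METRICS,
    PatientMaps,
    TissueMask,
    build_cohort_table,
    define_healthy_control_roi,
)
from .stats import pairwise_wilcoxon_bonferroni, ranked_rm_anova, shapiro_wilk, levene

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ValidationReport",
    "validate_inputs",
    "analyze_patient",
    "analyze_cohort",
    "run_statistics",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Serializable configuration of the full pipeline (YAML round trip)."""

    # cohort / phantom
    n_patients: int = 12
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    shells: tuple[tuple[float, int], ...] = ((0.0, 2), (500.0, 6), (1500.0, 6), (4000.0, 15))
    te_ms: float = 82.0
    tr_ms: float = 9000.0
    delta_ms: float = 29.34
    Delta_ms: float = 37.67
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 5.0)
    spectrum: tuple[float, float, float] = (0.0, 1.5e-3, 10.8e-3)
    noise_sigma: float = 0.02
    # preprocessing
    percentile_q: float = 98.0
    histogram_bins: int = 256
    background_mask: str | None = None
    # fitting
    adc_b_max: float = 1500.0
    adc_mode: str = "ols"
    fit_scope: str = "rois"  # "rois" (lesions + healthy ROI) or "full"
    # ROI
    healthy_n_target: int = 500
    benign_pooling: str = "pooled"
    # statistics
    bonferroni_family: int = 3
    exact_cutoff: int = 25
    zero_method: str = "wilcox"
    # run
    seed: int = 0
    outdir: str = "rsibreast_out"

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.shells = tuple((float(b), int(n)) for b, n in self.shells)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.spectrum = tuple(float(d) for d in self.spectrum)
        self.protocol()  # validate shells early (b=0 present, counts >= 1)

    def protocol(self) -> AcquisitionProtocol:
        return AcquisitionProtocol(
            shells=self.shells,
            te_ms=self.te_ms,
            tr_ms=self.tr_ms,
            delta_ms=self.delta_ms,
            Delta_ms=self.Delta_ms,
            voxel_size_mm=self.voxel_size_mm,
        )

    def diffusion_spectrum(self) -> DiffusionSpectrum:
        return DiffusionSpectrum(self.spectrum)

    def phantom_config(self) -> sim.PhantomConfig:
        return sim.PhantomConfig(
            grid_shape=self.grid_shape,
            protocol=self.protocol(),
            spectrum=self.diffusion_spectrum(),
            noise_sigma=self.noise_sigma,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)

        def plain(obj):
            if isinstance(obj, tuple):
                return [plain(o) for o in obj]
            return obj

        payload = {k: plain(v) for k, v in dataclasses.asdict(self).items()}
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in payload:
                kwargs[f.name] = payload[f.name]
        return cls(**kwargs)


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str]


def validate_inputs(
    dwi_path: str | Path,
    bvals_path: str | Path,
    mask_paths: list[str | Path] = (),
) -> ValidationReport:
    """Check volume/label agreement, grid consistency and signal sanity."""
    import nibabel as nib

    violations: list[str] = []
    img = nib.load(Path(dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    bvals = np.loadtxt(Path(bvals_path)).ravel()
    if data.ndim != 4:
        violations.append(f"DWI is {data.ndim}D, expected 4D")
    else:
        if data.shape[3] != bvals.size:
            violations.append(
                f"count mismatch: {data.shape[3]} volumes vs {bvals.size} b-value labels"
            )
        if not np.all(np.isfinite(data)):
            violations.append("DWI contains non-finite values")
        elif np.any(data < 0):
            violations.append("DWI contains negative signal values")
    for mp in mask_paths:
        m = load_mask(mp)
        if m.shape != data.shape[:3]:
            violations.append(
                f"grid mismatch: mask {Path(mp).name} is {m.shape}, DWI grid is {data.shape[:3]}"
            )
    return ValidationReport(passed=not violations, violations=violations)


def analyze_patient(
    phantom: sim.PatientPhantom, config: PipelineConfig
) -> tuple[PatientMaps, dict]:
    """Preprocess, fit and summarize one patient; returns maps + stage report."""
    dwi = phantom.dwi
    avg_norm, report = preprocess_dwi(
        dwi, q=config.percentile_q, bins=config.histogram_bins
    )
    avg_raw = average_shells(dwi)  # ADC uses data without noise correction

    lesion_masks = [TissueMask("malignant", phantom.malignant_mask)] + [
        TissueMask("benign", m) for m in phantom.benign_masks
    ]
    healthy = define_healthy_control_roi(
        dwi.grid_shape,
        lesion_masks,
        n_target=config.healthy_n_target,
        eligible_mask=phantom.breast_mask,
    )

    if config.fit_scope == "full":
        fit_mask = None
    else:
        fit_mask = healthy.mask.copy()
        for m in lesion_masks:
            fit_mask |= m.mask
    maps = fit_volume(avg_norm, config.diffusion_spectrum(), mask=fit_mask)
    derived = derive_product_maps(maps)
    adc = compute_adc_map(avg_raw, b_max=config.adc_b_max, mode=config.adc_mode)

    entry = PatientMaps(
        patient_id=phantom.patient_id,
        metrics={
            "C1": maps.c1,
            "C2": maps.c2,
            "C3": maps.c3,
            "C1C2": derived.product,
            "sqrtC1C2": derived.root_product,
            "ADC": adc.adc,
        },
        malignant=lesion_masks[0],
        benign=lesion_masks[1:],
        healthy=healthy,
        voxel_size_mm=dwi.voxel_size_mm,
        adc_validity=adc.adc_valid,
    )
    report["patient_id"] = phantom.patient_id
    report["healthy_roi_voxels"] = healthy.n_voxels
    return entry, report


def analyze_cohort(
    phantoms: list[sim.PatientPhantom], config: PipelineConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """Run preprocessing/fit/ROI for every patient and build the cohort table."""
    entries, reports = [], []
    for ph in phantoms:
        entry, rep = analyze_patient(ph, config)
        entries.append(entry)
        reports.append(rep)
    table = build_cohort_table(entries, benign_pooling=config.benign_pooling)
    return table, reports


def run_statistics(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Full statistical battery on a cohort table.

    Returns a JSON-serializable dict with the two-way ranked RM-ANOVA, the
    per-metric marginal tissue-effect ANOVAs, the pairwise Wilcoxon blocks
    with Bonferroni adjustment, and normality/variance diagnostics.
    """
    metrics = [m for m in METRICS if m in set(table["metric"])]
    out: dict = {"alpha": 0.05}

    def _anova(sub, within):
        try:
            return [r.to_dict() for r in ranked_rm_anova(sub, within=within)]
        except Exception as exc:  # e.g. sphericity undefined for tiny cohorts
            return {"error": str(exc)}

    out["rm_anova_two_way"] = _anova(table, ("tissue", "metric"))
    out["rm_anova_by_metric"] = {
        m: _anova(table[table["metric"] == m], ("tissue",)) for m in metrics
    }
    out["pairwise_wilcoxon"] = {
        m: [
            r.to_dict()
            for r in pairwise_wilcoxon_bonferroni(
                table,
                m,
                family_size=config.bonferroni_family,
                zero_method=config.zero_method,
                exact_cutoff=config.exact_cutoff,
            )
        ]
        for m in metrics
    }
    diagnostics = {}
    for m in metrics:
        sub = table[table["metric"] == m]
        groups = [
            sub[sub["tissue"] == t]["median"].to_numpy()
            for t in ("malignant", "benign", "healthy")
        ]
        entry: dict = {}
        try:
            entry["levene"] = levene(groups, comparison=m).to_dict()
        except Exception as exc:  # degenerate groups in tiny cohorts
            entry["levene"] = {"error": str(exc)}
        entry["shapiro_wilk"] = {}
        for t, g in zip(("malignant", "benign", "healthy"), groups):
            try:
                entry["shapiro_wilk"][t] = shapiro_wilk(g, comparison=f"{m}/{t}").to_dict()
            except Exception as exc:
                entry["shapiro_wilk"][t] = {"error": str(exc)}
        diagnostics[m] = entry
    out["diagnostics"] = diagnostics
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> preprocess -> fit -> ROI -> statistics and write all artifacts.

    Returns the manifest (relative path -> SHA-256).  Identical config and
    seed produce identical manifests.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = [config.save(outdir / "config.yaml")]

    try:
        phantoms = sim.generate_cohort(
            config.n_patients, config.phantom_config(), seed=config.seed
        )
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    for ph in phantoms:
        paths = sim.write_phantom(ph, outdir / "patients" / ph.patient_id)
        written.extend(Path(p) for p in paths.values())

    try:
        entries, reports = [], []
        for ph in phantoms:
            entry, rep = analyze_patient(ph, config)
            entries.append(entry)
            reports.append(rep)
            pdir = outdir / "patients" / ph.patient_id
            (pdir / "preprocess.json").write_text(json.dumps(rep, indent=2) + "\n")
            written.append(pdir / "preprocess.json")
            for name in ("C1", "C2", "C3", "C1C2", "sqrtC1C2", "ADC"):
                vol = entry.metrics[name]
                import nibabel as nib

                from .dwi import _affine

                path = pdir / f"map_{name}.nii"
                nib.save(
                    nib.Nifti1Image(np.nan_to_num(vol, nan=-1.0), _affine(config.voxel_size_mm)),
                    path,
                )
                written.append(path)
            written.append(
                save_mask(entry.adc_validity, pdir / "map_ADC_valid.nii", config.voxel_size_mm)
            )
            written.append(
                save_mask(entry.healthy.mask, pdir / "mask_healthy.nii", config.voxel_size_mm)
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    try:
        table = build_cohort_table(entries, benign_pooling=config.benign_pooling)
        table_path = outdir / "cohort_table.csv"
        table.to_csv(table_path, index=False)
        written.append(table_path)
    except Exception as exc:
        raise PipelineError("roi", str(exc)) from exc

    try:
        reports_out = run_statistics(table, config)
        stats_path = outdir / "stats_reports.json"
        stats_path.write_text(json.dumps(reports_out, indent=2) + "\n")
        written.append(stats_path)
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    manifest = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
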