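"""Region-of-interest definition and per-patient median extraction.

Each patient contributes a single data point per tissue type per metric:
the median of the metric map over the malignant ROI, over all benign-lesion
voxels pooled, and over a 500-voxel healthy control ROI placed in the
contralateral half of the grid (relative to the malignant lesion), with
lesion and user-supplied exclusion voxels removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissueMask",
    "RoiError",
    "define_healthy_control_roi",
    "roi_median",
    "PatientMaps",
    "build_cohort_table",
    "COHORT_COLUMNS",
    "METRICS",
    "TISSUES",
]

METRICS = ("C1", "C2", "C3", "C1C2", "sqrtC1C2", "ADC")
TISSUES = ("malignant", "benign", "healthy")

COHORT_COLUMNS = (
    "patient_id",
    "tissue",
    "metric",
    "median",
    "n_voxels",
    "roi_volume_cm3",
)


class RoiError(ValueError):
    """Raised for degenerate or infeasible ROI requests."""


@dataclass
class TissueMask:
    """A labelled boolean voxel set on the DWI grid."""

    label: str
    mask: np.ndarray
    provenance: str = "generated"

    def __post_init__(self) -> None:
        if self.label not in TISSUES:
            raise ValueError(f"unknown tissue label {self.label!r}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def define_healthy_control_roi(
    grid_shape: tuple[int, int, int],
    lesion_masks: Sequence[TissueMask],
    exclusion_masks: Sequence[np.ndarray] = (),
    n_target: int = 500,
    eligible_mask: np.ndarray | None = None,
    seed=None,
) -> TissueMask:
    """Construct the healthy control ROI: a contralateral box of ``n_target`` voxels.

    The contralateral side is the half of the x-axis not containing the
    centroid of the malignant mask.  A box centred on the centroid of the
    eligible contralateral region grows face by face until it contains
    ``n_target`` eligible voxels (eligible = inside ``eligible_mask`` if
    given, outside every lesion and exclusion mask); the ``n_target``
    eligible voxels closest to the box centre are returned, so overlapping
    lesion voxels are excluded while the count is preserved.

    The construction is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators and ignored.
    """
    if n_target < 1:
        raise RoiError("n_target must be >= 1")
    grid_shape = tuple(int(g) for g in grid_shape)
    nx = grid_shape[0]

    mal = [m for m in lesion_masks if m.label == "malignant"]
    if not mal or mal[0].n_voxels == 0:
        raise RoiError(
            "a non-empty malignant mask is required to define the contralateral side"
        )
    mal_centroid_x = float(np.mean(np.nonzero(mal[0].mask)[0]))

    eligible = (
        np.ones(grid_shape, dtype=bool)
        if eligible_mask is None
        else np.asarray(eligible_mask, dtype=bool).copy()
    )
    for m in lesion_masks:
        eligible &= ~m.mask
    for m in exclusion_masks:
        eligible &= ~np.asarray(m, dtype=bool)

    contra = np.zeros(grid_shape, dtype=bool)
    if mal_centroid_x < nx / 2.0:
        contra[nx // 2 :] = True
    else:
        contra[: nx // 2] = True
    eligible &= contra

    available = int(eligible.sum())
    if available < n_target:
        raise RoiError(
            f"only {available} eligible contralateral voxels available, "
            f"need {n_target}"
        )

    coords = np.array(np.nonzero(eligible)).T  # (n, 3)
    center = coords.mean(axis=0)

    # Grow a box around the centre until it holds enough eligible voxels.
    half = np.ones(3, dtype=float)
    lo = np.maximum(np.round(center - half), 0).astype(int)
    hi = np.minimum(np.round(center + half), np.array(grid_shape) - 1).astype(int)
    ax = 0
    for _ in range(10 * sum(grid_shape)):
        box = np.zeros(grid_shape, dtype=bool)
        box[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
        inside = box & eligible
        if int(inside.sum()) >= n_target:
            break
        grew = False
        for _ in range(3):  # find an axis that can still grow
            a = ax % 3
            ax += 1
            if lo[a] > 0:
                lo[a] -= 1
                grew = True
                break
            if hi[a] < grid_shape[a] - 1:
                hi[a] += 1
                grew = True
                break
        if not grew and int((box & eligible).sum()) < n_target:
            # box already spans the grid half; fall back to all eligible
            inside = eligible
            break
    else:  # pragma: no cover - loop bound is generous
        inside = eligible

    cand = np.array(np.nonzero(inside)).T
    box_center = (lo + hi) / 2.0
    d2 = ((cand - box_center) ** 2).sum(axis=1)
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], d2))
    chosen = cand[order[:n_target]]
    out = np.zeros(grid_shape, dtype=bool)
    out[tuple(chosen.T)] = True
    return TissueMask("healthy", out, provenance="generated")


def roi_median(
    volume: np.ndarray,
    mask: TissueMask | np.ndarray,
    validity: np.ndarray | None = None,
) -> tuple[float, int]:
    """Median of a map over an ROI; returns ``(median, n_voxels)``.

    Even voxel counts use the midpoint of the two central order statistics.
    An optional validity mask (ADC) is intersected first; an empty
    intersection is an error.
    """
    m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    if validity is not None:
        m = m & np.asarray(validity, dtype=bool)
    if not m.any():
        raise RoiError("ROI is empty after validity filtering")
    values = np.asarray(volume)[m]
    return float(np.median(values)), int(values.size)


@dataclass
class PatientMaps:
    """Everything needed to summarize one patient into cohort records."""

    patient_id: str
    metrics: Mapping[str, np.ndarray]  # metric name -> map volume
    malignant: TissueMask
    benign: Sequence[TissueMask]
    healthy: TissueMask
    voxel_size_mm: tuple[float, float, float]
    adc_validity: np.ndarray | None = None


def _tissue_records(
    entry: PatientMaps, tissue: str, mask: np.ndarray, pooling_note: str = ""
) -> list[dict]:
    vol_cm3 = float(np.prod(entry.voxel_size_mm)) / 1000.0
    records = []
    for metric in METRICS:
        if metric not in entry.metrics:
            continue
        validity = entry.adc_validity if metric == "ADC" else None
        med, n = roi_median(entry.metrics[metric], mask, validity)
        records.append(
            {
                "patient_id": entry.patient_id,
                "tissue": tissue,
                "metric": metric,
                "median": med,
                "n_voxels": n,
                "roi_volume_cm3": n * vol_cm3,
            }
        )
    return records


def build_cohort_table(
    patients: Sequence[PatientMaps],
    benign_pooling: str = "pooled",
) -> pd.DataFrame:
    """Assemble the long-format cohort table: one median per patient x tissue x metric.

    Patients with several benign lesions contribute a single benign record
    per metric.  With ``benign_pooling='pooled'`` (default) the voxels of
    all benign lesions are pooled before the median; ``'median_of_medians'``
    takes the median of the per-lesion medians instead.
    """
    if benign_pooling not in ("pooled", "median_of_medians"):
        raise ValueError(f"unknown benign pooling rule {benign_pooling!r}")
    rows: list[dict] = []
    for entry in patients:
        for tissue, present in (
            ("malignant", entry.malignant is not None and entry.malignant.n_voxels > 0),
            ("benign", bool(entry.benign)),
            ("healthy", entry.healthy is not None and entry.healthy.n_voxels > 0),
        ):
            if not present:
                raise RoiError(
                    f"patient {entry.patient_id!r} is missing the {tissue} tissue"
                )
        rows.extend(_tissue_records(entry, "malignant", entry.malignant.mask))
        rows.extend(_tissue_records(entry, "healthy", entry.healthy.mask))
        if benign_pooling == "pooled" or len(entry.benign) == 1:
            pooled = np.zeros_like(entry.malignant.mask, dtype=bool)
            for b in entry.benign:
                pooled |= b.mask
            rows.extend(_tissue_records(entry, "benign", pooled))
        else:
            vol_cm3 = float(np.prod(entry.voxel_size_mm)) / 1000.0
            for metric in METRICS:
                if metric not in entry.metrics:
                    continue
                validity = entry.adc_validity if metric == "ADC" else None
                meds, ns = zip(
                    *(
                        roi_median(entry.metrics[metric], b, validity)
                        for b in entry.benign
                    )
                )
                rows.append(
                    {
                        "patient_id": entry.patient_id,
                        "tissue": "benign",
                        "metric": metric,
                        "median": float(np.median(meds)),
                        "n_voxels": int(sum(ns)),
                        "roi_volume_cm3": sum(ns) * vol_cm3,
                    }
                )
    table = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return table.sort_values(["patient_id", "tissue", "metric"]).reset_index(drop=True)
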