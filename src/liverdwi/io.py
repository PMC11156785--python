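"""NIfTI readers/writers, slice records and the benchmark report.

Interchange format is NIfTI: one H x W x N volume per repetition stack, one
binary H x W volume per ROI mask, plus a YAML sidecar recording the phantom
configuration and seed.  Reports are CSV with a fixed column order and floats
at 6 significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import PhantomConfig, PhantomSlice
from .qscore import RoiSet, normalized_scores, trace_reference

log = logging.getLogger("liverdwi")

MASK_NAMES = ("left_lobe", "right_lobe", "vessels", "lesions", "background")

REPORT_COLUMNS = ["method", "pa_n", "dc_n", "vd_n", "cnr_n", "qtotal"]

__all__ = [
    "SliceRecord",
    "write_slice",
    "read_slice",
    "write_dataset",
    "list_slice_records",
    "run_benchmark",
    "save_report",
]


@dataclass
class SliceRecord:
    """Paths and provenance of one stored slice."""

    patient_id: int
    slice_index: int
    stack_path: Path
    mask_paths: dict[str, Path]
    reference_path: Path | None = None
    truth_path: Path | None = None
    provenance: dict = field(default_factory=dict)


def _save_nii(data: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.eye(4)), str(path))


def _load_nii(path: Path) -> np.ndarray:
    try:
        return np.asarray(nib.load(str(path)).get_fdata())
    except Exception as exc:  # corrupted header, missing file, ...
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc


def write_slice(slice_: PhantomSlice, outdir: Path | str) -> SliceRecord:
    """Write one slice (stack, truth, masks) as NIfTI plus a YAML sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"p{slice_.patient_id:03d}_s{slice_.slice_index:03d}"
    stack_path = outdir / f"{tag}_stack.nii"
    truth_path = outdir / f"{tag}_truth.nii"
    _save_nii(slice_.stack, stack_path)
    _save_nii(slice_.truth, truth_path)
    mask_paths = {}
    for name, mask in slice_.rois.as_dict().items():
        p = outdir / f"{tag}_mask_{name}.nii"
        _save_nii(mask.astype(np.uint8), p)
        mask_paths[name] = p
    sidecar = {
        "patient_id": slice_.patient_id,
        "slice_index": slice_.slice_index,
        "dropout_log": [float(v) for v in slice_.dropout_log],
        "config": asdict(slice_.config),
    }
    with open(outdir / f"{tag}_config.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return SliceRecord(
        patient_id=slice_.patient_id,
        slice_index=slice_.slice_index,
        stack_path=stack_path,
        mask_paths=mask_paths,
        truth_path=truth_path,
        provenance={"config": asdict(slice_.config)},
    )


def write_dataset(slices: list[PhantomSlice], outdir: Path | str) -> list[SliceRecord]:
    return [write_slice(s, outdir) for s in slices]


def list_slice_records(indir: Path | str) -> list[SliceRecord]:
    """Discover slice records written by :func:`write_slice` in a directory."""
    indir = Path(indir)
    records = []
    for stack_path in sorted(indir.glob("*_stack.nii")):
        tag = stack_path.name[: -len("_stack.nii")]
        pid = int(tag.split("_")[0][1:])
        sidx = int(tag.split("_")[1][1:])
        mask_paths = {
            name: indir / f"{tag}_mask_{name}.nii"
            for name in MASK_NAMES
            if (indir / f"{tag}_mask_{name}.nii").exists()
        }
        truth = indir / f"{tag}_truth.nii"
        records.append(
            SliceRecord(
                patient_id=pid,
                slice_index=sidx,
                stack_path=stack_path,
                mask_paths=mask_paths,
                truth_path=truth if truth.exists() else None,
            )
        )
    return records


def read_slice(
    record: SliceRecord, dirs_per_rep: int = 3
) -> tuple[np.ndarray, RoiSet, np.ndarray]:
    """Load one slice: repetition stack, ROI set and reference image.

    Masks are binarized on load; all volumes are validated against the stack
    grid.  The reference is computed from the stack when no stored reference
    exists.  A missing lesion mask loads as an all-False mask (lesion-dependent
    scores are then unavailable and flagged by the scoring layer).
    """
    stack = _load_nii(record.stack_path)
    if stack.ndim != 3:
        raise ValueError(f"{record.stack_path}: expected H x W x N stack")
    grid = stack.shape[:2]
    masks = {}
    for name in MASK_NAMES:
        if name in record.mask_paths:
            m = _load_nii(record.mask_paths[name]) > 0.5
            if m.shape != grid:
                raise ValueError(
                    f"{record.mask_paths[name]}: mask grid {m.shape} != stack grid {grid}"
                )
        elif name == "lesions":
            log.warning(
                "slice p%s/s%s has no lesion mask; CNR unavailable",
                record.patient_id,
                record.slice_index,
            )
            m = np.zeros(grid, dtype=bool)
        else:
            raise ValueError(
                f"required mask {name!r} missing for slice "
                f"p{record.patient_id}/s{record.slice_index}"
            )
        masks[name] = m
    rois = RoiSet(**masks)
    if record.reference_path is not None:
        reference = _load_nii(record.reference_path)
        if reference.shape != grid:
            raise ValueError(f"{record.reference_path}: reference grid mismatch")
    else:
        reference = trace_reference(stack, dirs_per_rep)
    return stack, rois, reference


def slice_scores(
    processed: np.ndarray, reference: np.ndarray, rois: RoiSet
) -> dict[str, float]:
    """Normalized scores of one slice; on lesion-free slices the CNR ratio
    and Qtotal are NaN so the slice still contributes PA/VD/DC to means."""
    if rois.has_lesions:
        return normalized_scores(processed, reference, rois).as_dict()
    from .qscore import dc_score, pa_score, vd_score

    return {
        "pa_n": pa_score(processed, rois) / pa_score(reference, rois),
        "vd_n": vd_score(processed, rois) / vd_score(reference, rois),
        "cnr_n": float("nan"),
        "dc_n": dc_score(processed, reference, rois),
        "qtotal": float("nan"),
    }


def run_benchmark(
    dataset: list[PhantomSlice] | list[tuple[np.ndarray, RoiSet]],
    methods: dict[str, Callable[[np.ndarray], np.ndarray]],
    model=None,
    dirs_per_rep: int = 3,
) -> pd.DataFrame:
    """Per-method mean normalized scores over a dataset.

    ``methods`` maps a row name to a stack -> image callable; a fitted
    network (anything with ``predict(stack)``) adds a ``deep_learning`` row.
    Rows keep the given method order; columns are fixed.
    """
    all_methods = dict(methods)
    if model is not None:
        all_methods["deep_learning"] = model.predict
    rows = []
    for name, fn in all_methods.items():
        per_slice = []
        for item in dataset:
            if isinstance(item, PhantomSlice):
                stack, rois = item.stack, item.rois
            else:
                stack, rois = item
            reference = trace_reference(stack, dirs_per_rep)
            per_slice.append(slice_scores(fn(stack), reference, rois))
        means = pd.DataFrame(per_slice).mean()  # NaN-skipping per feature
        rows.append({"method": name, **means.to_dict()})
    return pd.DataFrame(rows)[REPORT_COLUMNS]


def save_report(table: pd.DataFrame, path: Path | str) -> None:
    """CSV report with fixed column order, floats at 6 significant digits."""
    table.to_csv(path, index=False, float_format="%.6g")
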