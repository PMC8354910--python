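"""Adapters between on-disk formats and in-memory containers.

Real-data inputs arrive as a 4-D BOLD NIfTI plus a 3-D binary ROI mask on
the same grid; spatial preprocessing is assumed to have happened upstream.
Voxel order in the extracted matrix is the flattened (C-order) index order
of in-mask voxels, and is returned so results can be mapped back.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Run

__all__ = ["load_real_run", "read_schedule"]


def read_schedule(schedule_tsv_path: str | Path) -> np.ndarray:
    """Per-scan labels from a schedule TSV (columns scan_index, onset_s, label)."""
    frame = pd.read_csv(schedule_tsv_path, sep="\t")
    if "label" not in frame.columns:
        raise ValueError("schedule TSV must have a 'label' column")
    return frame.sort_values("scan_index")["label"].to_numpy(dtype=object)


def load_real_run(
    bold_nifti_path: str | Path,
    roi_mask_nifti_path: str | Path,
    schedule_tsv_path: str | Path | None = None,
    tr_seconds: float | None = None,
    session_id: int | None = None,
) -> tuple[Run, np.ndarray | None, np.ndarray]:
    """Extract a ``scans x voxels`` run from a 4-D BOLD image and ROI mask.

    Returns ``(run, schedule_or_None, voxel_indices)`` where
    ``voxel_indices`` are the flat C-order indices of in-mask voxels.
    The TR is taken from the NIfTI header zooms unless given explicitly.
    """
    bold = nib.load(str(bold_nifti_path))
    mask_img = nib.load(str(roi_mask_nifti_path))
    bold_data = np.asanyarray(bold.dataobj)
    mask = np.asanyarray(mask_img.dataobj) > 0

    if bold_data.ndim != 4:
        raise ValueError(f"BOLD image must be 4-D, got shape {bold_data.shape}")
    if mask.ndim != 3:
        raise ValueError(f"ROI mask must be 3-D, got shape {mask.shape}")
    if bold_data.shape[:3] != mask.shape:
        raise ValueError(
            f"grid mismatch: BOLD {bold_data.shape[:3]} vs mask {mask.shape}"
        )
    voxel_indices = np.flatnonzero(mask.ravel(order="C"))
    if voxel_indices.size == 0:
        raise ValueError("ROI mask selects no voxels")

    n_scans = bold_data.shape[3]
    flat = bold_data.reshape(-1, n_scans, order="C")  # voxels x scans
    matrix = flat[voxel_indices].T.astype(float)  # scans x voxels

    if tr_seconds is None:
        zooms = bold.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) >= 4 and zooms[3] > 0 else 3.0

    schedule = None
    if schedule_tsv_path is not None:
        schedule = read_schedule(schedule_tsv_path)
        if len(schedule) != n_scans:
            raise ValueError(
                f"schedule has {len(schedule)} rows but the run has {n_scans} scans"
            )
    run = Run(data=matrix, tr_seconds=tr_seconds, session_id=session_id)
    return run, schedule, voxel_indices
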