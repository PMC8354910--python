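"""Core in-memory containers shared across the pipeline.

A :class:`Run` is the canonical unit of fMRI data here: a dense
``scans x voxels`` matrix sampled every ``tr_seconds``.  Voxels are kept as a
flat index (ROI-mask order); no 3-D geometry is attached because every
operation downstream is purely multivariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Class labels used throughout. "Rest" marks inter-trial baseline scans in a
# task run's schedule; it is never a decoder class.
WRIST = "Wrist"
FINGER = "Finger"
REST = "Rest"


@dataclass
class Run:
    """One fMRI session: ``data[t, v]`` is the BOLD signal of voxel ``v`` at
    scan ``t``; scans are ``tr_seconds`` apart.

    Parameters
    ----------
    data:
        2-D float array, shape ``(n_scans, n_voxels)``.
    tr_seconds:
        Repetition time (sampling interval) in seconds.
    session_id:
        Identifier of the session this run came from (0-based); ``None`` for
        resting runs.
    """

    data: np.ndarray
    tr_seconds: float = 3.0
    session_id: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"Run.data must be 2-D (scans x voxels), got ndim={self.data.ndim}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "Run":
        """Return a copy of this run carrying new data, same metadata."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class NuisanceSet:
    """Scan-wise nuisance time series attached to one run.

    Holds the nine standard confound series: cerebrospinal fluid (``csf``),
    white matter (``wm``), global signal (``gs``) and six rigid-body motion
    parameters (``rp``, shape ``(n_scans, 6)``).
    """

    csf: np.ndarray
    wm: np.ndarray
    gs: np.ndarray
    rp: np.ndarray

    def __post_init__(self) -> None:
        self.csf = np.asarray(self.csf, dtype=float).ravel()
        self.wm = np.asarray(self.wm, dtype=float).ravel()
        self.gs = np.asarray(self.gs, dtype=float).ravel()
        self.rp = np.asarray(self.rp, dtype=float)
        if self.rp.ndim != 2 or self.rp.shape[1] != 6:
            raise ValueError(f"rp must have shape (n_scans, 6), got {self.rp.shape}")
        n = self.csf.shape[0]
        if n == 0:
            raise ValueError("nuisance series must be non-empty")
        if not (self.wm.shape[0] == n == self.gs.shape[0] == self.rp.shape[0]):
            raise ValueError("all nuisance series must share the run's scan count")

    @property
    def n_scans(self) -> int:
        return self.csf.shape[0]

    def base_columns(self) -> np.ndarray:
        """The nine raw confound series stacked as columns.

        Order: CSF, WM, GS, then the six motion parameters.
        """
        return np.column_stack([self.csf, self.wm, self.gs, self.rp])

    def map_series(self, fn) -> "NuisanceSet":
        """Apply ``fn`` (1-D array -> 1-D array) to every series."""
        return NuisanceSet(
            csf=fn(self.csf),
            wm=fn(self.wm),
            gs=fn(self.gs),
            rp=np.column_stack([fn(self.rp[:, j]) for j in range(6)]),
        )
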