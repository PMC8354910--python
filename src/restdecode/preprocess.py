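"""Temporal preprocessing: confound regression, trend removal, band-pass.

Task runs get confound + trend regression only.  Resting runs are demeaned
per voxel, band-pass filtered (0.010-0.10 Hz, zero-phase Butterworth), and
then regressed against confound regressors that were passed through the same
filter — filtering the regressors identically prevents the regression from
reintroducing frequencies the filter removed.

The confound design follows the standard expansion: for each of the nine base
series (CSF, WM, GS, six motion parameters) the design carries the series,
its temporal derivative, its square, and its derivative's square; every
confound column is scaled so its maximum absolute value is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import NuisanceSet, Run

__all__ = [
    "RegressorMatrix",
    "build_noise_regressors",
    "add_trend_regressors",
    "regress_out",
    "bandpass_filter",
    "preprocess_task_run",
    "preprocess_rest_run",
]

NOISE_ROLES = ("noise", "noise_derivative", "noise_quadratic", "noise_derivative_quadratic")


@dataclass
class RegressorMatrix:
    """A ``scans x regressors`` design with one role tag per column."""

    matrix: np.ndarray
    column_roles: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("regressor matrix must be 2-D")
        if self.matrix.shape[1] != len(self.column_roles):
            raise ValueError("one role per column required")
        if self.column_roles.count("constant") > 1:
            raise ValueError("duplicate constant column")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]


def _max_abs_normalize(col: np.ndarray) -> np.ndarray:
    """Scale so max |value| is exactly 1; all-zero columns stay zero."""
    m = np.max(np.abs(col))
    return col if m == 0 else col / m


def _derivative(col: np.ndarray) -> np.ndarray:
    """First-order backward difference with a leading zero (length-preserving)."""
    out = np.zeros_like(col)
    out[1:] = np.diff(col)
    return out


def build_noise_regressors(nuisance: NuisanceSet) -> RegressorMatrix:
    """Expand the nine confound series into the 36-column noise design
    ``[N, N', N^2, N'^2]``, each column normalised to max |value| = 1."""
    base = nuisance.base_columns()
    deriv = np.apply_along_axis(_derivative, 0, base)
    blocks = [base, deriv, base**2, deriv**2]
    cols = np.column_stack([np.apply_along_axis(_max_abs_normalize, 0, b) for b in blocks])
    roles = [role for role, b in zip(NOISE_ROLES, blocks) for _ in range(b.shape[1])]
    return RegressorMatrix(matrix=cols, column_roles=roles)


def add_trend_regressors(reg: RegressorMatrix, n_scans: int) -> RegressorMatrix:
    """Append the baseline (constant) and linear-trend columns.

    The trend is a ramp scaled to [-1, 1].  Calling twice is an error (the
    constant column must appear exactly once).
    """
    if reg.n_scans != n_scans:
        raise ValueError(f"regressor matrix has {reg.n_scans} scans, expected {n_scans}")
    if "constant" in reg.column_roles or "trend" in reg.column_roles:
        raise ValueError("trend/baseline regressors already present")
    const = np.ones(n_scans)
    ramp = np.linspace(-1.0, 1.0, n_scans) if n_scans > 1 else np.zeros(1)
    return RegressorMatrix(
        matrix=np.column_stack([reg.matrix, const, ramp]),
        column_roles=reg.column_roles + ["constant", "trend"],
    )


def regress_out(data: Run, reg: RegressorMatrix) -> Run:
    """Remove the regressors by least squares; returns the residual run.

    Uses the pseudoinverse projection so rank-deficient designs (duplicated
    or zero columns) are handled without error; residuals are orthogonal to
    every regressor column.
    """
    if data.n_scans != reg.n_scans:
        raise ValueError(
            f"run has {data.n_scans} scans but regressors have {reg.n_scans}"
        )
    X = reg.matrix
    beta = np.linalg.pinv(X) @ data.data
    return data.with_data(data.data - X @ beta)


def design_bandpass(
    tr_seconds: float, low_hz: float = 0.010, high_hz: float = 0.10, order: int = 4
):
    """Second-order sections for the band-pass; raises if the passband is
    infeasible at this sampling rate."""
    fs = 1.0 / tr_seconds
    nyquist = fs / 2.0
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"passband ({low_hz}-{high_hz} Hz) infeasible for TR {tr_seconds} s "
            f"(Nyquist {nyquist:.4f} Hz)"
        )
    return signal.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")


def bandpass_filter(
    data: Run,
    low_hz: float = 0.010,
    high_hz: float = 0.10,
    order: int = 4,
) -> Run:
    """Zero-phase Butterworth band-pass, applied per voxel.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    attenuation and cancels phase shifts; DC is outside the passband, so the
    per-voxel output mean is ~0.
    """
    sos = design_bandpass(data.tr_seconds, low_hz, high_hz, order)
    if data.n_scans <= 6 * order:
        raise ValueError(f"run too short ({data.n_scans} scans) for an order-{order} band-pass")
    return data.with_data(signal.sosfiltfilt(sos, data.data, axis=0))


def _full_design(nuisance: NuisanceSet, n_scans: int) -> RegressorMatrix:
    return add_trend_regressors(build_noise_regressors(nuisance), n_scans)


def preprocess_task_run(run: Run, nuisance: NuisanceSet) -> Run:
    """Task-session preprocessing: regress out the full confound + trend
    design.  No band-pass is applied to task runs."""
    return regress_out(run, _full_design(nuisance, run.n_scans))


def preprocess_rest_run(
    run: Run,
    nuisance: NuisanceSet,
    low_hz: float = 0.010,
    high_hz: float = 0.10,
    order: int = 4,
) -> Run:
    """Resting-run preprocessing: demean per voxel, band-pass, then regress
    out band-pass-matched confounds plus trend.

    The confound series are passed through the identical filter before the
    regressor expansion so the regression cannot reintroduce out-of-band
    power.  The constant column in the design guarantees ~0 output means.
    """
    demeaned = run.with_data(run.data - run.data.mean(axis=0, keepdims=True))
    filtered = bandpass_filter(demeaned, low_hz, high_hz, order)

    sos = design_bandpass(run.tr_seconds, low_hz, high_hz, order)
    filt_nuis = nuisance.map_series(lambda s: signal.sosfiltfilt(sos, s))
    design = _full_design(filt_nuis, run.n_scans)
    return regress_out(filtered, design)
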