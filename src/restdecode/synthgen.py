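"""Synthetic subjects for the cross-decoding pipeline.

The generator emulates the study design the analysis expects: block-design
wrist/finger movement sessions (18 s blocks, 4 trials per class per session,
TR 3 s, 102 scans per session) and a 200-scan resting run.  Resting activity
is built by the additive mixture the analysis is designed to detect: a
task-relevant component (the wrist/finger spatial patterns modulated by slow
latent processes) plus task-irrelevant noise plus physiological/motion
nuisance.  Setting ``rc_amplitude = 0`` produces a null world in which resting
scans carry no task-pattern information; setting ``task_amplitude = 0``
produces task runs whose labels are independent of the data.

Every generated quantity is a deterministic function of the configuration and
seed, so tests downstream can assert exact reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .core import FINGER, REST, WRIST, NuisanceSet, Run

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SubjectDataset",
    "double_gamma_hrf",
    "generate_patterns",
    "generate_nuisance",
    "generate_task_run",
    "generate_rest_run",
    "generate_subject",
    "schedule_to_frame",
    "write_schedule",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration.

    Defaults encode the study design: 18 s blocks at TR 3 s, four trials per
    class per session giving 102 scans per task session, eight sessions, and
    a 200-scan resting run.

    Parameters
    ----------
    n_voxels:
        Voxels in the simulated ROI.
    n_sessions:
        Number of movement-task sessions (>= 2; leave-one-session-out
        cross-validation needs at least two).
    tr_seconds:
        Sampling interval in seconds.
    block_seconds:
        Duration of each task block and of each interleaved rest block; must
        be an integer multiple of ``tr_seconds``.
    trials_per_class_per_session:
        Task blocks per class in one session.
    rest_scans:
        Length of the resting run in scans.
    task_amplitude:
        Gain of the class pattern in task blocks (0 = no task signal, labels
        independent of data).
    rc_amplitude:
        Gain of the task-relevant component in the resting run (0 = pure
        task-irrelevant null world).
    common_amplitude:
        Gain of a third spatial pattern injected into both task blocks (both
        classes) and rest; models activity shared between states that carries
        no class information.  Off by default.
    noise_sd:
        Standard deviation of i.i.d. Gaussian scan noise per voxel.
    pattern_overlap:
        Target Pearson correlation between the wrist and finger patterns,
        in [0, 1).
    nuisance_gain:
        Coupling of the nuisance processes into the voxel signal.
    seed:
        Seed for all randomness when no generator is supplied.
    """

    n_voxels: int = 200
    n_sessions: int = 8
    tr_seconds: float = 3.0
    block_seconds: float = 18.0
    trials_per_class_per_session: int = 4
    rest_scans: int = 200
    task_amplitude: float = 1.0
    rc_amplitude: float = 0.0
    common_amplitude: float = 0.0
    noise_sd: float = 1.0
    pattern_overlap: float = 0.0
    nuisance_gain: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 8:
            raise ValueError("n_voxels must be >= 8")
        if self.n_sessions < 2:
            raise ValueError("n_sessions must be >= 2 (leave-one-session-out CV needs >= 2)")
        if self.tr_seconds <= 0 or self.block_seconds <= 0:
            raise ValueError("tr_seconds and block_seconds must be positive")
        ratio = self.block_seconds / self.tr_seconds
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("block_seconds must be an integer multiple of tr_seconds")
        if self.trials_per_class_per_session < 1:
            raise ValueError("trials_per_class_per_session must be >= 1")
        if self.rest_scans < 2:
            raise ValueError("rest_scans must be >= 2")
        if not (0.0 <= self.pattern_overlap < 1.0):
            raise ValueError("pattern_overlap must lie in [0, 1)")
        if self.rc_amplitude < 0:
            raise ValueError("rc_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def block_scans(self) -> int:
        """Scans per block (task or rest)."""
        return int(round(self.block_seconds / self.tr_seconds))

    @property
    def task_run_scans(self) -> int:
        """Scans in one task session: leading rest block, then each task
        block followed by a rest block."""
        n_task_blocks = 2 * self.trials_per_class_per_session
        return (2 * n_task_blocks + 1) * self.block_scans


@dataclass
class GroundTruth:
    """The latent spatial patterns a simulated subject expresses.

    ``wrist_pattern`` and ``finger_pattern`` are unit-Euclidean-norm voxel
    vectors whose Pearson correlation equals ``realized_overlap``.
    ``common_pattern`` is an optional third unit-norm vector shared between
    task and rest when ``common_amplitude > 0``.
    """

    wrist_pattern: np.ndarray
    finger_pattern: np.ndarray
    realized_overlap: float
    common_pattern: np.ndarray | None = None


@dataclass
class SubjectDataset:
    """Everything generated for one simulated subject."""

    task_runs: list[Run]
    schedules: list[np.ndarray]
    task_nuisance: list[NuisanceSet]
    rest_run: Run
    rest_nuisance: NuisanceSet
    truth: GroundTruth
    config: SimConfig


def double_gamma_hrf(tr_seconds: float, duration_seconds: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR.

    Peak at 6 s, undershoot at 16 s, undershoot ratio 1/6; normalised so the
    kernel's maximum is 1.  Any plausible HRF serves here — the pipeline fits
    no GLM — so this is a fixed documented constant.
    """
    t = np.arange(0, duration_seconds + 1e-9, tr_seconds)
    from scipy.stats import gamma as gamma_dist

    peak = gamma_dist.pdf(t, a=6, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_patterns(config: SimConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw the wrist and finger spatial patterns.

    Construction: draw two i.i.d. Gaussian voxel vectors, orthogonalise the
    second against the first in the mean-centred (Pearson) sense, and mix
    them so the realised Pearson correlation equals ``pattern_overlap``
    exactly; both outputs are scaled to unit Euclidean norm (which leaves the
    correlation unchanged).
    """
    if config.n_voxels < 8:
        raise ValueError("n_voxels must be >= 8 to realise a stable overlap")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rho = config.pattern_overlap

    for _ in range(50):
        z1 = rng.standard_normal(config.n_voxels)
        z2 = rng.standard_normal(config.n_voxels)
        c1 = z1 - z1.mean()
        c2 = z2 - z2.mean()
        c2 = c2 - (c2 @ c1) / (c1 @ c1) * c1  # orthogonal to c1, still zero-mean
        n1, n2 = np.linalg.norm(c1), np.linalg.norm(c2)
        if n1 < 1e-12 or n2 < 1e-12:
            continue  # astronomically unlikely; redraw
        mixed = rho * c1 / n1 + np.sqrt(1.0 - rho**2) * c2 / n2
        wrist = _unit(c1)
        finger = _unit(mixed)
        realized = float(np.corrcoef(wrist, finger)[0, 1])
        if abs(realized - rho) <= 0.05:
            common = None
            if config.common_amplitude > 0:
                common = _unit(rng.standard_normal(config.n_voxels))
            return GroundTruth(
                wrist_pattern=wrist,
                finger_pattern=finger,
                realized_overlap=realized,
                common_pattern=common,
            )
    raise RuntimeError(
        f"could not realise pattern_overlap={rho} with n_voxels={config.n_voxels}"
    )


def generate_nuisance(
    n_scans: int, tr_seconds: float, rng: np.random.Generator
) -> NuisanceSet:
    """Plausible nuisance processes for one run.

    Motion parameters are scaled Gaussian random walks; CSF/WM/GS are slow
    sinusoids (periods of tens of seconds, random phase) plus white noise.
    Shapes are plumbing — only their removal matters downstream.
    """
    t = np.arange(n_scans) * tr_seconds

    def slow_series() -> np.ndarray:
        period = rng.uniform(40.0, 120.0)
        phase = rng.uniform(0, 2 * np.pi)
        return np.sin(2 * np.pi * t / period + phase) + 0.2 * rng.standard_normal(n_scans)

    rp = np.cumsum(0.05 * rng.standard_normal((n_scans, 6)), axis=0)
    return NuisanceSet(csf=slow_series(), wm=slow_series(), gs=slow_series(), rp=rp)


def _nuisance_contribution(
    nuis: NuisanceSet, n_voxels: int, gain: float, rng: np.random.Generator
) -> np.ndarray:
    """Project the nine nuisance series into voxel space via random loadings."""
    base = nuis.base_columns()  # scans x 9
    loadings = rng.standard_normal((base.shape[1], n_voxels)) / np.sqrt(base.shape[1])
    return gain * base @ loadings


def block_labels(config: SimConfig, first_task: str) -> np.ndarray:
    """Per-scan labels for one task session.

    Timeline: a rest block, then ``2 * trials_per_class_per_session`` task
    blocks alternating between the two classes (starting with ``first_task``),
    each followed by a rest block.
    """
    if first_task not in (WRIST, FINGER):
        raise ValueError(f"first_task must be {WRIST!r} or {FINGER!r}, got {first_task!r}")
    other = FINGER if first_task == WRIST else WRIST
    order = [first_task, other] * config.trials_per_class_per_session
    labels: list[str] = [REST] * config.block_scans
    for task in order:
        labels += [task] * config.block_scans
        labels += [REST] * config.block_scans
    return np.array(labels, dtype=object)


def generate_task_run(
    config: SimConfig,
    truth: GroundTruth,
    first_task: str,
    rng: np.random.Generator,
    session_id: int | None = None,
) -> tuple[Run, np.ndarray, NuisanceSet]:
    """Simulate one movement-task session.

    The per-scan signal is ``task_amplitude`` times the active class pattern
    modulated by an HRF-convolved boxcar, plus the nuisance contribution and
    i.i.d. Gaussian noise.  Returns the run, the per-scan label schedule and
    the nuisance set used.
    """
    labels = block_labels(config, first_task)
    n_scans = labels.shape[0]
    hrf = double_gamma_hrf(config.tr_seconds)

    data = np.zeros((n_scans, config.n_voxels))
    for cls, pattern in ((WRIST, truth.wrist_pattern), (FINGER, truth.finger_pattern)):
        boxcar = (labels == cls).astype(float)
        drive = np.convolve(boxcar, hrf)[:n_scans]
        data += config.task_amplitude * np.outer(drive, pattern)
    if config.common_amplitude > 0 and truth.common_pattern is not None:
        boxcar = (labels != REST).astype(float)
        drive = np.convolve(boxcar, hrf)[:n_scans]
        data += config.common_amplitude * np.outer(drive, truth.common_pattern)

    nuis = generate_nuisance(n_scans, config.tr_seconds, rng)
    data += _nuisance_contribution(nuis, config.n_voxels, config.nuisance_gain, rng)
    data += config.noise_sd * rng.standard_normal(data.shape)

    run = Run(data=data, tr_seconds=config.tr_seconds, session_id=session_id)
    return run, labels, nuis


def _slow_process(n_scans: int, tr_seconds: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance process band-limited below 0.1 Hz.

    White Gaussian noise low-pass filtered (4th-order Butterworth, 0.08 Hz,
    zero phase), then standardised.
    """
    fs = 1.0 / tr_seconds
    sos = signal.butter(4, 0.08, btype="low", fs=fs, output="sos")
    # pad by reflection is sosfiltfilt's default; generate extra samples to
    # avoid edge transients dominating short runs
    raw = rng.standard_normal(n_scans + 200)
    smooth = signal.sosfiltfilt(sos, raw)[100 : 100 + n_scans]
    smooth = smooth - smooth.mean()
    sd = smooth.std()
    if sd < 1e-12:
        return smooth
    return smooth / sd


def generate_rest_run(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> tuple[Run, NuisanceSet]:
    """Simulate the resting run as the weighted sum of task-relevant and
    task-irrelevant components.

    Each scan is ``rc_amplitude * (a_w(t) * wrist + a_f(t) * finger)`` with
    ``a_w, a_f`` independent slow (< 0.1 Hz) zero-mean unit-variance
    processes, plus white task-irrelevant noise and the nuisance
    contribution.  ``rc_amplitude = 0`` yields a pure task-irrelevant world.
    """
    n = config.rest_scans
    a_w = _slow_process(n, config.tr_seconds, rng)
    a_f = _slow_process(n, config.tr_seconds, rng)

    data = config.rc_amplitude * (
        np.outer(a_w, truth.wrist_pattern) + np.outer(a_f, truth.finger_pattern)
    )
    if config.common_amplitude > 0 and truth.common_pattern is not None:
        a_c = _slow_process(n, config.tr_seconds, rng)
        data += config.common_amplitude * np.outer(a_c, truth.common_pattern)

    nuis = generate_nuisance(n, config.tr_seconds, rng)
    data = data + _nuisance_contribution(nuis, config.n_voxels, config.nuisance_gain, rng)
    data += config.noise_sd * rng.standard_normal(data.shape)

    return Run(data=data, tr_seconds=config.tr_seconds), nuis


def generate_subject(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SubjectDataset:
    """Generate a full subject: ``n_sessions`` task runs with alternating
    first task (session 1 starts with Wrist), one resting run, fresh nuisance
    per run, all reproducible from the configuration seed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    truth = generate_patterns(config, rng)

    task_runs: list[Run] = []
    schedules: list[np.ndarray] = []
    task_nuis: list[NuisanceSet] = []
    for s in range(config.n_sessions):
        first = WRIST if s % 2 == 0 else FINGER  # odd-numbered sessions (1-based) start Wrist
        run, labels, nuis = generate_task_run(config, truth, first, rng, session_id=s)
        task_runs.append(run)
        schedules.append(labels)
        task_nuis.append(nuis)

    rest_run, rest_nuis = generate_rest_run(config, truth, rng)
    return SubjectDataset(
        task_runs=task_runs,
        schedules=schedules,
        task_nuisance=task_nuis,
        rest_run=rest_run,
        rest_nuisance=rest_nuis,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# serialisation


def schedule_to_frame(labels: np.ndarray, tr_seconds: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scan_index": np.arange(len(labels)),
            "onset_s": np.arange(len(labels)) * tr_seconds,
            "label": labels,
        }
    )


def write_schedule(labels: np.ndarray, tr_seconds: float, path: str | Path) -> None:
    schedule_to_frame(labels, tr_seconds).to_csv(path, sep="\t", index=False)


def _nuis_to_array(nuis: NuisanceSet) -> np.ndarray:
    return nuis.base_columns()


def _nuis_from_array(arr: np.ndarray) -> NuisanceSet:
    return NuisanceSet(csf=arr[:, 0], wm=arr[:, 1], gs=arr[:, 2], rp=arr[:, 3:9])


def save_dataset(ds: SubjectDataset, out_dir: str | Path) -> None:
    """Write a subject to a directory: one ``.npy`` array per run and
    nuisance block, TSV schedules, and a JSON config snapshot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(ds.config), indent=2))
    np.save(out / "wrist_pattern.npy", ds.truth.wrist_pattern)
    np.save(out / "finger_pattern.npy", ds.truth.finger_pattern)
    meta = {"realized_overlap": ds.truth.realized_overlap, "n_sessions": len(ds.task_runs)}
    (out / "truth.json").write_text(json.dumps(meta, indent=2))
    for i, (run, labels, nuis) in enumerate(zip(ds.task_runs, ds.schedules, ds.task_nuisance)):
        np.save(out / f"task_{i:02d}.npy", run.data)
        np.save(out / f"task_{i:02d}_nuisance.npy", _nuis_to_array(nuis))
        write_schedule(labels, ds.config.tr_seconds, out / f"task_{i:02d}_schedule.tsv")
    np.save(out / "rest.npy", ds.rest_run.data)
    np.save(out / "rest_nuisance.npy", _nuis_to_array(ds.rest_nuisance))


def load_dataset(in_dir: str | Path) -> SubjectDataset:
    """Inverse of :func:`save_dataset`."""
    src = Path(in_dir)
    config = SimConfig(**json.loads((src / "config.json").read_text()))
    meta = json.loads((src / "truth.json").read_text())
    truth = GroundTruth(
        wrist_pattern=np.load(src / "wrist_pattern.npy"),
        finger_pattern=np.load(src / "finger_pattern.npy"),
        realized_overlap=meta["realized_overlap"],
    )
    task_runs, schedules, task_nuis = [], [], []
    for i in range(meta["n_sessions"]):
        data = np.load(src / f"task_{i:02d}.npy")
        task_runs.append(Run(data=data, tr_seconds=config.tr_seconds, session_id=i))
        frame = pd.read_csv(src / f"task_{i:02d}_schedule.tsv", sep="\t")
        schedules.append(frame["label"].to_numpy(dtype=object))
        task_nuis.append(_nuis_from_array(np.load(src / f"task_{i:02d}_nuisance.npy")))
    rest_run = Run(data=np.load(src / "rest.npy"), tr_seconds=config.tr_seconds)
    rest_nuis = _nuis_from_array(np.load(src / "rest_nuisance.npy"))
    return SubjectDataset(
        task_runs=task_runs,
        schedules=schedules,
        task_nuisance=task_nuis,
        rest_run=rest_run,
        rest_nuisance=rest_nuis,
        truth=truth,
        config=config,
    )
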