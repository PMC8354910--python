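"""End-to-end experiment orchestration over simulated subjects.

For each subject: generate data, temporally preprocess every run, extract
trial patterns, score the decoder by leave-one-session-out CV, train the
final decoder on all sessions, cross-decode the resting run against the
shuffled-weight null, and record the outcome.  All randomness derives from a
single master seed: subject ``i`` uses ``SeedSequence([master_seed, i])``,
split once for data generation and once for the null.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Run
from .crossdecode import cross_decode
from .decoder import TrialSet, extract_trials, loo_cv_accuracy, train_decoder
from .preprocess import preprocess_rest_run, preprocess_task_run
from .synthgen import SimConfig, generate_subject

logger = logging.getLogger("restdecode")

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "run_subject",
    "run_experiment",
    "validate_report",
    "write_report",
]

# Every design constant of the study surfaces here as a named, defaulted key.
DEFAULT_CONFIG: dict = {
    "experiment": {
        "n_subjects": 5,
        "master_seed": 0,
    },
    "simulation": {
        "n_voxels": 200,
        "n_sessions": 8,
        "tr_seconds": 3.0,
        "block_seconds": 18.0,
        "trials_per_class_per_session": 4,
        "rest_scans": 200,
        "task_amplitude": 1.0,
        "rc_amplitude": 0.0,
        "common_amplitude": 0.0,
        "noise_sd": 1.0,
        "pattern_overlap": 0.0,
        "nuisance_gain": 0.5,
    },
    "preprocessing": {
        "low_hz": 0.010,
        "high_hz": 0.10,
        "order": 4,
    },
    "decoder": {
        "lam": 1.0,
        "drop_initial_scans": 2,
        "weight_map_fraction": 0.10,
    },
    "null": {
        "n_iterations": 1000,
        "normalize_scans": True,
    },
    "significance": {
        "alpha": 0.05,
    },
    "output": {
        "write_weight_maps": False,
    },
}


def load_config(source: str | Path | dict | None = None) -> dict:
    """Merge a YAML/JSON config (path or dict) over the defaults.

    Unknown sections or keys raise a ``ValueError`` listing every offender.
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        import yaml

        user = yaml.safe_load(Path(source).read_text()) or {}

    config = {sec: dict(vals) for sec, vals in DEFAULT_CONFIG.items()}
    offenders: list[str] = []
    for section, values in user.items():
        if section is None:
            section = "null"  # YAML parses the bare key `null` as None
        if section not in config:
            offenders.append(str(section))
            continue
        if not isinstance(values, dict):
            offenders.append(f"{section} (expected a mapping)")
            continue
        for key, value in values.items():
            if key not in config[section]:
                offenders.append(f"{section}.{key}")
            else:
                config[section][key] = value
    if offenders:
        raise ValueError(f"unknown config keys: {', '.join(sorted(offenders))}")
    return config


def _subject_seed_sequence(master_seed: int, subject_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), int(subject_index)])


def run_subject(config: dict, subject_index: int) -> dict:
    """Run the full pipeline for one simulated subject and return its record."""
    ss = _subject_seed_sequence(config["experiment"]["master_seed"], subject_index)
    gen_ss, null_ss = ss.spawn(2)
    gen_rng = np.random.default_rng(gen_ss)

    sim = SimConfig(**config["simulation"], seed=0)  # rng below overrides the seed path
    t0 = time.perf_counter()
    ds = generate_subject(sim, rng=gen_rng)

    pp = config["preprocessing"]
    dec = config["decoder"]
    trials: TrialSet | None = None
    for run, labels, nuis in zip(ds.task_runs, ds.schedules, ds.task_nuisance):
        clean = preprocess_task_run(run, nuis)
        ts = extract_trials(clean, labels, drop_initial=dec["drop_initial_scans"])
        trials = ts if trials is None else trials.concat(ts)

    accuracy, folds = loo_cv_accuracy(trials, lam=dec["lam"])
    model = train_decoder(trials, lam=dec["lam"])

    rest_clean = preprocess_rest_run(
        ds.rest_run, ds.rest_nuisance,
        low_hz=pp["low_hz"], high_hz=pp["high_hz"], order=pp["order"],
    )
    result = cross_decode(
        model,
        rest_clean,
        n_iterations=config["null"]["n_iterations"],
        alpha=config["significance"]["alpha"],
        rng=np.random.default_rng(null_ss),
        normalize_scans=config["null"]["normalize_scans"],
    )
    elapsed = time.perf_counter() - t0
    logger.info(
        "subject %d: accuracy=%.3f sd_rs_corrected=%.4g significant=%s (%.1fs)",
        subject_index, accuracy, result.sd_rs_corrected, result.significant, elapsed,
    )
    record = {
        "subject": subject_index,
        "seed_entropy": [int(config["experiment"]["master_seed"]), subject_index],
        "loo_cv_accuracy": accuracy,
        "realized_overlap": ds.truth.realized_overlap,
        "n_trials": trials.n_trials,
        "elapsed_seconds": elapsed,
        **result.to_record(),
    }
    record["_weights"] = model.w  # stripped before serialisation unless requested
    return record


def run_experiment(
    config: dict | str | Path | None = None,
    out_dir: str | Path | None = None,
    **overrides,
) -> dict:
    """Run the configured number of subjects and assemble the report.

    ``overrides`` are ``section.key=value`` style dotted keys (e.g.
    ``experiment__n_subjects=5``) applied after loading the config.
    """
    cfg = load_config(config)
    for dotted, value in overrides.items():
        section, _, key = dotted.partition("__")
        if section not in cfg or key not in cfg[section]:
            raise ValueError(f"unknown config key override: {dotted}")
        cfg[section][key] = value

    records = []
    weights = []
    for i in range(cfg["experiment"]["n_subjects"]):
        rec = run_subject(cfg, i)
        weights.append(rec.pop("_weights"))
        records.append(rec)

    accs = np.array([r["loo_cv_accuracy"] for r in records])
    sds = np.array([r["sd_rs_corrected"] for r in records])
    report = {
        "config": cfg,
        "created_unix": time.time(),
        "records": records,
        "summary": {
            "n_subjects": len(records),
            "mean_accuracy": float(accs.mean()),
            "sd_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
            "mean_sd_rs_corrected": float(sds.mean()),
            "significant_fraction": float(np.mean([r["significant"] for r in records])),
        },
    }
    if out_dir is not None:
        write_report(report, out_dir)
        if cfg["output"]["write_weight_maps"]:
            np.save(Path(out_dir) / "decoder_weights.npy", np.array(weights))
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write ``report.json`` and the per-subject ``summary.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    validate_report(report)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    frame = pd.DataFrame(report["records"])
    frame = frame.drop(columns=["elapsed_seconds"])  # keep the TSV reproducible
    frame.to_csv(out / "summary.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# report schema

_SCHEMA_PATH = Path(__file__).with_name("report_schema.json")


def _check(instance, schema, path: str, errors: list[str]) -> None:
    """Minimal JSON-schema subset checker (type / required / properties /
    items); a full validator library is deliberately not a dependency."""
    expected = schema.get("type")
    type_map = {
        "object": dict,
        "array": list,
        "string": str,
        "boolean": bool,
        "number": (int, float),
        "integer": int,
    }
    if expected is not None:
        pytype = type_map[expected]
        ok = isinstance(instance, pytype)
        if expected in ("number", "integer") and isinstance(instance, bool):
            ok = False
        if not ok:
            errors.append(f"{path or '$'}: expected {expected}, got {type(instance).__name__}")
            return
    if expected == "object":
        for req in schema.get("required", []):
            if req not in instance:
                errors.append(f"{path or '$'}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}", errors)
    elif expected == "array" and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def validate_report(report: dict) -> None:
    """Validate an experiment report against the published schema file."""
    schema = json.loads(_SCHEMA_PATH.read_text())
    errors: list[str] = []
    _check(report, schema, "", errors)
    if errors:
        raise ValueError("report does not match schema:\n" + "\n".join(errors))
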