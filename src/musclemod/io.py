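"""Reading and writing trial tables, results and configuration.

Trial tables are delimited text (CSV, UTF-8, header row mandatory) with
one row per trial: ``subject_id, group, task, trial`` followed by either
the 9 raw-RMS channels or the 7 merged MVC-normalized channels in
canonical order.  Results round-trip losslessly: SED and correlation
matrices as labelled CSV, module sets and nested diagnostics as JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (CHANNELS7, CHANNELS9, Config, GROUPS, ModuleSet,
                        N_CHANNELS, N_TASKS, N_TRIALS, SedMatrix, SubjectTruth,
                        TASKS, TrialSet)
from .exceptions import IntegrityError, SchemaError

logger = logging.getLogger("musclemod")

_META_COLS = ["subject_id", "group", "task", "trial"]
_SCHEMAS = {"raw9": CHANNELS9, "norm7": CHANNELS7}


def read_trial_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a trial table.

    ``schema`` is ``"raw9"`` (9 unmerged RMS channels, downstream merge
    required) or ``"norm7"`` (7 merged normalized channels).  Task labels
    outside the 6-task vocabulary, missing channel columns or duplicate
    (subject, task, trial) rows are rejected.  The schema is recorded in
    ``df.attrs["schema"]``.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"schema must be one of {tuple(_SCHEMAS)}")
    channels = list(_SCHEMAS[schema])
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS + channels if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df[_META_COLS + channels].copy()
    bad_tasks = sorted(set(df["task"]) - set(TASKS))
    if bad_tasks:
        raise SchemaError(f"unknown task labels: {bad_tasks}")
    bad_groups = sorted(set(df["group"]) - set(GROUPS))
    if bad_groups:
        raise SchemaError(f"unknown group labels: {bad_groups}")
    if df.duplicated(subset=["subject_id", "task", "trial"]).any():
        raise IntegrityError("duplicate (subject, task, trial) rows")
    if not df["trial"].between(1, N_TRIALS).all():
        raise IntegrityError(f"trial indices must lie in 1..{N_TRIALS}")
    vals = df[channels].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise IntegrityError("channel values must be finite and nonnegative")
    df.attrs["schema"] = schema
    return df


def trial_table_to_trialsets(df: pd.DataFrame) -> list[TrialSet]:
    """Convert a validated norm7 trial table into per-subject TrialSets.

    Every subject must have the full 6 tasks x 16 trials.
    """
    if df.attrs.get("schema") == "raw9":
        raise SchemaError("raw9 tables must be merged to 7 channels first "
                          "(preprocess.merge_wrist_channels)")
    out = []
    for sid, sub in df.groupby("subject_id", sort=True):
        acts = np.zeros((N_TASKS, N_TRIALS, N_CHANNELS))
        seen = np.zeros((N_TASKS, N_TRIALS), dtype=bool)
        for _, row in sub.iterrows():
            t = TASKS.index(row["task"])
            k = int(row["trial"]) - 1
            acts[t, k] = [row[c] for c in CHANNELS7]
            seen[t, k] = True
        if not seen.all():
            raise IntegrityError(f"subject {sid}: incomplete trial grid "
                                 f"({int(seen.sum())}/{N_TASKS * N_TRIALS} trials)")
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise IntegrityError(f"subject {sid} has multiple group labels")
        out.append(TrialSet(acts, subject_id=str(sid), group=str(groups[0])))
    return out


def trialsets_to_table(trialsets: list[TrialSet]) -> pd.DataFrame:
    """Flatten TrialSets into a norm7 trial table."""
    rows = []
    for ts in trialsets:
        for t, task in enumerate(TASKS):
            for k in range(N_TRIALS):
                row = {"subject_id": ts.subject_id, "group": ts.group,
                       "task": task, "trial": k + 1}
                row.update(dict(zip(CHANNELS7, ts.activations[t, k])))
                rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["schema"] = "norm7"
    return df


def write_trial_table(trialsets: list[TrialSet] | TrialSet, path: str | Path) -> Path:
    if isinstance(trialsets, TrialSet):
        trialsets = [trialsets]
    path = Path(path)
    trialsets_to_table(trialsets).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# result writers (round-trip lossless)

def write_sed_csv(sed: SedMatrix, path: str | Path,
                  task_order: tuple[str, ...] | None = None) -> Path:
    """Write a SED matrix as labelled CSV, optionally permuted to ``task_order``."""
    if task_order is not None:
        sed = sed.reordered(task_order)
    path = Path(path)
    pd.DataFrame(sed.d, index=list(sed.task_order), columns=list(sed.task_order)) \
        .rename_axis("task").to_csv(path, float_format="%.17g")
    return path


def read_sed_csv(path: str | Path) -> SedMatrix:
    df = pd.read_csv(path).set_index("task")
    return SedMatrix(df.to_numpy(dtype=float), task_order=tuple(df.index))


def write_moduleset_json(ms: ModuleSet, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "C": ms.C.tolist(), "W_task": ms.W_task.tolist(),
        "H_trial": ms.H_trial.tolist(),
        "vaf_total": ms.vaf_total, "vaf_local": ms.vaf_local.tolist(),
        "n_mod": ms.n_mod, "restarts_used": ms.restarts_used, "seed": ms.seed,
        "subject_id": ms.subject_id, "group": ms.group,
        "channels": list(CHANNELS7), "tasks": list(TASKS),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_moduleset_json(path: str | Path) -> ModuleSet:
    d = json.loads(Path(path).read_text())
    return ModuleSet(C=np.array(d["C"]), W_task=np.array(d["W_task"]),
                     H_trial=np.array(d["H_trial"]), vaf_total=d["vaf_total"],
                     vaf_local=np.array(d["vaf_local"]), n_mod=d["n_mod"],
                     restarts_used=d["restarts_used"], seed=d["seed"],
                     subject_id=d["subject_id"], group=d["group"])


def write_truth_json(truth: SubjectTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {"C_true": truth.C_true.tolist(), "W_true": truth.W_true.tolist(),
               "noise_sd": truth.noise_sd, "profile": truth.profile,
               "seed": truth.seed, "n_trials": truth.n_trials}
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_truth_json(path: str | Path) -> SubjectTruth:
    d = json.loads(Path(path).read_text())
    return SubjectTruth(C_true=np.array(d["C_true"]), W_true=np.array(d["W_true"]),
                        noise_sd=d["noise_sd"], profile=d["profile"],
                        seed=d["seed"], n_trials=d["n_trials"])


def write_matrix_csv(M: np.ndarray, path: str | Path,
                     labels: tuple[str, ...] = CHANNELS7,
                     index_name: str = "muscle") -> Path:
    path = Path(path)
    pd.DataFrame(np.asarray(M, dtype=float), index=list(labels), columns=list(labels)) \
        .rename_axis(index_name).to_csv(path, float_format="%.17g")
    return path


def read_matrix_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)


def write_results(results, path: str | Path) -> Path:
    """Dispatch writer for pipeline products.

    SED matrices go to labelled CSV, module sets and subject truths to
    JSON, DataFrames to CSV, plain arrays to labelled CSV when 7x7, and an
    empty list produces an empty file with a warning.
    """
    path = Path(path)
    if isinstance(results, SedMatrix):
        return write_sed_csv(results, path)
    if isinstance(results, ModuleSet):
        return write_moduleset_json(results, path)
    if isinstance(results, SubjectTruth):
        return write_truth_json(results, path)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=True)
        return path
    if isinstance(results, np.ndarray) and results.shape == (N_CHANNELS, N_CHANNELS):
        return write_matrix_csv(results, path)
    if isinstance(results, (list, tuple)) and len(results) == 0:
        warnings.warn(f"writing empty result list to {path}", RuntimeWarning)
        path.write_text("")
        return path
    if isinstance(results, dict):
        path.write_text(json.dumps(results, indent=1, default=_json_default))
        return path
    raise SchemaError(f"no writer for result type {type(results).__name__}")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path: str | Path | None) -> Config:
    """Load a Config from YAML (missing file or None gives defaults)."""
    if path is None:
        return Config()
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(Config.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return Config(**data)
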