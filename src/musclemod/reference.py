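"""Published group-level reference matrices.

Small CSV tables bundled with the package: the group-averaged SED
matrices, module-similarity cells (stratified by module count) and
pairwise-coactivation matrices reported for the severely impaired,
moderately impaired and unimpaired groups of the motivating stroke study.
They serve as worked-example inputs for the summary operations (the
subject-level EMG behind them was never deposited).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import GROUPS, SedMatrix, TASKS_TABLE_ORDER
from .exceptions import ParameterError


def _read(name: str) -> pd.DataFrame:
    with resources.files("musclemod.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _check_group(group: str) -> None:
    if group not in GROUPS:
        raise ParameterError(f"unknown group {group!r}")


def sed_table(group: str) -> SedMatrix:
    """Group-mean SED matrix (percent units), in the published WE-first order."""
    _check_group(group)
    df = _read(f"sed_{group}.csv").set_index("task")
    return SedMatrix(df.to_numpy(dtype=float), task_order=TASKS_TABLE_ORDER)


def coactivation_table(group: str) -> np.ndarray:
    """Group-mean 7x7 coactivation (correlation) matrix, canonical channel order."""
    _check_group(group)
    return _read(f"coactivation_{group}.csv").set_index("muscle").to_numpy(dtype=float)


def similarity_cells(which: str) -> pd.DataFrame:
    """Module-similarity cells as a long table (row, col, mean, sd).

    ``which`` is one of ``stroke_stroke``, ``unimpaired_unimpaired`` or
    ``stroke_unimpaired``; strata are module-count groups (S2/S3/S4 for
    stroke survivors with 2/3/4 modules, U4/U5 for unimpaired subjects).
    """
    valid = ("stroke_stroke", "unimpaired_unimpaired", "stroke_unimpaired")
    if which not in valid:
        raise ParameterError(f"which must be one of {valid}")
    return _read(f"similarity_{which}.csv")
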