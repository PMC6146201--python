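"""File formats: the per-subject epoch container and the printed-table
fixtures.

Epoch container
---------------
One subject = two files sharing a stem:

* ``<stem>.dat`` — raw little-endian float64, C order, trials x channels x
  samples (channel-major within a trial), microvolts;
* ``<stem>.json`` — sidecar with ``channels``, ``sampling_rate``, ``times``
  (ms), ``labels``, ``trial_ids``, ``subject_id``, ``n_trials`` and optional
  ``artifact_flags`` / ``config`` echo.

The write -> read round trip is bit-exact for data, labels, channels and
times.

Printed-table fixtures
----------------------
The per-subject generalization tables of the three classifiers, shipped as
CSV with header ``Subject,CA,AUC,SE,SP,Kappa,CT`` (20 subjects), are loaded
with :func:`read_table_fixture` / :func:`load_packaged_table`.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = [
    "write_epochs", "read_epochs", "read_table_fixture",
    "load_packaged_table", "FormatError", "PACKAGED_TABLES",
]

#: packaged fixture name per classifier
PACKAGED_TABLES = {
    "l1lr": "table_l1lr.csv",
    "rbfsvm": "table_rbfsvm.csv",
    "lda": "table_lda.csv",
}

TABLE_COLUMNS = ["Subject", "CA", "AUC", "SE", "SP", "Kappa", "CT"]


class FormatError(ValueError):
    """Malformed epoch container or fixture file."""


def write_epochs(epochs: EpochSet, stem: str | Path) -> None:
    """Write one subject's epochs as ``<stem>.dat`` + ``<stem>.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(epochs.data, dtype="<f8")
    data.tofile(stem.with_suffix(".dat"))
    sidecar = {
        "subject_id": epochs.subject_id,
        "n_trials": epochs.n_trials,
        "channels": list(epochs.channels),
        "sampling_rate": epochs.sampling_rate,
        "times": epochs.times.tolist(),
        "labels": [str(l) for l in epochs.labels],
        "trial_ids": epochs.trial_ids.tolist(),
        "artifact_flags": (
            None if epochs.artifact_flags is None
            else epochs.artifact_flags.astype(int).tolist()
        ),
        "meta": epochs.meta,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar))


def read_epochs(stem: str | Path) -> EpochSet:
    """Read an epoch container written by :func:`write_epochs`."""
    stem = Path(stem)
    sidecar_path = stem.with_suffix(".json")
    data_path = stem.with_suffix(".dat")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    for key in ("channels", "sampling_rate", "times", "labels", "n_trials"):
        if key not in sidecar:
            raise FormatError(f"sidecar missing required field {key!r}")
    channels = sidecar["channels"]
    times = np.asarray(sidecar["times"], dtype=float)
    n_trials = int(sidecar["n_trials"])
    raw = np.fromfile(data_path, dtype="<f8")
    expected = n_trials * len(channels) * times.size
    if raw.size != expected:
        raise FormatError(
            f"data size {raw.size} != trials*channels*samples = {expected} "
            f"declared by sidecar"
        )
    flags = sidecar.get("artifact_flags")
    return EpochSet(
        data=raw.reshape(n_trials, len(channels), times.size),
        labels=np.array(sidecar["labels"], dtype=object),
        channels=channels,
        times=times,
        sampling_rate=float(sidecar["sampling_rate"]),
        subject_id=sidecar.get("subject_id", "S0"),
        trial_ids=np.asarray(sidecar.get("trial_ids",
                                         np.arange(n_trials)), dtype=np.int64),
        artifact_flags=None if flags is None else np.asarray(flags, dtype=bool),
        meta=sidecar.get("meta", {}),
    )


def read_table_fixture(path: str | Path) -> pd.DataFrame:
    """Load a per-subject metric table CSV (header
    ``Subject,CA,AUC,SE,SP,Kappa,CT``), validating cells are numeric and
    warning when the row count is not the expected 20 subjects."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty fixture file {path}") from exc
    if list(table.columns) != TABLE_COLUMNS:
        raise FormatError(
            f"{path}: expected header {','.join(TABLE_COLUMNS)}, "
            f"got {','.join(table.columns)}"
        )
    for col in TABLE_COLUMNS[1:]:
        numeric = pd.to_numeric(table[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise FormatError(
                f"{path}: non-numeric cell at row {row + 1}, column {col!r}"
            )
        table[col] = numeric
    if len(table) != 20:
        warnings.warn(f"{path}: {len(table)} rows, expected 20 subjects")
    return table


def load_packaged_table(classifier: str) -> pd.DataFrame:
    """Load the shipped per-subject generalization table for one of
    ``l1lr`` / ``rbfsvm`` / ``lda``."""
    if classifier not in PACKAGED_TABLES:
        raise ValueError(f"no packaged table for {classifier!r}")
    ref = resources.files("n170trial") / "data" / PACKAGED_TABLES[classifier]
    with resources.as_file(ref) as path:
        return read_table_fixture(path)
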