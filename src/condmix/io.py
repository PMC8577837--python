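"""Trial-table I/O: CSV and HDF5 round trips for spike-count datasets.

The canonical on-disk form is a rectangular table with one row per
trial: a ``stimulus`` column (condition label or orientation in degrees)
followed by one non-negative integer column per neuron.  CSV is the
human-auditable interchange format; HDF5 (datasets ``/counts``,
``/stimulus``, ``/neuron_ids``) is preferred for more than ~10⁵ trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrialTable", "read_trials", "write_trials"]


@dataclass
class TrialTable:
    """One spike-count dataset: per-trial stimulus labels and count vectors."""

    stimulus: np.ndarray
    counts: np.ndarray
    neuron_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = _validate_counts(np.asarray(self.counts))
        self.stimulus = np.asarray(self.stimulus)
        if self.stimulus.shape[0] != self.counts.shape[0]:
            raise ValueError("stimulus and counts must have one row per trial")
        if self.neuron_ids is None:
            self.neuron_ids = [f"neuron_{i + 1}" for i in range(self.counts.shape[1])]
        if len(self.neuron_ids) != self.counts.shape[1]:
            raise ValueError("need one neuron id per count column")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.neuron_ids)
        df.insert(0, "stimulus", self.stimulus)
        return df


def _validate_counts(arr: np.ndarray) -> np.ndarray:
    if arr.ndim != 2:
        raise ValueError("counts must be a trials x neurons table")
    bad = ~(np.isfinite(arr.astype(float)) & (arr.astype(float) >= 0)
            & (np.mod(arr.astype(float), 1) == 0))
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"count at row {r}, column {c} is {arr[r, c]!r}; "
            "counts must be non-negative integers")
    return arr.astype(np.int64)


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def read_trials(path, fmt: str | None = None) -> TrialTable:
    """Read a trial table from CSV or HDF5 (format inferred from the suffix).

    Counts are validated on read: a negative or fractional entry raises
    a ``ValueError`` naming the offending cell.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        df = pd.read_csv(path)
        if "stimulus" not in df.columns:
            raise ValueError("CSV must have a 'stimulus' header column")
        neuron_ids = [c for c in df.columns if c != "stimulus"]
        counts = df[neuron_ids].to_numpy()
        stimulus = df["stimulus"].to_numpy()
        return TrialTable(stimulus, counts, neuron_ids)
    if fmt == "hdf5":
        import h5py
        with h5py.File(path, "r") as f:
            counts = f["counts"][...]
            stimulus = f["stimulus"][...]
            ids = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["neuron_ids"][...]]
        if stimulus.dtype.kind in ("S", "O"):
            stimulus = np.array([s.decode() if isinstance(s, bytes) else s
                                 for s in stimulus])
        return TrialTable(stimulus, counts, ids)
    raise ValueError(f"unknown format {fmt!r}")


def write_trials(table: TrialTable, path, fmt: str | None = None) -> None:
    """Write a trial table; the round trip through either format is lossless."""
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        table.to_dataframe().to_csv(path, index=False)
        return
    if fmt == "hdf5":
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=table.counts)
            stim = table.stimulus
            if stim.dtype.kind in ("U", "O"):
                stim = stim.astype("S")
            f.create_dataset("stimulus", data=stim)
            f.create_dataset("neuron_ids",
                             data=np.array(table.neuron_ids, dtype="S"))
        return
    raise ValueError(f"unknown format {fmt!r}")


def save_model_json(doc: dict, path, *, seed=None, config: dict | None = None) -> None:
    """Write a model/metrics document with schema, seed, and config hash."""
    import hashlib
    payload = dict(doc)
    payload.setdefault("schema_version", 1)
    if seed is not None:
        payload["seed"] = int(seed)
    blob = json.dumps(config or {}, sort_keys=True)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    with open(path, "w") as f:
        json.dump(payload, f, indent=1, sort_keys=True)
        f.write("\n")


def load_model_json(path) -> dict:
    with open(path) as f:
        return json.load(f)
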