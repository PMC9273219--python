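"""Reading and writing trace matrices.

Two on-disk dialects are supported:

* **CSV** — one neuron per row, first column a neuron id, remaining columns
  frames. Trial metadata lives in a JSON sidecar next to the CSV
  (``<stem>.json``) with keys ``sampling_rate_hz``, ``condition``,
  ``trial_id``.
* **HDF5** — a ``traces`` dataset (neurons x frames) with the same metadata
  stored as root attributes.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, MetadataError
from .trace import CalciumTraceSet

_META_KEYS = ("sampling_rate_hz", "condition", "trial_id")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def load_traces(path: str | Path, format: str | None = None) -> CalciumTraceSet:
    """Load a trial from ``path``; format inferred from suffix if omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if format == "csv":
        return _load_csv(path)
    if format == "hdf5":
        return _load_hdf5(path)
    raise ValueError(f"unknown format {format!r}")


def save_traces(traces: CalciumTraceSet, path: str | Path,
                format: str | None = None) -> Path:
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for i, row in enumerate(traces.values):
                writer.writerow([f"n{i:03d}"] + [repr(float(v)) for v in row])
        meta = {"sampling_rate_hz": traces.sampling_rate,
                "condition": traces.condition, "trial_id": traces.trial_id}
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif format == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("traces", data=traces.values)
            fh.attrs["sampling_rate_hz"] = traces.sampling_rate
            fh.attrs["condition"] = traces.condition
            fh.attrs["trial_id"] = traces.trial_id
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _load_csv(path: Path) -> CalciumTraceSet:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "sampling_rate_hz" not in meta:
        raise MetadataError("sidecar lacks sampling_rate_hz")
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh), start=1):
            if not rec:
                continue
            try:
                rows.append([float(v) for v in rec[1:]])
            except ValueError as exc:
                raise FormatError(f"non-numeric value on line {lineno}") from exc
    if not rows:
        raise FormatError(f"{path} contains no trace rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"ragged rows in {path}: frame counts {sorted(widths)}")
    return CalciumTraceSet(
        values=np.array(rows, dtype=float),
        sampling_rate=float(meta["sampling_rate_hz"]),
        trial_id=str(meta.get("trial_id", path.stem)),
        condition=str(meta.get("condition", "")),
    )


def _load_hdf5(path: Path) -> CalciumTraceSet:
    with h5py.File(path, "r") as fh:
        if "traces" not in fh:
            raise FormatError(f"{path} lacks a 'traces' dataset")
        values = fh["traces"][()]
        attrs = dict(fh.attrs)
    if "sampling_rate_hz" not in attrs:
        raise MetadataError(f"{path} lacks sampling_rate_hz attribute")
    return CalciumTraceSet(
        values=np.asarray(values, dtype=float),
        sampling_rate=float(attrs["sampling_rate_hz"]),
        trial_id=str(attrs.get("trial_id", path.stem)),
        condition=str(attrs.get("condition", "")),
    )
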