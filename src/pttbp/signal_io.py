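"""Reading and writing two-channel records and cuff-reference tables.

The native on-disk format is diffable plain text: a record CSV with columns
``time_s,ecg_mV,mic_V`` plus a JSON sidecar carrying the sampling rate,
subject parameters, the per-beat ground-truth table (when present) and
generation metadata.  Cuff reference readings travel as a CSV with header
``timestamp_s,sbp_mmHg,dbp_mmHg``.  All timestamps are record-relative
seconds with time zero at the first sample.

WFDB and EDF import adapters are interface stubs only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .bp_model import SubjectProfile
from .synthetic_data import SignalRecord

__all__ = [
    "FormatError",
    "ReferenceReading",
    "write_record",
    "read_record",
    "write_references",
    "read_references",
    "read_wfdb",
    "read_edf",
]

PathLike = Union[str, Path]

#: Float formatting for on-disk CSVs; 9+ significant digits so that
#: write -> read round-trips are identities to within float formatting.
_FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Raised when an on-disk record or reference table is malformed."""


@dataclass(frozen=True)
class ReferenceReading:
    """One timestamped cuff reading (record-relative seconds, mmHg)."""

    timestamp: float
    sbp_ref: float
    dbp_ref: float
    device_label: str = ""

    def __post_init__(self) -> None:
        if not (self.sbp_ref > self.dbp_ref > 0):
            raise FormatError(
                f"require sbp_ref > dbp_ref > 0, got "
                f"({self.sbp_ref}, {self.dbp_ref})"
            )


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_record(record: SignalRecord, path: PathLike) -> Path:
    """Write a record CSV plus its JSON sidecar; returns the CSV path."""
    path = Path(path)
    frame = pd.DataFrame(
        {"time_s": record.times(), "ecg_mV": record.ecg, "mic_V": record.mic}
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar: dict = {
        "sampling_rate": record.sampling_rate,
        "start_time": record.start_time,
        "n_samples": record.n_samples,
    }
    if record.subject is not None:
        sidecar["subject"] = dataclasses.asdict(record.subject)
    if record.ground_truth is not None:
        sidecar["ground_truth"] = record.ground_truth.to_dict(orient="list")
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_record(path: PathLike) -> SignalRecord:
    """Read a record CSV + JSON sidecar back into a :class:`SignalRecord`.

    The sidecar is mandatory (it carries the sampling rate); sample-count
    disagreement between CSV and sidecar, or a non-monotonic time column,
    is a :class:`FormatError`.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path} (sampling rate required)")
    sidecar = json.loads(sidecar_path.read_text())
    if "sampling_rate" not in sidecar:
        raise FormatError(f"sidecar {sidecar_path} lacks field 'sampling_rate'")
    frame = pd.read_csv(path)
    for col in ("time_s", "ecg_mV", "mic_V"):
        if col not in frame.columns:
            raise FormatError(f"record CSV lacks column '{col}'")
    if "n_samples" in sidecar and sidecar["n_samples"] != len(frame):
        raise FormatError(
            f"sample count mismatch: CSV has {len(frame)} rows, sidecar "
            f"claims {sidecar['n_samples']}"
        )
    t = frame["time_s"].to_numpy()
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise FormatError("non-monotonic time_s column")
    subject = None
    if "subject" in sidecar:
        subject = SubjectProfile(**sidecar["subject"])
    ground_truth = None
    if "ground_truth" in sidecar:
        ground_truth = pd.DataFrame(sidecar["ground_truth"])
    return SignalRecord(
        sampling_rate=float(sidecar["sampling_rate"]),
        ecg=frame["ecg_mV"].to_numpy(),
        mic=frame["mic_V"].to_numpy(),
        start_time=float(sidecar.get("start_time", t[0] if t.size else 0.0)),
        subject=subject,
        ground_truth=ground_truth,
    )


def write_references(readings: list[ReferenceReading], path: PathLike) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "timestamp_s": [r.timestamp for r in readings],
            "sbp_mmHg": [r.sbp_ref for r in readings],
            "dbp_mmHg": [r.dbp_ref for r in readings],
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_references(path: PathLike) -> list[ReferenceReading]:
    """Read cuff reference readings, sorted by timestamp.

    Rows violating ``sbp > dbp > 0`` raise a :class:`FormatError` naming
    the offending (1-based, header-exclusive) row number.
    """
    frame = pd.read_csv(path)
    for col in ("timestamp_s", "sbp_mmHg", "dbp_mmHg"):
        if col not in frame.columns:
            raise FormatError(f"references CSV lacks column '{col}'")
    readings = []
    for i, row in frame.iterrows():
        try:
            readings.append(
                ReferenceReading(
                    timestamp=float(row["timestamp_s"]),
                    sbp_ref=float(row["sbp_mmHg"]),
                    dbp_ref=float(row["dbp_mmHg"]),
                )
            )
        except FormatError as exc:
            raise FormatError(f"row {i + 1}: {exc}") from exc
    return sorted(readings, key=lambda r: r.timestamp)


def read_wfdb(path: PathLike) -> SignalRecord:  # pragma: no cover - stub
    """Interface stub for WFDB record import (not implemented)."""
    raise NotImplementedError(
        "WFDB import is an interface stub; convert the record to the native "
        "CSV + JSON sidecar format instead"
    )


def read_edf(path: PathLike) -> SignalRecord:  # pragma: no cover - stub
    """Interface stub for EDF record import (not implemented)."""
    raise NotImplementedError(
        "EDF import is an interface stub; convert the record to the native "
        "CSV + JSON sidecar format instead"
    )
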