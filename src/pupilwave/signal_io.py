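"""Long-format time-series I/O.

Recordings are serialized one sample per row with the header
``participant_id,group,session,sample,value``.  A session is one
contiguous signal (for pupillometry: 1 kHz pupil diameter over ~20
trials); sample indices are 0-based within a session.  Missing samples
are written as empty fields and read back as masked entries; an
additional numeric sentinel (e.g. 0 or -1, common in eye-tracker
exports) can be declared missing by the caller.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")

REQUIRED_COLUMNS = ["participant_id", "group", "session", "sample", "value"]


class SchemaError(ValueError):
    """A required column is missing or a label is malformed."""


class IntegrityError(ValueError):
    """Duplicate or inconsistent rows in a long-format table."""


@dataclass
class Signal:
    """One session's signal: values plus a missing-value mask.

    Masked entries carry no information; every downstream operation
    ignores them.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    session_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise IntegrityError(
                "values and missing_mask must have equal length "
                f"({self.values.size} != {self.missing_mask.size})"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean()) if len(self) else 0.0


@dataclass
class TimeSeriesRecording:
    """One participant's labeled multi-session recording."""

    participant_id: str
    group: str
    sessions: list[Signal] = field(default_factory=list)
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(
                f"group must be one of {GROUPS}, got {self.group!r}"
            )
        idx = [s.session_index for s in self.sessions]
        if len(set(idx)) != len(idx):
            raise IntegrityError(
                f"duplicate session indices for {self.participant_id}: {idx}"
            )
        self.sessions = sorted(self.sessions, key=lambda s: s.session_index)


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_long_table(
    path: str,
    missing_code: str | float | None = None,
    delimiter: str | None = None,
) -> list[TimeSeriesRecording]:
    """Read a long-format table into per-participant recordings.

    Empty fields and non-numeric values are always treated as missing;
    ``missing_code`` additionally declares a numeric sentinel as missing.
    Rows are grouped by (participant, session) and ordered by sample
    index.  Duplicate (participant, session, sample) triples raise
    :class:`IntegrityError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if df.empty:
        return []

    df["session"] = df["session"].astype(int)
    df["sample"] = df["sample"].astype(int)
    dup = df.duplicated(subset=["participant_id", "session", "sample"])
    if dup.any():
        first = df[dup].iloc[0]
        raise IntegrityError(
            "duplicate (participant, session, sample): "
            f"({first['participant_id']}, {first['session']}, {first['sample']})"
        )

    values = pd.to_numeric(df["value"], errors="coerce")
    mask = values.isna()
    if missing_code is not None:
        try:
            sentinel = float(missing_code)
            mask |= values == sentinel
        except (TypeError, ValueError):
            mask |= df["value"].astype(str).str.strip() == str(missing_code)
    df = df.assign(_value=values.fillna(0.0), _missing=mask)

    recordings = []
    n_rows = 0
    for pid, sub in df.groupby("participant_id", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise IntegrityError(
                f"participant {pid!r} has conflicting group labels: {list(groups)}"
            )
        sessions = []
        for sess, rows in sub.groupby("session", sort=True):
            rows = rows.sort_values("sample")
            sessions.append(
                Signal(
                    values=rows["_value"].to_numpy(),
                    missing_mask=rows["_missing"].to_numpy(),
                    session_index=int(sess),
                )
            )
            n_rows += len(rows)
        recordings.append(
            TimeSeriesRecording(
                participant_id=str(pid), group=str(groups[0]), sessions=sessions
            )
        )
    logger.info(
        "read %d rows -> %d recordings from %s", n_rows, len(recordings), path
    )
    return recordings


def write_long_table(
    recordings: list[TimeSeriesRecording],
    path: str,
    delimiter: str | None = None,
) -> None:
    """Write recordings in long format, re-readable by :func:`read_long_table`.

    Masked entries are emitted as empty fields, so the round trip is
    lossless for values, masks, labels, and ordering.
    """
    frames = []
    for rec in recordings:
        for sig in rec.sessions:
            vals = np.where(sig.missing_mask, np.nan, sig.values)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": rec.participant_id,
                        "group": rec.group,
                        "session": sig.session_index,
                        "sample": np.arange(len(sig)),
                        "value": vals,
                    }
                )
            )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=REQUIRED_COLUMNS)
    out.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)
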