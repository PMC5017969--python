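"""Reading/writing of recordings, annotations, feature tables and model artifacts.

Recordings are plain delimited text, one sample per row (a configurable
column for multi-column exports).  Annotation sidecars are CSV with header
``start,end,class_id``; sample indices are 0-based half-open ``[start, end)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Number of vowel classes (class ids run 1..N_CLASSES).
N_CLASSES = 11

#: Shortest trial a 3-level DWT and spectral framing can analyze.
MIN_TRIAL_LEN = 64


class SignalIOError(ValueError):
    """Raised on parse or validation failures in this module."""


@dataclass
class Recording:
    """A single-channel sEMG recording in millivolts."""

    samples: np.ndarray
    fs: float = 1000.0
    subject_id: str = ""
    channel_label: str = "ch1"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise SignalIOError("recording must be a non-empty 1-D sample vector")
        if not np.all(np.isfinite(self.samples)):
            raise SignalIOError("recording contains non-finite samples")
        if not self.fs > 0:
            raise SignalIOError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class AnnotationTrack:
    """Utterance intervals: sorted, non-overlapping (start, end, class_id) triples."""

    intervals: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(int(s), int(e), int(c)) for s, e, c in self.intervals]
        ivs.sort(key=lambda t: t[0])
        prev_end = -1
        for start, end, class_id in ivs:
            if start < 0 or end <= start:
                raise SignalIOError(f"invalid interval [{start}, {end})")
            if start < prev_end:
                raise SignalIOError(
                    f"interval [{start}, {end}) overlaps previous (ends at {prev_end})"
                )
            if not 1 <= class_id <= N_CLASSES:
                raise SignalIOError(
                    f"class_id {class_id} outside 1..{N_CLASSES}"
                )
            prev_end = end
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class Trial:
    """One isolated utterance with its vowel label."""

    samples: np.ndarray
    fs: float
    class_id: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < MIN_TRIAL_LEN:
            raise SignalIOError(
                f"trial has {self.samples.size} samples; minimum is {MIN_TRIAL_LEN}"
            )
        if not 1 <= int(self.class_id) <= N_CLASSES:
            raise SignalIOError(f"class_id {self.class_id} outside 1..{N_CLASSES}")
        self.class_id = int(self.class_id)

    def __len__(self) -> int:
        return len(self.samples)


def _delimiter_for(path: str) -> str | None:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".csv":
        return ","
    if ext == ".tsv":
        return "\t"
    return None  # whitespace


def read_recording(
    path: str,
    fs: float = 1000.0,
    column: int = 0,
    subject_id: str = "",
    channel_label: str = "ch1",
) -> Recording:
    """Parse a delimited text file into a :class:`Recording`.

    Non-numeric rows raise :class:`SignalIOError` naming the offending line.
    """
    delim = _delimiter_for(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(delim) if delim else line.split()
            if column >= len(fields):
                raise SignalIOError(
                    f"{path}: line {lineno} has no column {column}"
                )
            try:
                values.append(float(fields[column]))
            except ValueError as exc:
                raise SignalIOError(
                    f"{path}: non-numeric value {fields[column]!r} on line {lineno}"
                ) from exc
    if not values:
        raise SignalIOError(f"{path}: empty recording file")
    return Recording(np.array(values), fs=fs, subject_id=subject_id,
                     channel_label=channel_label)


def write_recording(rec: Recording, path: str) -> None:
    # %.17g round-trips float64 exactly
    with open(path, "w") as fh:
        fh.write("\n".join(format(v, ".17g") for v in rec.samples))
        fh.write("\n")


def read_annotations(path: str) -> AnnotationTrack:
    """Read a CSV sidecar with header ``start,end,class_id``."""
    df = pd.read_csv(path)
    required = {"start", "end", "class_id"}
    if not required.issubset(df.columns):
        raise SignalIOError(
            f"{path}: annotation file must have columns {sorted(required)}"
        )
    intervals = [
        (int(r.start), int(r.end), int(r.class_id)) for r in df.itertuples()
    ]
    return AnnotationTrack(intervals)


def write_annotations(ann: AnnotationTrack, path: str) -> None:
    pd.DataFrame(ann.intervals, columns=["start", "end", "class_id"]).to_csv(
        path, index=False
    )


def segment_trials(rec: Recording, ann: AnnotationTrack) -> list[Trial]:
    """Cut one :class:`Trial` per annotated interval, carrying labels through."""
    trials: list[Trial] = []
    n = len(rec)
    for start, end, class_id in ann.intervals:
        if end > n:
            raise SignalIOError(
                f"interval [{start}, {end}) exceeds recording length {n}"
            )
        trials.append(
            Trial(rec.samples[start:end].copy(), fs=rec.fs,
                  class_id=class_id, subject_id=rec.subject_id)
        )
    return trials


def write_feature_table(
    vectors: list,
    class_ids: list[int],
    subject_ids: list[str],
    path: str,
) -> None:
    """Write feature vectors plus labels as CSV.

    Header is the canonical 57 feature names followed by ``class_id`` and
    ``subject_id``.  All vectors must share an identical name tuple.
    """
    if not (len(vectors) == len(class_ids) == len(subject_ids)):
        raise SignalIOError("vectors, class_ids and subject_ids must align")
    if vectors:
        names = tuple(vectors[0].names)
        for v in vectors[1:]:
            if tuple(v.names) != names:
                raise SignalIOError("ragged feature rows: inconsistent names")
        data = np.array([v.values for v in vectors], dtype=float)
        df = pd.DataFrame(data, columns=list(names))
    else:
        from .features import FEATURE_NAMES

        df = pd.DataFrame(columns=list(FEATURE_NAMES))
    df["class_id"] = pd.array(class_ids, dtype="int64")
    df["subject_id"] = pd.array(subject_ids, dtype="string")
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "class_id" not in df.columns:
        raise SignalIOError(f"{path}: feature table lacks class_id column")
    return df
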