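"""Recordings, label events and artifact filtering.

A :class:`Recording` holds a fixed-rate multichannel physiological time
series for one subject/session: heart rate (HR, beats per minute), breath
rate (BR, breath cycles per minute), skin conductance (SC, microsiemens)
and skin temperature (ST, degrees Celsius), sampled at 10 Hz by default.
Frame ``k`` corresponds to time ``start_time_s + k / sampling_rate_hz``;
all windows downstream are half-open ``[a, b)`` in frame space.

Sensor artifacts (loss of skin contact driving skin conductance negative,
implausibly high heart rate) are repaired by :func:`filter_artifacts`:
short invalid runs are linearly interpolated, long ones are marked invalid
so that downstream windowing can reject them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical channel order used throughout the package.
CHANNELS = ("HR", "BR", "SC", "ST")

#: Mapping from channel name to its CSV column.
CHANNEL_COLUMNS = {
    "HR": "hr_bpm",
    "BR": "br_bcpm",
    "SC": "sc_us",
    "ST": "st_c",
}

_COLUMN_CHANNELS = {v: k for k, v in CHANNEL_COLUMNS.items()}

#: Default per-channel validity ranges, ``channel -> (low, high)`` inclusive
#: except that SC must be strictly positive.  BR and ST are unconstrained.
DEFAULT_ARTIFACT_RULES: dict[str, tuple[float, float]] = {
    "SC": (np.nextafter(0.0, 1.0), np.inf),
    "HR": (25.0, 240.0),
}

LABEL_STATES = ("concentration",)
LABEL_SOURCES = ("expert", "synthetic")


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Input values violate a domain invariant."""


@dataclass(frozen=True)
class Recording:
    """One subject/session multichannel recording.

    ``values`` has shape ``(n_channels, n_frames)`` with rows ordered as
    ``channel_names``.  ``invalid_mask`` (same shape, boolean) marks frames
    invalidated by artifact filtering; ``None`` means all frames are valid.
    """

    subject_id: str
    session_id: str
    values: np.ndarray
    channel_names: tuple[str, ...] = CHANNELS
    sampling_rate_hz: float = 10.0
    start_time_s: float = 0.0
    invalid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D (channels x frames) array")
        if values.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"{values.shape[0]} rows for {len(self.channel_names)} channels"
            )
        if values.shape[1] < 1:
            raise ValidationError("recording must contain at least one frame")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("duplicate channel names")
        unknown = set(self.channel_names) - set(CHANNELS)
        if unknown:
            raise ValidationError(f"unknown channels: {sorted(unknown)}")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.invalid_mask is not None:
            mask = np.asarray(self.invalid_mask, dtype=bool)
            if mask.shape != values.shape:
                raise ValidationError("invalid_mask shape mismatch")
            object.__setattr__(self, "invalid_mask", mask)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds from session start."""
        return self.start_time_s + np.arange(self.n_frames) / self.sampling_rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.values[self.channel_names.index(name)]


@dataclass(frozen=True, order=True)
class LabelEvent:
    """Expert- or generator-provided timestamp of a concentration peak."""

    time_s: float
    state: str = "concentration"
    source: str = "expert"

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValidationError(f"negative event time {self.time_s}")
        if self.state not in LABEL_STATES:
            raise ValidationError(f"unknown label state {self.state!r}")
        if self.source not in LABEL_SOURCES:
            raise ValidationError(f"unknown label source {self.source!r}")


@dataclass
class ArtifactReport:
    """Per-channel bookkeeping of what artifact filtering changed."""

    n_frames_interpolated: dict[str, int] = field(default_factory=dict)
    n_frames_invalidated: dict[str, int] = field(default_factory=dict)
    invalid_spans: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total_interpolated(self) -> int:
        return sum(self.n_frames_interpolated.values())

    @property
    def total_invalidated(self) -> int:
        return sum(self.n_frames_invalidated.values())


# ---------------------------------------------------------------------------
# I/O


def read_recording(
    path,
    *,
    subject_id: str | None = None,
    session_id: str | None = None,
) -> Recording:
    """Read a recording from the canonical CSV dialect.

    The file has a header ``time_s,hr_bpm,br_bcpm,sc_us,st_c`` and one row
    per frame.  Leading ``#`` comment lines may carry metadata
    (``# subject=...``, ``# session=...``, ``# rate_hz=...``).  The sampling
    rate is taken from the metadata when present, otherwise inferred from
    the time column (which must be uniform to within a relative jitter of
    1e-3).
    """
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                pos = fh.tell()
                continue
            fh.seek(pos)
            break
        try:
            df = pd.read_csv(fh)
        except pd.errors.EmptyDataError:
            raise FormatError(f"{path}: empty recording file") from None

    required = ["time_s", *CHANNEL_COLUMNS.values()]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")

    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: time column is not strictly increasing")

    if "rate_hz" in meta:
        rate = float(meta["rate_hz"])
    elif len(t) > 1:
        dt = np.diff(t)
        mean_dt = dt.mean()
        if np.max(np.abs(dt - mean_dt)) > 1e-3 * mean_dt:
            raise FormatError(f"{path}: non-uniform time column, cannot infer rate")
        rate = 1.0 / mean_dt
    else:
        rate = 10.0

    values = np.stack([df[CHANNEL_COLUMNS[ch]].to_numpy(dtype=float) for ch in CHANNELS])
    return Recording(
        subject_id=subject_id or meta.get("subject", "unknown"),
        session_id=session_id or meta.get("session", "unknown"),
        values=values,
        channel_names=CHANNELS,
        sampling_rate_hz=rate,
        start_time_s=float(t[0]),
    )


def write_recording(rec: Recording, path, *, float_fmt: str = "%.6f") -> None:
    """Write a recording in the canonical CSV dialect (inverse of read)."""
    df = pd.DataFrame({"time_s": rec.times()})
    for ch in rec.channel_names:
        df[CHANNEL_COLUMNS[ch]] = rec.channel(ch)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject={rec.subject_id}\n")
        fh.write(f"# session={rec.session_id}\n")
        fh.write(f"# rate_hz={rec.sampling_rate_hz:g}\n")
        df.to_csv(fh, index=False, float_format=float_fmt)


def read_labels(path) -> list[LabelEvent]:
    """Read label events from CSV (``time_s,state,source``), sorted by time."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return []
    for col in ("time_s", "state", "source"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    events = [
        LabelEvent(time_s=float(row.time_s), state=str(row.state), source=str(row.source))
        for row in df.itertuples(index=False)
    ]
    return sorted(events, key=lambda e: e.time_s)


def write_labels(events: list[LabelEvent], path) -> None:
    df = pd.DataFrame(
        {
            "time_s": [e.time_s for e in events],
            "state": [e.state for e in events],
            "source": [e.source for e in events],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Artifact filtering


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean vector."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def filter_artifacts(
    rec: Recording,
    rules: dict[str, tuple[float, float]] | None = None,
    *,
    max_gap_s: float = 1.0,
) -> tuple[Recording, ArtifactReport]:
    """Repair or invalidate out-of-range sensor frames.

    ``rules`` maps channel names to inclusive ``(low, high)`` validity
    ranges; channels absent from the mapping are unconstrained.  Defaults
    encode the loss-of-contact and implausible-heart-rate rules:
    SC > 0 and 25 <= HR <= 240 BPM.

    Invalid runs no longer than ``max_gap_s`` are linearly interpolated
    between the nearest valid neighbours (held constant at recording
    edges); longer runs are left in place but marked in the returned
    recording's ``invalid_mask`` and listed in the report, so that
    windowing can reject them.  Valid frames are preserved bit-exactly and
    the operation is idempotent.
    """
    if rules is None:
        rules = DEFAULT_ARTIFACT_RULES
    max_gap_frames = int(round(max_gap_s * rec.sampling_rate_hz))

    values = rec.values.copy()
    invalid_mask = np.zeros_like(values, dtype=bool)
    if rec.invalid_mask is not None:
        invalid_mask |= rec.invalid_mask
    report = ArtifactReport()

    for ci, ch in enumerate(rec.channel_names):
        report.n_frames_interpolated.setdefault(ch, 0)
        report.n_frames_invalidated.setdefault(ch, 0)
        if ch not in rules:
            continue
        low, high = rules[ch]
        x = values[ci]
        bad = (x < low) | (x > high) | ~np.isfinite(x)
        bad |= invalid_mask[ci]
        if bad.all():
            raise ValidationError(f"channel {ch} is entirely invalid")
        for start, stop in _runs(bad):
            n = stop - start
            if n <= max_gap_frames:
                left = start - 1
                right = stop
                if left < 0 and right >= len(x):  # unreachable: bad.all() checked
                    raise ValidationError(f"channel {ch} is entirely invalid")
                if left < 0:
                    x[start:stop] = x[right]
                elif right >= len(x):
                    x[start:stop] = x[left]
                else:
                    x[start:stop] = np.interp(
                        np.arange(start, stop), [left, right], [x[left], x[right]]
                    )
                invalid_mask[ci, start:stop] = False
                report.n_frames_interpolated[ch] += n
            else:
                invalid_mask[ci, start:stop] = True
                report.n_frames_invalidated[ch] += n
                report.invalid_spans.append((ch, int(start), int(stop)))

    filtered = replace(rec, values=values, invalid_mask=invalid_mask)
    if report.total_interpolated or report.total_invalidated:
        logger.info(
            "artifact filtering %s/%s: %d frames interpolated, %d invalidated",
            rec.subject_id,
            rec.session_id,
            report.total_interpolated,
            report.total_invalidated,
        )
    return filtered, report
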