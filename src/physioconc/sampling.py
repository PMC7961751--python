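"""Extraction of concentrated (S+) and non-concentrated (S-) samples.

Each sample is a fixed-length multichannel window: 6 s at 10 Hz, i.e. a
``channels x 60`` matrix.  Positives are windows spanning the 3 s before
and after an expert-labelled concentration peak.  Negatives are 6 s slots
chosen greedily left-to-right after discarding the first second of the
session, keeping every point of every slot at least two minutes away from
every concentration peak and at least 6 s away from the previous slot.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .signal_model import LabelEvent, Recording, ValidationError

logger = logging.getLogger(__name__)

CONCENTRATED = "concentrated"
NON_CONCENTRATED = "non_concentrated"


@dataclass(frozen=True)
class Sample:
    """One fixed-length labelled signal window.

    ``matrix`` has shape ``(n_channels, n_frames)``; ``origin_time_s`` is
    the peak time for positives and the slot start time for negatives.
    """

    subject_id: str
    matrix: np.ndarray
    channel_names: tuple[str, ...]
    klass: str
    origin_time_s: float
    session_id: str = ""

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        if matrix.ndim != 2 or matrix.shape[0] != len(self.channel_names):
            raise ValidationError("matrix rows must match channel_names")
        if self.klass not in (CONCENTRATED, NON_CONCENTRATED):
            raise ValidationError(f"unknown sample class {self.klass!r}")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


def _window_valid(rec: Recording, start: int, stop: int) -> bool:
    if start < 0 or stop > rec.n_frames:
        return False
    if rec.invalid_mask is not None and rec.invalid_mask[:, start:stop].any():
        return False
    return True


def extract_positive_samples(
    rec: Recording,
    events: list[LabelEvent],
    *,
    half_window_s: float = 3.0,
) -> list[Sample]:
    """Cut one window per concentration peak: frames in ``[t-3 s, t+3 s)``.

    The peak time is snapped to the nearest frame index, giving exactly 60
    frames per channel at the defaults (6 s window, 10 Hz).  Events whose
    window runs out of the recording or touches an invalidated artifact
    span are skipped and logged.
    """
    rate = rec.sampling_rate_hz
    half = int(round(half_window_s * rate))
    samples = []
    for ev in events:
        if ev.state != "concentration":
            continue
        center = int(round((ev.time_s - rec.start_time_s) * rate))
        start, stop = center - half, center + half
        if not _window_valid(rec, start, stop):
            logger.info(
                "skipping event at %.2f s (%s/%s): window out of bounds or invalid",
                ev.time_s,
                rec.subject_id,
                rec.session_id,
            )
            continue
        samples.append(
            Sample(
                subject_id=rec.subject_id,
                session_id=rec.session_id,
                matrix=rec.values[:, start:stop].copy(),
                channel_names=tuple(rec.channel_names),
                klass=CONCENTRATED,
                origin_time_s=ev.time_s,
            )
        )
    return samples


def negative_slot_starts(
    n_frames: int,
    rate: float,
    peak_frames: list[int],
    *,
    slot_frames: int,
    peak_gap_frames: int,
    slot_gap_frames: int,
    head_frames: int,
    is_free,
) -> list[int]:
    """Greedy left-to-right packing of negative slots, in frame units.

    A start frame ``a`` is feasible when the slot ``[a, a+slot_frames)``
    lies in bounds, starts at or after ``head_frames``, every frame of it
    is at least ``peak_gap_frames`` from every peak frame, and
    ``is_free(a, a + slot_frames)`` holds (artifact check).  Selected
    slots are separated by at least ``slot_gap_frames``.
    """

    def feasible(a: int) -> bool:
        if a < head_frames or a + slot_frames > n_frames:
            return False
        for pf in peak_frames:
            # nearest-point distance: every frame of the slot >= gap away
            if not (a >= pf + peak_gap_frames or a + slot_frames - 1 <= pf - peak_gap_frames):
                return False
        return is_free(a, a + slot_frames)

    starts: list[int] = []
    a = head_frames
    while a + slot_frames <= n_frames:
        if feasible(a):
            starts.append(a)
            a += slot_frames + slot_gap_frames
        else:
            a += 1
    return starts


def extract_negative_samples(
    rec: Recording,
    events: list[LabelEvent],
    *,
    slot_s: float = 6.0,
    peak_gap_s: float = 120.0,
    slot_gap_s: float = 6.0,
    discard_head_s: float = 1.0,
    exclude_all_labels: bool = False,
) -> list[Sample]:
    """Greedily pack non-concentrated slots into the eligible regions.

    By default only concentration peaks carve out the +/- 2 min exclusion
    zone; set ``exclude_all_labels`` to exclude around every label event.
    """
    rate = rec.sampling_rate_hz
    peaks = [
        ev for ev in events if exclude_all_labels or ev.state == "concentration"
    ]
    peak_frames = [int(round((ev.time_s - rec.start_time_s) * rate)) for ev in peaks]

    starts = negative_slot_starts(
        rec.n_frames,
        rate,
        peak_frames,
        slot_frames=int(round(slot_s * rate)),
        peak_gap_frames=int(round(peak_gap_s * rate)),
        slot_gap_frames=int(round(slot_gap_s * rate)),
        head_frames=int(round(discard_head_s * rate)),
        is_free=lambda a, b: _window_valid(rec, a, b),
    )
    slot_frames = int(round(slot_s * rate))
    return [
        Sample(
            subject_id=rec.subject_id,
            session_id=rec.session_id,
            matrix=rec.values[:, a : a + slot_frames].copy(),
            channel_names=tuple(rec.channel_names),
            klass=NON_CONCENTRATED,
            origin_time_s=rec.start_time_s + a / rate,
        )
        for a in starts
    ]


def project_channels(sample: Sample, subset: tuple[str, ...] | list[str]) -> Sample:
    """Restrict a sample to an ordered channel subset (fusion projection)."""
    subset = tuple(subset)
    if not subset:
        raise ValidationError("channel subset must be nonempty")
    unknown = set(subset) - set(sample.channel_names)
    if unknown:
        raise ValidationError(f"unknown channels: {sorted(unknown)}")
    rows = [sample.channel_names.index(ch) for ch in subset]
    return replace(sample, matrix=sample.matrix[rows], channel_names=subset)


# ---------------------------------------------------------------------------
# Serialisation


def write_samples(samples: list[Sample], outdir) -> str:
    """Write samples as per-sample CSV matrices plus a manifest CSV."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        fname = f"sample_{i:05d}.csv"
        pd.DataFrame(s.matrix.T, columns=list(s.channel_names)).to_csv(
            os.path.join(outdir, fname), index=False
        )
        rows.append(
            {
                "subject_id": s.subject_id,
                "session_id": s.session_id,
                "klass": s.klass,
                "origin_time_s": s.origin_time_s,
                "channels": "|".join(s.channel_names),
                "path": fname,
            }
        )
    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_samples(manifest_path) -> list[Sample]:
    base = os.path.dirname(manifest_path)
    manifest = pd.read_csv(manifest_path)
    samples = []
    for row in manifest.itertuples(index=False):
        mat = pd.read_csv(os.path.join(base, row.path)).to_numpy().T
        samples.append(
            Sample(
                subject_id=str(row.subject_id),
                session_id="" if pd.isna(row.session_id) else str(row.session_id),
                matrix=mat,
                channel_names=tuple(str(row.channels).split("|")),
                klass=str(row.klass),
                origin_time_s=float(row.origin_time_s),
            )
        )
    return samples
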