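"""Synthetic labelled physiological sessions for end-to-end testing.

The generator emulates the statistical structure the detection pipeline
relies on, without claiming biophysical realism:

* subject-specific channel baselines (between-subject spread scaled by
  ``subject_scale``),
* slow autocorrelated noise — an AR(1) process per channel (coefficient
  0.95 at 10 Hz by default, emulating physiological drift),
* a deterministic event-locked deflection at each concentration peak —
  a raised cosine of per-channel amplitude ``concentration_delta`` and
  half-width ``ramp_s``, scaled by ``state_scale``.

Each session follows the study protocol: 9 minutes at 10 Hz, with a
2-minute rest block, a 5-minute activity block in which all concentration
events fall, and a closing 2-minute rest block.  Events are clustered
inside the activity block so that the two rest blocks stay more than two
minutes away from every peak and remain eligible for negative slots.

Channel anchors (HR 70 BPM, BR 15 BCPM, SC 5 uS, ST 33 degC) are
conventional resting physiology, as are the default event deflections
(HR +5 BPM, BR +2 BCPM, SC +0.8 uS, ST -0.5 degC: sympathetic arousal
raises heart and breath rate and sweat-gland activity and causes
peripheral vasoconstriction, cooling the skin).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .signal_model import (
    CHANNELS,
    LabelEvent,
    Recording,
    ValidationError,
    read_labels,
    read_recording,
    write_labels,
    write_recording,
)

#: (baseline anchor, between-subject sd at subject_scale=1) per channel
BASELINE_ANCHORS = {
    "HR": (70.0, 8.0),
    "BR": (15.0, 2.0),
    "SC": (5.0, 1.5),
    "ST": (33.0, 0.8),
}

#: AR(1) innovation standard deviation per channel (units of the channel)
NOISE_SD = {"HR": 0.8, "BR": 0.5, "SC": 0.08, "ST": 0.02}

#: Event-locked deflection at state_scale=1 (units of the channel)
DELTA_ANCHORS = {"HR": 5.0, "BR": 2.0, "SC": 0.8, "ST": -0.5}

AR_COEFF_DEFAULT = 0.95

#: Event-locked steadying of the signals: at a concentration peak the AR(1)
#: innovation sd is multiplied by exp(-NOISE_ATTENUATION * state_scale).
#: Concentration is accompanied by reduced moment-to-moment variability
#: (e.g. suppressed heart-rate variability, stiller posture), and this
#: second-order effect is what a one-class model trained on concentrated
#: windows keys on: a pure mean shift leaves flat windows inside the span
#: of the trained trajectory and hence indistinguishable by likelihood.
NOISE_ATTENUATION = 0.7


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    baseline: dict[str, float]
    ar_coeff: dict[str, float]
    noise_sd: dict[str, float]
    concentration_delta: dict[str, float]
    ramp_s: float = 4.5

    def __post_init__(self) -> None:
        if self.ramp_s <= 0:
            raise ValidationError("ramp_s must be positive")
        for ch in CHANNELS:
            if not 0 <= self.ar_coeff[ch] < 1:
                raise ValidationError("ar_coeff must lie in [0, 1)")
            if self.noise_sd[ch] <= 0:
                raise ValidationError("noise_sd must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Study-shaped cohort: 4 subjects x 4 sessions of 9 minutes at 10 Hz."""

    n_subjects: int = 4
    sessions_per_subject: int = 4
    session_s: float = 540.0
    sampling_rate_hz: float = 10.0
    events_per_session: tuple[int, int] = (2, 7)   # inclusive range
    rest_block_s: float = 120.0                    # opening/closing rest
    event_cluster_s: float = 120.0                 # events fall in this mid-activity span
    subject_scale: float = 1.0
    state_scale: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.session_s <= 0:
            raise ValidationError("session_s must be positive")
        if self.subject_scale < 0 or self.state_scale < 0:
            raise ValidationError("scales must be >= 0")
        lo, hi = self.events_per_session
        if not 0 <= lo <= hi:
            raise ValidationError("events_per_session must be a nonempty range")


@dataclass
class Cohort:
    """Generated recordings and label events, grouped by subject."""

    spec: CohortSpec
    profiles: dict[str, SubjectProfile]
    sessions: dict[str, list[tuple[Recording, list[LabelEvent]]]] = field(
        default_factory=dict
    )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.profiles)


def make_profile(rng: np.random.Generator, spec: CohortSpec, subject_id: str) -> SubjectProfile:
    """Draw one subject's baselines, noise law and event-locked response.

    With ``subject_scale = 0`` every subject gets the identical profile;
    with ``state_scale = 0`` the concentration deflection vanishes.
    Subject individuality enters both the baselines and the *shape* of the
    deflection (per-channel multiplicative jitter), mirroring the finding
    that how concentration manifests is itself subject-specific.
    """
    baseline = {}
    ar_coeff = {}
    noise_sd = {}
    delta = {}
    floors = {"HR": 40.0, "BR": 6.0, "ST": 28.0}
    for ch in CHANNELS:
        anchor, spread = BASELINE_ANCHORS[ch]
        if ch == "SC":
            # skin conductance is positive and right-skewed across people
            baseline[ch] = anchor * np.exp(
                spec.subject_scale * (spread / anchor) * rng.standard_normal()
            )
        else:
            baseline[ch] = max(
                floors[ch],
                anchor + spec.subject_scale * spread * rng.standard_normal(),
            )
        ar_coeff[ch] = AR_COEFF_DEFAULT
        noise_sd[ch] = NOISE_SD[ch]
        shape = 1.0 + 0.4 * spec.subject_scale * rng.standard_normal()
        delta[ch] = spec.state_scale * DELTA_ANCHORS[ch] * shape
    return SubjectProfile(
        subject_id=subject_id,
        baseline=baseline,
        ar_coeff=ar_coeff,
        noise_sd=noise_sd,
        concentration_delta=delta,
    )


def _raised_cosine(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Smooth compactly supported bump: 1 at center, 0 outside +/- half_width.

    Integrates to ``half_width`` (so the deflection area is
    ``delta * ramp_s``).
    """
    u = (t - center) / half_width
    out = np.zeros_like(t)
    inside = np.abs(u) < 1
    out[inside] = 0.5 * (1 + np.cos(np.pi * u[inside]))
    return out


def _place_events(
    rng: np.random.Generator, spec: CohortSpec, profile: SubjectProfile
) -> np.ndarray:
    """Cluster event times mid-activity with >= 2 * ramp_s spacing."""
    n = int(rng.integers(spec.events_per_session[0], spec.events_per_session[1] + 1))
    if n == 0:
        return np.array([])
    mid = spec.session_s / 2
    lo = mid - spec.event_cluster_s / 2
    hi = mid + spec.event_cluster_s / 2
    gap = 2 * profile.ramp_s
    slack = (hi - lo) - (n - 1) * gap
    if slack < 0:
        raise ValidationError(
            f"cannot place {n} events with {gap:g} s spacing in {hi - lo:g} s"
        )
    offsets = np.sort(rng.uniform(0, slack, size=n))
    times = lo + offsets + gap * np.arange(n)
    # snap to the frame grid so peak times are exactly representable
    return np.round(times * spec.sampling_rate_hz) / spec.sampling_rate_hz


def simulate_session(
    profile: SubjectProfile,
    spec: CohortSpec,
    rng: np.random.Generator,
    session_id: str = "s1",
) -> tuple[Recording, list[LabelEvent]]:
    """One session: baseline + AR(1) noise + event-locked deflections."""
    rate = spec.sampling_rate_hz
    n = int(round(spec.session_s * rate))
    t = np.arange(n) / rate
    events = _place_events(rng, spec, profile)

    # event-locked envelope in [0, 1]: how "in concentration" each frame is
    envelope = np.zeros(n)
    for ev in events:
        envelope = np.maximum(envelope, _raised_cosine(t, ev, profile.ramp_s))
    steadying = np.exp(-NOISE_ATTENUATION * spec.state_scale * envelope)

    values = np.empty((len(CHANNELS), n))
    for ci, ch in enumerate(CHANNELS):
        phi = profile.ar_coeff[ch]
        sd = profile.noise_sd[ch]
        innov = rng.normal(0.0, sd, size=n) * steadying
        noise = np.empty(n)
        # start at the stationary distribution so the head is not transient
        noise[0] = rng.normal(0.0, sd / np.sqrt(1 - phi**2)) if phi > 0 else innov[0]
        for k in range(1, n):
            noise[k] = phi * noise[k - 1] + innov[k]
        x = profile.baseline[ch] + noise
        x = x + profile.concentration_delta[ch] * envelope if len(events) else x
        values[ci] = x

    rec = Recording(
        subject_id=profile.subject_id,
        session_id=session_id,
        values=values,
        channel_names=CHANNELS,
        sampling_rate_hz=rate,
    )
    labels = [LabelEvent(time_s=float(ev), source="synthetic") for ev in events]
    return rec, labels


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort, reproducible from ``spec.master_seed``."""
    root = np.random.SeedSequence(spec.master_seed)
    subject_seeds = root.spawn(spec.n_subjects)
    cohort = Cohort(spec=spec, profiles={})
    for si, sseq in enumerate(subject_seeds):
        subject_id = f"subject{si + 1}"
        streams = sseq.spawn(spec.sessions_per_subject + 1)
        profile = make_profile(np.random.default_rng(streams[0]), spec, subject_id)
        cohort.profiles[subject_id] = profile
        cohort.sessions[subject_id] = [
            simulate_session(
                profile,
                spec,
                np.random.default_rng(streams[k + 1]),
                session_id=f"session{k + 1}",
            )
            for k in range(spec.sessions_per_subject)
        ]
    return cohort


def write_cohort(cohort: Cohort, outdir) -> str:
    """Write recordings/labels as CSV plus a manifest JSON; returns manifest path."""
    os.makedirs(outdir, exist_ok=True)
    entries = []
    for subject_id, sessions in cohort.sessions.items():
        for rec, labels in sessions:
            rec_path = f"{subject_id}_{rec.session_id}.csv"
            lab_path = f"{subject_id}_{rec.session_id}_labels.csv"
            write_recording(rec, os.path.join(outdir, rec_path))
            write_labels(labels, os.path.join(outdir, lab_path))
            entries.append(
                {
                    "subject_id": subject_id,
                    "session_id": rec.session_id,
                    "recording": rec_path,
                    "labels": lab_path,
                }
            )
    manifest = {
        "spec": asdict(cohort.spec),
        "profiles": {sid: asdict(p) for sid, p in cohort.profiles.items()},
        "sessions": entries,
    }
    manifest_path = os.path.join(outdir, "cohort.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path


def read_cohort_dir(path) -> dict[str, list[tuple[Recording, list[LabelEvent]]]]:
    """Load a cohort directory written by :func:`write_cohort`.

    Returns the subject -> [(recording, labels), ...] mapping expected by
    :func:`physioconc.evaluation.build_dataset`.
    """
    manifest_path = os.path.join(path, "cohort.json")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    sessions: dict[str, list[tuple[Recording, list[LabelEvent]]]] = {}
    for entry in manifest["sessions"]:
        rec = read_recording(os.path.join(path, entry["recording"]))
        labels = read_labels(os.path.join(path, entry["labels"]))
        sessions.setdefault(entry["subject_id"], []).append((rec, labels))
    return sessions
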