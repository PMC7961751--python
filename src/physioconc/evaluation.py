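"""Iterated hold-out evaluation, pooled ROC/AUC/EER, and the experiments.

Three experiment designs probe subject dependency of the concentration
signal, each repeated per subject u_i:

* ``intra_detection`` — can u_i's own concentrated windows train a model
  that separates their concentrated from non-concentrated windows?
  S+ = u_i's concentrated samples, S- = u_i's non-concentrated samples.
* ``subject_id`` — does concentration manifest subject-specifically?
  S+ = u_i's concentrated samples, S- = everyone else's concentrated
  samples.
* ``inter_subject`` — does a model trained on *other* subjects transfer?
  One single fit (no iteration loop); the default direction trains on the
  pooled concentrated samples of U - {u_i} and tests on u_i's positives
  and negatives; a flag selects the reverse direction (train on u_i, test
  on everyone else).

The first two use an iterated 75/25 hold-out over S+ (12,500 iterations
by default): each iteration fits a fresh one-class HMM on the training
positives and scores the held-out positives plus ALL of S-; the scores of
every iteration are pooled into a single ROC curve.  Pooling raw
log-likelihoods is sound here because all windows share one length (60
frames), so scores live on a common scale.

AUC is computed by midrank pair counting (ties count 1/2), which equals
the trapezoidal area under the tie-grouped ROC polygon; EER is read off
the polygon by linear interpolation where FPR = FNR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import hmm
from .hmm import InsufficientDataError, Standardizer
from .sampling import Sample, project_channels
from .signal_model import CHANNELS, ValidationError

DEFAULT_N_ITERATIONS = 12_500
DEFAULT_TRAIN_FRACTION = 0.75

EXPERIMENTS = ("intra_detection", "subject_id", "inter_subject")


@dataclass(frozen=True)
class ScoredSample:
    sample_ref: str
    score: float
    truth: bool
    iteration: int = 0


@dataclass(frozen=True)
class ROCResult:
    """Pooled ROC curve with the two accuracy indicators, AUC and EER."""

    points: np.ndarray          # (n_points, 2) of (FPR, TPR)
    auc: float
    eer: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ExperimentConfig:
    n_iterations: int = DEFAULT_N_ITERATIONS
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    seed: int = 0
    channel_subset: tuple[str, ...] | None = None
    experiment: str = "intra_detection"
    n_states: int = hmm.DEFAULT_N_STATES
    max_iter: int = 50
    tol: float = 1e-3
    standardize: bool = True
    pool_scores: bool = True
    inter_direction: str = "train_others"   # or "train_target"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.experiment not in EXPERIMENTS:
            raise ValidationError(f"unknown experiment {self.experiment!r}")


@dataclass
class SubjectSamples:
    """One subject's S+ / S- pools."""

    positives: list[Sample] = field(default_factory=list)
    negatives: list[Sample] = field(default_factory=list)


Dataset = Mapping[str, SubjectSamples]


def build_dataset(
    sessions: Mapping[str, list], *, filter_kwargs: dict | None = None
) -> dict[str, SubjectSamples]:
    """Artifact-filter and window a mapping subject -> [(recording, labels)]."""
    from .sampling import extract_negative_samples, extract_positive_samples
    from .signal_model import filter_artifacts

    dataset: dict[str, SubjectSamples] = {}
    for subject_id, recs in sessions.items():
        ss = SubjectSamples()
        for rec, labels in recs:
            filtered, _ = filter_artifacts(rec, **(filter_kwargs or {}))
            ss.positives.extend(extract_positive_samples(filtered, labels))
            ss.negatives.extend(extract_negative_samples(filtered, labels))
        dataset[subject_id] = ss
    return dataset


# ---------------------------------------------------------------------------
# ROC / AUC / EER


def roc(scored: list[ScoredSample]) -> ROCResult:
    """Pooled ROC over all scored samples; higher score => predicted positive.

    Thresholds are placed at every distinct score, so tied scores produce
    diagonal ROC segments; with that convention the trapezoidal area under
    the polygon equals the midrank (Mann-Whitney) statistic exactly.
    """
    scores = np.array([s.score for s in scored], dtype=float)
    truth = np.array([s.truth for s in scored], dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("non-finite scores")

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    t_sorted = truth[order]
    # group ties: one ROC vertex after each block of equal scores
    boundaries = np.flatnonzero(np.diff(s_sorted)) + 1
    cum_tp = np.cumsum(t_sorted)
    cum_fp = np.cumsum(~t_sorted)
    idx = np.concatenate([boundaries - 1, [len(scores) - 1]])
    tpr = np.concatenate([[0.0], cum_tp[idx] / n_pos])
    fpr = np.concatenate([[0.0], cum_fp[idx] / n_neg])
    points = np.column_stack([fpr, tpr])

    ranks = rankdata(scores)  # midranks
    auc = (ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return ROCResult(
        points=points, auc=float(auc), eer=_eer(points), n_pos=n_pos, n_neg=n_neg
    )


def _eer(points: np.ndarray) -> float:
    """Equal error rate: FPR at the polygon's crossing of FPR = 1 - TPR."""
    g = points[:, 0] + points[:, 1] - 1.0   # monotone non-decreasing along curve
    for i in range(len(points) - 1):
        if g[i] <= 0.0 <= g[i + 1]:
            dx = points[i + 1, 0] - points[i, 0]
            dy = points[i + 1, 1] - points[i, 1]
            if dx + dy == 0.0:
                continue
            t = -g[i] / (dx + dy)
            return float(points[i, 0] + t * dx)
    # curve starts at (0,0) and ends at (1,1), so a crossing always exists
    raise AssertionError("no EER crossing found on ROC polygon")


def iteration_averaged_roc(scored: list[ScoredSample]) -> ROCResult:
    """Sensitivity-analysis mode: one ROC per hold-out iteration, AUC/EER
    averaged across iterations (the curve and counts reported are pooled).
    """
    pooled = roc(scored)
    by_iter: dict[int, list[ScoredSample]] = {}
    for s in scored:
        by_iter.setdefault(s.iteration, []).append(s)
    per = [roc(group) for group in by_iter.values()]
    return ROCResult(
        points=pooled.points,
        auc=float(np.mean([r.auc for r in per])),
        eer=float(np.mean([r.eer for r in per])),
        n_pos=pooled.n_pos,
        n_neg=pooled.n_neg,
    )


def trapezoid_auc(points: np.ndarray) -> float:
    """Area under the ROC polygon (cross-check against the midrank AUC)."""
    return float(np.trapezoid(points[:, 1], points[:, 0]))


# ---------------------------------------------------------------------------
# iterated hold-out


def _matrices(samples: list[Sample], subset: tuple[str, ...] | None) -> list[np.ndarray]:
    if subset is not None:
        samples = [project_channels(s, subset) for s in samples]
    return [s.matrix for s in samples]


def _fit_and_score(
    train: list[np.ndarray],
    test_groups: list[list[np.ndarray]],
    cfg: ExperimentConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Standardise on the training set, fit, and score each test group."""
    if cfg.standardize:
        scaler = Standardizer().fit(train)
        train = [scaler.transform(m) for m in train]
        test_groups = [[scaler.transform(m) for m in g] for g in test_groups]
    params, _ = hmm.fit(
        train, n_states=cfg.n_states, seed=rng, max_iter=cfg.max_iter, tol=cfg.tol
    )
    return [
        hmm.loglik_batch(params, g) if g else np.array([]) for g in test_groups
    ]


def run_iterated(
    s_plus: list[Sample],
    s_minus: list[Sample],
    cfg: ExperimentConfig,
) -> list[ScoredSample]:
    """The iterated 75/25 hold-out over S+ with per-iteration scoring of S-.

    Each iteration draws a seeded random split with ``floor(train_fraction
    * |S+|)`` (at least 2) training positives, fits a one-class HMM on
    them, and scores the held-out positives (truth=True) together with all
    of S- (truth=False).  Scores from all iterations are pooled.
    Substreams derive deterministically from ``(cfg.seed, iteration)``, so
    a fixed master seed reproduces every split and fit bit-for-bit.
    """
    n = len(s_plus)
    if n < 4:
        who = s_plus[0].subject_id if s_plus else "<empty>"
        raise InsufficientDataError(
            f"subject {who}: need >= 4 positive samples for the 75/25 scheme, got {n}"
        )
    pos = _matrices(s_plus, cfg.channel_subset)
    neg = _matrices(s_minus, cfg.channel_subset)
    n_train = max(2, int(np.floor(cfg.train_fraction * n)))
    n_train = min(n_train, n - 1)

    out: list[ScoredSample] = []
    for it in range(cfg.n_iterations):
        rng = np.random.default_rng([cfg.seed, it])
        perm = rng.permutation(n)
        train = [pos[j] for j in perm[:n_train]]
        held = perm[n_train:]
        (pos_scores, neg_scores) = _fit_and_score(
            train, [[pos[j] for j in held], neg], cfg, rng
        )
        out.extend(
            ScoredSample(f"pos{j}", float(sc), True, it)
            for j, sc in zip(held, pos_scores)
        )
        out.extend(
            ScoredSample(f"neg{j}", float(sc), False, it)
            for j, sc in enumerate(neg_scores)
        )
    return out


# ---------------------------------------------------------------------------
# the three experiments


def _check_subject(dataset: Dataset, subject: str) -> None:
    if subject not in dataset:
        raise ValidationError(f"unknown subject {subject!r}")


def experiment_intra_detection(
    dataset: Dataset, subject: str, cfg: ExperimentConfig
) -> ROCResult:
    """Within-subject concentration detection (criterion: is concentrated)."""
    _check_subject(dataset, subject)
    ss = dataset[subject]
    if not ss.negatives:
        raise InsufficientDataError(f"subject {subject}: no non-concentrated samples")
    scored = run_iterated(ss.positives, ss.negatives, cfg)
    return roc(scored) if cfg.pool_scores else iteration_averaged_roc(scored)


def experiment_subject_id(
    dataset: Dataset, subject: str, cfg: ExperimentConfig
) -> ROCResult:
    """Subject identification from concentrated samples (criterion: is u_i)."""
    _check_subject(dataset, subject)
    if len(dataset) < 2:
        raise InsufficientDataError("subject identification needs >= 2 subjects")
    s_plus = dataset[subject].positives
    s_minus = [s for sid, ss in dataset.items() if sid != subject for s in ss.positives]
    if not s_minus:
        raise InsufficientDataError("no concentrated samples from other subjects")
    scored = run_iterated(s_plus, s_minus, cfg)
    return roc(scored) if cfg.pool_scores else iteration_averaged_roc(scored)


def experiment_inter_subject(
    dataset: Dataset, subject: str, cfg: ExperimentConfig
) -> ROCResult:
    """Cross-subject transfer: a single fit, no iteration loop.

    Default direction (``train_others``): fit on the pooled concentrated
    samples of all other subjects, score u_i's positives and negatives.
    ``train_target``: fit on all of u_i's concentrated samples, score the
    other subjects' positives and negatives.
    """
    _check_subject(dataset, subject)
    if len(dataset) < 2:
        raise InsufficientDataError("inter-subject experiment needs >= 2 subjects")
    others = [sid for sid in dataset if sid != subject]
    if cfg.inter_direction == "train_others":
        train_samples = [s for sid in others for s in dataset[sid].positives]
        test_pos = dataset[subject].positives
        test_neg = dataset[subject].negatives
    elif cfg.inter_direction == "train_target":
        train_samples = list(dataset[subject].positives)
        test_pos = [s for sid in others for s in dataset[sid].positives]
        test_neg = [s for sid in others for s in dataset[sid].negatives]
    else:
        raise ValidationError(f"unknown inter_direction {cfg.inter_direction!r}")
    if len(train_samples) < 2:
        raise InsufficientDataError("inter-subject experiment: too few training samples")
    if not test_pos or not test_neg:
        raise InsufficientDataError("inter-subject experiment: empty test class")

    train = _matrices(train_samples, cfg.channel_subset)
    rng = np.random.default_rng([cfg.seed, 0])
    pos_scores, neg_scores = _fit_and_score(
        train,
        [_matrices(test_pos, cfg.channel_subset), _matrices(test_neg, cfg.channel_subset)],
        cfg,
        rng,
    )
    scored = [
        ScoredSample(f"pos{j}", float(sc), True, 0) for j, sc in enumerate(pos_scores)
    ] + [
        ScoredSample(f"neg{j}", float(sc), False, 0) for j, sc in enumerate(neg_scores)
    ]
    return roc(scored)


_EXPERIMENT_FNS = {
    "intra_detection": experiment_intra_detection,
    "subject_id": experiment_subject_id,
    "inter_subject": experiment_inter_subject,
}


def run_experiment(
    dataset: Dataset, subject: str, cfg: ExperimentConfig
) -> ROCResult:
    return _EXPERIMENT_FNS[cfg.experiment](dataset, subject, cfg)


# ---------------------------------------------------------------------------
# fusion sweep


def channel_subsets(channels: tuple[str, ...] = CHANNELS) -> list[tuple[str, ...]]:
    """All 2^M - 1 nonempty subsets, by size then canonical channel order."""
    subsets = []
    for k in range(1, len(channels) + 1):
        subsets.extend(itertools.combinations(channels, k))
    return subsets


def fusion_sweep(
    dataset: Dataset,
    experiment: str,
    cfg: ExperimentConfig,
    channels: tuple[str, ...] = CHANNELS,
) -> pd.DataFrame:
    """Re-run an intra-subject experiment over every nonempty channel subset.

    Returns one row per subset with per-subject AUC/EER plus averages.
    The transfer (inter-subject) experiment is not part of the sweep.
    """
    if experiment == "inter_subject":
        raise ValidationError("fusion sweep supports only the intra-subject experiments")
    if experiment not in _EXPERIMENT_FNS:
        raise ValidationError(f"unknown experiment {experiment!r}")
    if not channels:
        raise ValidationError("need at least one channel")
    subjects = list(dataset)
    rows = []
    for subset in channel_subsets(channels):
        sub_cfg = replace(cfg, channel_subset=subset, experiment=experiment)
        row: dict[str, float | int] = {ch: int(ch in subset) for ch in channels}
        aucs, eers = [], []
        for subject in subjects:
            res = _EXPERIMENT_FNS[experiment](dataset, subject, sub_cfg)
            row[f"{subject}_auc"] = res.auc
            row[f"{subject}_eer"] = res.eer
            aucs.append(res.auc)
            eers.append(res.eer)
        row["avg_auc"] = float(np.mean(aucs))
        row["avg_eer"] = float(np.mean(eers))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def experiment_table(results: Mapping[str, ROCResult]) -> pd.DataFrame:
    """Per-subject AUC/EER with a closing Average row."""
    if not results:
        raise ValidationError("empty results")
    rows = [
        {"subject": sid, "auc": r.auc, "eer": r.eer} for sid, r in results.items()
    ]
    rows.append(
        {
            "subject": "Average",
            "auc": float(np.mean([r.auc for r in results.values()])),
            "eer": float(np.mean([r.eer for r in results.values()])),
        }
    )
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path) -> None:
    """2-decimal CSV plus a full-precision companion (``*_full.csv``)."""
    path = str(path)
    df.round(2).to_csv(path, index=False)
    stem, dot, ext = path.rpartition(".")
    df.to_csv(f"{stem}_full.{ext}" if dot else f"{path}_full", index=False)
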