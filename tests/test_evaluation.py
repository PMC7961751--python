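import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from physioconc import (
    ExperimentConfig,
    InsufficientDataError,
    ScoredSample,
    SubjectSamples,
    ValidationError,
    channel_subsets,
    experiment_inter_subject,
    experiment_intra_detection,
    experiment_subject_id,
    experiment_table,
    fusion_sweep,
    roc,
    run_iterated,
)
from physioconc.evaluation import trapezoid_auc, write_report

from _oracles import pair_count_auc


def scored(pos, neg):
    return [ScoredSample(f"p{i}", s, True) for i, s in enumerate(pos)] + [
        ScoredSample(f"n{i}", s, False) for i, s in enumerate(neg)
    ]


# ---------------------------------------------------------------------------
# ROC / AUC / EER


def test_perfect_separation():
    r = roc(scored([2.0, 3.0], [0.0, 1.0]))
    assert r.auc == 1.0
    assert r.eer == 0.0
    assert r.n_pos == 2 and r.n_neg == 2


def test_all_tied_scores():
    r = roc(scored([1.0, 1.0], [1.0, 1.0, 1.0]))
    assert r.auc == 0.5
    assert r.eer == 0.5


def test_pair_counting_example():
    r = roc(scored([0.9, 0.4], [0.5, 0.1]))
    assert r.auc == pytest.approx(0.75)


def test_roc_polygon_shape():
    r = roc(scored([0.9, 0.4, 0.4], [0.5, 0.4, 0.1]))
    assert tuple(r.points[0]) == (0.0, 0.0)
    assert tuple(r.points[-1]) == (1.0, 1.0)
    assert np.all(np.diff(r.points[:, 0]) >= 0)
    assert np.all(np.diff(r.points[:, 1]) >= 0)


@pytest.mark.parametrize("seed", range(25))
def test_auc_equals_pair_counting_and_trapezoid(seed):
    """Midrank AUC == exhaustive pair counting exactly; trapezoid within 1e-12."""
    rng = np.random.default_rng(seed)
    n_pos = int(rng.integers(1, 100))
    n_neg = int(rng.integers(1, 100))
    # coarse grid forces plenty of ties
    pos = rng.integers(0, 8, size=n_pos).astype(float)
    neg = rng.integers(0, 8, size=n_neg).astype(float)
    r = roc(scored(pos, neg))
    assert r.auc == pair_count_auc(pos, neg)
    assert trapezoid_auc(r.points) == pytest.approx(r.auc, abs=1e-12)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    pos=st.lists(st.integers(0, 6), min_size=1, max_size=40),
    neg=st.lists(st.integers(0, 6), min_size=1, max_size=40),
)
def test_auc_pair_counting_property(pos, neg):
    """Property over arbitrary tie patterns: midrank AUC is exactly the
    fraction of (positive, negative) pairs the score orders correctly."""
    pos = [float(p) for p in pos]
    neg = [float(q) for q in neg]
    r = roc(scored(pos, neg))
    assert r.auc == pair_count_auc(pos, neg)
    assert abs(trapezoid_auc(r.points) - r.auc) <= 1e-12
    assert 0.0 <= r.eer <= 1.0


def test_auc_cross_check_sklearn():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(42)
    pos = rng.normal(1, 1, size=30)
    neg = rng.normal(0, 1, size=50)
    r = roc(scored(pos, neg))
    y = np.r_[np.ones(30), np.zeros(50)]
    assert r.auc == pytest.approx(sk.roc_auc_score(y, np.r_[pos, neg]), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    pos = rng.normal(1, 1, size=20)
    neg = rng.normal(0, 1, size=20)
    r1 = roc(scored(pos, neg))
    r2 = roc(scored(np.exp(pos / 3), np.exp(neg / 3)))
    assert r1.auc == pytest.approx(r2.auc, abs=1e-12)


def test_truth_reversal_flips_auc():
    rng = np.random.default_rng(1)
    pos = rng.normal(1, 1, size=15)
    neg = rng.normal(0, 1, size=25)
    r = roc(scored(pos, neg))
    flipped = roc(
        [ScoredSample(s.sample_ref, s.score, not s.truth) for s in scored(pos, neg)]
    )
    assert flipped.auc == pytest.approx(1 - r.auc, abs=1e-12)


def test_eer_lies_on_curve_where_fpr_equals_fnr():
    rng = np.random.default_rng(2)
    pos = rng.normal(0.6, 1, size=40)
    neg = rng.normal(0.0, 1, size=40)
    r = roc(scored(pos, neg))
    # the interpolated EER point satisfies FPR = 1 - TPR by construction;
    # verify it sits inside the hull of adjacent vertices' residuals
    g = r.points[:, 0] + r.points[:, 1] - 1
    i = int(np.searchsorted(g, 0.0))
    assert g[max(i - 1, 0)] <= 1e-12 and g[min(i, len(g) - 1)] >= -1e-12
    assert 0.0 <= r.eer <= 1.0


def test_roc_single_class_errors():
    with pytest.raises(ValidationError):
        roc([ScoredSample("p", 1.0, True)])


# ---------------------------------------------------------------------------
# iterated hold-out


def test_run_iterated_counts_and_reproducibility(default_dataset):
    ss = default_dataset["subject2"]
    s_plus, s_minus = ss.positives[:8], ss.negatives[:10]
    cfg = ExperimentConfig(n_iterations=10, seed=5)
    out = run_iterated(s_plus, s_minus, cfg)
    # 6 train / 2 held-out positives per iteration, all 10 negatives scored
    assert len(out) == 10 * (2 + 10)
    assert sum(s.truth for s in out) == 20
    again = run_iterated(s_plus, s_minus, cfg)
    assert [(s.score, s.truth, s.iteration) for s in out] == [
        (s.score, s.truth, s.iteration) for s in again
    ]


def test_run_iterated_insufficient_positives(default_dataset):
    ss = default_dataset["subject1"]
    cfg = ExperimentConfig(n_iterations=2, seed=0)
    with pytest.raises(InsufficientDataError, match="subject1"):
        run_iterated(ss.positives[:2], ss.negatives, cfg)


# ---------------------------------------------------------------------------
# experiments (structure and error paths; regimes live in test_acceptance)


def test_intra_detection_requires_negatives(default_dataset):
    d = {"subject1": SubjectSamples(default_dataset["subject1"].positives, [])}
    with pytest.raises(InsufficientDataError):
        experiment_intra_detection(d, "subject1", ExperimentConfig(n_iterations=1))


def test_subject_id_requires_two_subjects(default_dataset):
    d = {"subject1": default_dataset["subject1"]}
    with pytest.raises(InsufficientDataError):
        experiment_subject_id(d, "subject1", ExperimentConfig(n_iterations=1))


def test_inter_subject_requires_two_subjects(default_dataset):
    d = {"subject1": default_dataset["subject1"]}
    with pytest.raises(InsufficientDataError):
        experiment_inter_subject(d, "subject1", ExperimentConfig(n_iterations=1))


def test_inter_subject_directions_differ(small_dataset):
    cfg = ExperimentConfig(seed=3)
    fwd = experiment_inter_subject(small_dataset, "subject1", cfg)
    rev = experiment_inter_subject(
        small_dataset,
        "subject1",
        ExperimentConfig(seed=3, inter_direction="train_target"),
    )
    # default direction tests on the target subject's own samples ...
    assert fwd.n_pos == len(small_dataset["subject1"].positives)
    assert fwd.n_neg == len(small_dataset["subject1"].negatives)
    # ... the reverse direction on everyone else's
    assert rev.n_pos == len(small_dataset["subject2"].positives)
    assert rev.n_neg == len(small_dataset["subject2"].negatives)


def test_channel_subset_restricts_model(small_dataset):
    cfg = ExperimentConfig(n_iterations=3, seed=1, channel_subset=("ST",))
    res = experiment_intra_detection(small_dataset, "subject1", cfg)
    assert 0.0 <= res.auc <= 1.0


# ---------------------------------------------------------------------------
# fusion sweep


def test_channel_subset_enumeration():
    subsets = channel_subsets(("HR", "BR", "SC", "ST"))
    assert len(subsets) == 15
    assert len(set(subsets)) == 15
    assert subsets[:4] == [("HR",), ("BR",), ("SC",), ("ST",)]
    assert subsets[-1] == ("HR", "BR", "SC", "ST")
    sizes = [len(s) for s in subsets]
    assert sizes == sorted(sizes)
    assert len(channel_subsets(("HR",))) == 1
    assert len(channel_subsets(("HR", "BR", "SC"))) == 7


def test_fusion_sweep_rejects_inter_subject(small_dataset):
    with pytest.raises(ValidationError):
        fusion_sweep(small_dataset, "inter_subject", ExperimentConfig(n_iterations=1))


def test_fusion_sweep_table_two_channels(small_dataset):
    cfg = ExperimentConfig(n_iterations=2, seed=2)
    table = fusion_sweep(small_dataset, "intra_detection", cfg, channels=("HR", "ST"))
    assert len(table) == 3
    assert list(table["HR"]) == [1, 0, 1]
    assert list(table["ST"]) == [0, 1, 1]
    for col in ("subject1_auc", "subject2_eer", "avg_auc", "avg_eer"):
        assert col in table.columns
    np.testing.assert_allclose(
        table["avg_auc"], (table["subject1_auc"] + table["subject2_auc"]) / 2
    )


# ---------------------------------------------------------------------------
# reporting


def test_experiment_table_layout(default_dataset):
    cfg = ExperimentConfig(n_iterations=2, seed=0)
    results = {
        sid: experiment_intra_detection(default_dataset, sid, cfg)
        for sid in default_dataset
    }
    table = experiment_table(results)
    assert list(table["subject"]) == [*default_dataset.keys(), "Average"]
    assert table["auc"].iloc[-1] == pytest.approx(table["auc"].iloc[:-1].mean())


def test_experiment_table_single_subject(default_dataset):
    cfg = ExperimentConfig(n_iterations=2, seed=0)
    res = experiment_intra_detection(default_dataset, "subject1", cfg)
    table = experiment_table({"subject1": res})
    assert table["auc"].iloc[-1] == table["auc"].iloc[0]


def test_write_report_rounding(tmp_path, default_dataset):
    import pandas as pd

    cfg = ExperimentConfig(n_iterations=2, seed=0)
    res = experiment_intra_detection(default_dataset, "subject1", cfg)
    df = experiment_table({"subject1": res})
    write_report(df, tmp_path / "t.csv")
    rounded = pd.read_csv(tmp_path / "t.csv")
    full = pd.read_csv(tmp_path / "t_full.csv")
    assert rounded["auc"].iloc[0] == round(full["auc"].iloc[0], 2)


def test_iteration_averaged_mode(default_dataset):
    """The sensitivity-analysis flag averages per-iteration ROCs instead of
    pooling scores; both modes agree on the trivial single-iteration case."""
    ss = default_dataset["subject1"]
    pooled_cfg = ExperimentConfig(n_iterations=1, seed=4)
    avg_cfg = ExperimentConfig(n_iterations=1, seed=4, pool_scores=False)
    a = experiment_intra_detection(default_dataset, "subject1", pooled_cfg)
    b = experiment_intra_detection(default_dataset, "subject1", avg_cfg)
    assert a.auc == b.auc and a.eer == b.eer
    multi = experiment_intra_detection(
        default_dataset, "subject1", ExperimentConfig(n_iterations=5, seed=4, pool_scores=False)
    )
    assert 0.0 <= multi.auc <= 1.0
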