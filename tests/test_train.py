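"""Leave-one-pair-out protocol plumbing, metrics, and the paired test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hemignn.model import ModelConfig
from hemignn.synth import SynthSpec, generate_cohort
from hemignn.train import (
    ProtocolError,
    TrainConfig,
    compare_runs,
    compute_metrics,
    make_lopo_folds,
    paired_one_sided_t_test,
    prepare_windows,
    run_experiment,
    split_train_val,
    train_fold,
    windows_to_arrays,
)


# -- fold construction ------------------------------------------------------------

def _subjects(n):
    return [(f"MDD{i:02d}", "MDD") for i in range(n)] + [
        (f"HC{i:02d}", "HC") for i in range(n)
    ]


def test_lopo_fold_count_and_partition():
    pairs = make_lopo_folds(_subjects(3), seed=0)
    assert len(pairs) == 3
    mdd, hc = zip(*pairs)
    assert sorted(mdd) == [f"MDD{i:02d}" for i in range(3)]
    assert sorted(hc) == [f"HC{i:02d}" for i in range(3)]


def test_lopo_matching_is_seeded():
    a = make_lopo_folds(_subjects(8), seed=5)
    b = make_lopo_folds(_subjects(8), seed=5)
    c = make_lopo_folds(_subjects(8), seed=6)
    assert a == b
    assert a != c  # a different seed shuffles the matching


def test_lopo_unbalanced_rejected():
    with pytest.raises(ProtocolError, match="unbalanced"):
        make_lopo_folds(_subjects(3) + [("MDD99", "MDD")], seed=0)


def test_window_bookkeeping_per_pair():
    """windows per fold = 2 subjects x 2 conditions x floor(segment / window)."""
    spec = SynthSpec(n_pairs=1, duration=16.0, seed=0)
    _, recordings = generate_cohort(spec)
    windows = prepare_windows(recordings, segment_seconds=12.0, window_seconds=2.0)
    assert len(windows) == 2 * 2 * 6
    x, y, subjects = windows_to_arrays(windows)
    assert x.shape == (24, 19, 512)
    assert y.sum() == 12  # half the windows are MDD


# -- train/validation split --------------------------------------------------------

def test_split_sizes_and_determinism(rng):
    y = np.array([0] * 50 + [1] * 50)
    tr, va = split_train_val(y, 0.2, seed=3)
    assert len(tr) == 80 and len(va) == 20
    assert set(tr) | set(va) == set(range(100))
    assert not set(tr) & set(va)
    tr2, va2 = split_train_val(y, 0.2, seed=3)
    np.testing.assert_array_equal(tr, tr2)
    np.testing.assert_array_equal(va, va2)


@given(n0=st.integers(5, 60), n1=st.integers(5, 60), seed=st.integers(0, 100))
@settings(max_examples=50, deadline=None)
def test_split_is_stratified(n0, n1, seed):
    y = np.array([0] * n0 + [1] * n1)
    _, va = split_train_val(y, 0.2, seed=seed)
    for cls, n in ((0, n0), (1, n1)):
        got = (y[va] == cls).sum()
        assert abs(got - 0.2 * n) <= 1.0  # class proportion within one window


# -- metrics ------------------------------------------------------------------------

def test_metrics_reproduce_aggregated_confusion():
    m = compute_metrics(tp=4606, tn=4357, fp=503, fn=254)
    assert round(m["accuracy"], 2) == 92.21
    assert round(m["sensitivity"], 2) == 94.77
    assert round(m["specificity"], 2) == 89.65
    assert m["f_measure"] == pytest.approx(9212 / 9969, abs=1e-12)


def test_metrics_perfect_and_degenerate():
    perfect = compute_metrics(1, 1, 0, 0)
    assert perfect["accuracy"] == perfect["sensitivity"] == perfect["specificity"] == 100.0
    assert perfect["f_measure"] == 1.0
    no_positives = compute_metrics(0, 5, 0, 0)
    assert np.isnan(no_positives["sensitivity"])  # undefined, not an exception
    with pytest.raises(ValueError):
        compute_metrics(-1, 0, 0, 0)
    with pytest.raises(ValueError):
        compute_metrics(0, 0, 0, 0)


@given(
    tp=st.integers(0, 500), tn=st.integers(0, 500),
    fp=st.integers(0, 500), fn=st.integers(0, 500),
)
@settings(max_examples=100, deadline=None)
def test_accuracy_identity(tp, tn, fp, fn):
    """accuracy = (sens*P + spec*N) / (P + N) whenever both are defined."""
    if tp + tn + fp + fn == 0:
        return
    m = compute_metrics(tp, tn, fp, fn)
    p, n = tp + fn, tn + fp
    if p == 0 or n == 0:
        return
    blended = (m["sensitivity"] * p + m["specificity"] * n) / (p + n)
    assert m["accuracy"] == pytest.approx(blended, abs=1e-9)


# -- paired one-sided t-test ---------------------------------------------------------

def test_ttest_equal_vectors():
    res = paired_one_sided_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.degenerate and res.p == 0.5


def test_ttest_constant_shift_degenerate():
    res = paired_one_sided_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
    assert res.degenerate and res.p == 0.0 and res.t == np.inf
    rev = paired_one_sided_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert rev.degenerate and rev.p == 1.0


def test_ttest_matches_scipy_oracle(rng):
    for _ in range(25):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        res = paired_one_sided_t_test(a, b)
        ref = stats.ttest_rel(a, b, alternative="greater")
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert not res.degenerate


def test_ttest_input_validation():
    with pytest.raises(ValueError):
        paired_one_sided_t_test([1.0], [2.0])
    with pytest.raises(ValueError):
        paired_one_sided_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


def test_subject_level_split_keeps_subjects_whole(caplog):
    import logging

    y = np.array([0] * 30 + [1] * 30)
    subjects = np.array(
        [f"HC{i}" for i in range(5) for _ in range(6)]
        + [f"MDD{i}" for i in range(5) for _ in range(6)]
    )
    with caplog.at_level(logging.WARNING, logger="hemignn.train"):
        tr, va = split_train_val(y, 0.2, seed=1, subjects=subjects, level="subject")
    assert "deviation" in caplog.text
    assert not set(subjects[tr]) & set(subjects[va])
    assert {0, 1} <= set(y[va])  # one held-out subject per class
    with pytest.raises(ProtocolError):
        split_train_val(y, 0.2, seed=1, level="subject")


def test_compare_runs_pairs_folds_by_held_out_pair():
    from hemignn.train import EvalSummary, FoldResult

    def summary(accs, order):
        folds = [
            FoldResult((f"MDD{i}", f"HC{i}"), dict(tp=1, tn=1, fp=0, fn=0),
                       {"accuracy": a, "sensitivity": 100.0, "specificity": 100.0,
                        "f_measure": 1.0}, 1, 1)
            for i, a in zip(order, accs)
        ]
        return EvalSummary(folds, {}, {}, {}, {}, {}, {})

    a = summary([90.0, 80.0, 85.0], [0, 1, 2])
    b = summary([70.0, 75.0, 80.0], [2, 0, 1])  # same pairs, shuffled fold order
    res = compare_runs(a, b)
    # matched by pair: a - b = (90-75, 80-80, 85-70) -> all >= 0
    assert res.p < 0.5
    with pytest.raises(ProtocolError):
        compare_runs(a, summary([50.0], [9]))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(val_fraction=1.5)
    with pytest.raises(ValueError):
        TrainConfig(val_split="fold")


# -- a tiny end-to-end fold ----------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_training_setup():
    spec = SynthSpec(n_pairs=2, duration=8.0, asymmetry_effect=4.0, snr=1.0, seed=21)
    _, recordings = generate_cohort(spec)
    windows = prepare_windows(recordings, segment_seconds=6.0, window_seconds=2.0)
    return windows_to_arrays(windows)


def test_train_fold_smoke(tiny_training_setup):
    x, y, subjects = tiny_training_setup
    mask = (subjects == "MDD01") | (subjects == "HC01")
    cfg = TrainConfig(max_epochs=2, seed=0)
    result, model = train_fold(
        x[~mask], y[~mask], x[mask], y[mask], ("MDD01", "HC01"),
        ModelConfig(), cfg, fold_seed=3,
    )
    conf = result.confusion
    assert sum(conf.values()) == int(mask.sum())
    assert conf["tp"] + conf["fn"] == int(y[mask].sum())
    assert conf["tn"] + conf["fp"] == int((1 - y[mask]).sum())
    assert result.epochs_run <= cfg.max_epochs
    assert 1 <= result.best_epoch <= result.epochs_run
    preds = model.predict(x[mask])
    assert set(np.unique(preds)) <= {0, 1}


def test_run_experiment_structure_and_no_leakage(tiny_training_setup):
    x, y, subjects = tiny_training_setup
    spec = SynthSpec(n_pairs=2, duration=8.0, asymmetry_effect=4.0, snr=1.0, seed=21)
    _, recordings = generate_cohort(spec)
    summary = run_experiment(
        recordings,
        ModelConfig(),
        TrainConfig(max_epochs=2, seed=1),
        segment_seconds=6.0,
    )
    assert len(summary.folds) == 2
    held_out = [s for f in summary.folds for s in f.held_out_pair]
    assert sorted(held_out) == ["HC01", "HC02", "MDD01", "MDD02"]
    total = sum(summary.aggregated_confusion.values())
    assert total == 2 * 2 * 2 * 3  # pairs x subjects x conditions x windows
    for key in ("tp", "tn", "fp", "fn"):
        assert summary.aggregated_confusion[key] == sum(
            f.confusion[key] for f in summary.folds
        )


def test_summary_serialization_round_trip(tmp_path, tiny_training_setup):
    spec = SynthSpec(n_pairs=2, duration=8.0, seed=21)
    _, recordings = generate_cohort(spec)
    summary = run_experiment(
        recordings, ModelConfig(), TrainConfig(max_epochs=1, seed=2),
        segment_seconds=6.0,
    )
    summary.save(tmp_path)
    import json

    blob = json.loads((tmp_path / "summary.json").read_text())
    assert blob["aggregated_confusion"] == summary.aggregated_confusion
    assert (tmp_path / "folds.csv").exists()
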