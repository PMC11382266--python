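import numpy as np
import pandas as pd
import pytest

from conftest import FAST_RF, FAST_SPLIT
from surfclass import (
    PlantedTableSpec,
    SplitSpec,
    balanced_split,
    compare_algorithms,
    evaluate,
    f1_from_precision_recall,
    make_planted_table,
    prune_by_importance,
    run_protocol,
    train_forest,
)
from surfclass.rf_protocol import (
    DegenerateTrainingError,
    InsufficientClassError,
    SchemaError,
)


def _label_table(n_a, n_b, seed=0):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame({"f": rng.normal(size=n_a + n_b)})
    t["class"] = ["cytosol"] * n_a + ["secreted"] * n_b
    t.index = [f"p{i}" for i in range(n_a + n_b)]
    return t


def test_study_scale_split_counts():
    """354+354 rows at 70% training give 248 per class and 212 test rows."""
    t = _label_table(354, 354)
    train, test = balanced_split(t, SplitSpec(train_fraction=0.7, n_iterations=1), seed=3)
    counts = train["class"].value_counts()
    assert counts["cytosol"] == 248 and counts["secreted"] == 248
    assert len(test) == 212
    assert set(train.index).isdisjoint(test.index)


def test_half_split_counts():
    t = _label_table(10, 10)
    train, test = balanced_split(t, SplitSpec(train_fraction=0.5, n_iterations=1), seed=0)
    assert train["class"].value_counts().to_dict() == {"cytosol": 5, "secreted": 5}
    assert len(test) == 10


def test_small_class_raises_insufficient():
    t = _label_table(300, 100)
    with pytest.raises(InsufficientClassError):
        balanced_split(t, SplitSpec(train_fraction=0.7, n_iterations=1), seed=0)


def test_split_reproducible_and_seed_sensitive():
    t = _label_table(60, 60)
    spec = SplitSpec(train_fraction=0.7, n_iterations=1)
    a1, _ = balanced_split(t, spec, seed=5)
    a2, _ = balanced_split(t, spec, seed=5)
    b, _ = balanced_split(t, spec, seed=6)
    assert list(a1.index) == list(a2.index)
    assert list(a1.index) != list(b.index)


def test_separable_training_is_perfect(toy_table):
    forest = train_forest(toy_table, {"n_estimators": 50}, seed=0)
    X = toy_table.drop(columns="class")
    assert (forest.predict(X) == toy_table["class"]).mean() == 1.0


def test_training_is_deterministic(toy_table):
    X = toy_table.drop(columns="class")
    p1 = train_forest(toy_table, {"n_estimators": 50}, seed=1).predict(X)
    p2 = train_forest(toy_table, {"n_estimators": 50}, seed=1).predict(X)
    assert np.array_equal(p1, p2)


def test_single_class_training_is_degenerate(toy_table):
    t = toy_table.copy()
    t["class"] = "cytosol"
    with pytest.raises(DegenerateTrainingError):
        train_forest(t)


def test_planted_table_heldout_accuracy():
    tab = make_planted_table(PlantedTableSpec(n_per_class=400, seed=3))
    spec = SplitSpec(train_fraction=0.7, n_iterations=1)
    train, test = balanced_split(tab, spec, seed=0)
    forest = train_forest(train, FAST_RF, seed=0)
    m = evaluate(forest, test)
    assert m.accuracy > 0.90  # Bayes rate is ~95% at 5% label noise


@pytest.mark.parametrize(
    "precision,recall,expected",
    [(0.939, 0.930, 0.935), (0.906, 0.906, 0.906)],
)
def test_f1_worked_examples(precision, recall, expected):
    """f1 recomputed from 3-dp-rounded precision/recall agrees with the
    reported 3-dp f1 to within one unit in the last digit (the inputs'
    own rounding can move the harmonic mean by up to that much)."""
    assert f1_from_precision_recall(precision, recall) == pytest.approx(
        expected, abs=1e-3
    )


def test_perfect_predictions_metrics(toy_table):
    forest = train_forest(toy_table, {"n_estimators": 50}, seed=0)
    m = evaluate(forest, toy_table)  # training set is separable -> perfect
    assert m.accuracy == m.precision == m.recall == m.f1 == 1.0
    assert m.auc == pytest.approx(1.0)
    c = m.confusion
    assert c["fp"] == c["fn"] == 0
    assert sum(c.values()) == len(toy_table)


def test_evaluate_schema_mismatch(toy_table):
    forest = train_forest(toy_table, {"n_estimators": 10}, seed=0)
    bad = toy_table.rename(columns={"fa": "unknown"})
    with pytest.raises(SchemaError):
        evaluate(forest, bad)


def test_protocol_single_iteration(planted_table):
    res = run_protocol(planted_table, SplitSpec(n_iterations=1), FAST_RF, seed=0)
    assert len(res.runs) == 1
    assert res.best is res.runs[0]


def test_protocol_internal_consistency(planted_result):
    for run in planted_result.runs:
        m = run.metrics
        assert 0 <= m.accuracy <= 1 and 0 <= m.auc <= 1
        assert round(m.f1, 3) == round(f1_from_precision_recall(m.precision, m.recall), 3)
        assert run.importances.sum() == pytest.approx(1.0, abs=1e-9)
        assert (run.importances >= 0).all()
        assert sum(m.confusion.values()) == 800 - 2 * (round(0.7 * 800) // 2)
    assert planted_result.mean_importances.sum() == pytest.approx(1.0, abs=1e-9)
    assert planted_result.best.metrics.accuracy == planted_result.accuracies.max()
    top_accs = [r.metrics.accuracy for r in planted_result.top_k]
    assert top_accs == sorted(top_accs, reverse=True)


def test_protocol_accuracy_stability(planted_result, planted_table):
    single = run_protocol(planted_table, SplitSpec(n_iterations=1), FAST_RF, seed=99)
    assert abs(planted_result.accuracies.mean() - single.accuracies[0]) < 0.02


def test_planted_feature_ranks_first_across_seeds():
    wins = 0
    for seed in range(10):
        tab = make_planted_table(
            PlantedTableSpec(
                n_per_class=150,
                rules=(PlantedTableSpec().rules[0],),
                n_noise_features=5,
                seed=seed,
            )
        )
        res = run_protocol(tab, SplitSpec(n_iterations=3), {"n_estimators": 60}, seed=seed)
        wins += res.mean_importances.idxmax() == "surf_GLU_pct"
    assert wins >= 9


def test_prune_by_importance_boundary_semantics():
    imps = {"f1": 0.60, "f2": 0.38, "f3": 0.02, "f4": 0.00}
    kept = prune_by_importance(imps, floor=0.02)
    assert kept == ["f1", "f2", "f3"]  # exactly 2% kept, strict less-than drops


def test_prune_by_importance_keeps_all_above_floor():
    imps = {"a": 0.5, "b": 0.3, "c": 0.2}
    assert set(prune_by_importance(imps)) == {"a", "b", "c"}


def test_prune_by_importance_guards_two_features():
    imps = {"a": 0.9995, "b": 0.0003, "c": 0.0002}
    assert len(prune_by_importance(imps)) == 2


def test_noise_features_pruned_on_noiseless_planted_table():
    """Without label noise, pure-noise features sit at the 2% importance
    floor (sharing only the boundary-localization residue of the Gini
    decrease): the rule features always survive pruning and rank top-3,
    and noise features are almost always all dropped (never more than one
    survives)."""
    rules = {"surf_GLU_pct", "surf_CYS_pct", "surf_LEU_pct"}
    n_noise_kept = []
    for seed in range(6):
        tab = make_planted_table(
            PlantedTableSpec(n_per_class=400, noise_rate=0.0, seed=seed)
        )
        res = run_protocol(tab, FAST_SPLIT, FAST_RF, seed=seed + 100)
        kept = prune_by_importance(res, floor=0.02)
        assert rules <= set(kept)
        assert set(res.mean_importances.nlargest(3).index) == rules
        n_noise_kept.append(len(set(kept) - rules))
    assert max(n_noise_kept) <= 1
    assert sorted(n_noise_kept)[len(n_noise_kept) // 2] == 0  # median: all dropped


def test_algorithm_comparison_forest_beats_linear():
    tab = make_planted_table(PlantedTableSpec(n_per_class=150, n_noise_features=4, seed=4))
    spec = SplitSpec(n_iterations=4)
    out = compare_algorithms(
        tab, spec, seed=0, algorithms=["logistic_regression", "random_forest"]
    )
    assert out["random_forest"]["mean"] >= out["logistic_regression"]["mean"]
    for entry in out.values():
        assert np.all((entry["accuracies"] >= 0) & (entry["accuracies"] <= 1))


def test_algorithm_comparison_no_signal_near_chance():
    rng = np.random.default_rng(8)
    t = pd.DataFrame({"f1": rng.normal(size=200), "f2": rng.normal(size=200)})
    t["class"] = ["cytosol", "secreted"] * 100
    out = compare_algorithms(
        t, SplitSpec(n_iterations=4), seed=1, algorithms=["random_forest", "knn"]
    )
    for entry in out.values():
        assert 0.3 < entry["mean"] < 0.7
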