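"""Relabeling, balancing, splitting, grid CV and evaluation protocol."""

import numpy as np
import pandas as pd
import pytest

from hsfluor.classify import (
    EvaluationReport,
    FeatureTable,
    ModelSpec,
    build_feature_table,
    compact_grids,
    cross_validate_grid,
    evaluate,
    make_estimator,
    relabel_who2021,
    select_and_fit,
    split_train_test,
    table1_grids,
)
from hsfluor.exceptions import TaskInfeasibleError
from hsfluor.spectral import FLUOROPHORES


def _roster(counts: dict[str, int], seed=0, n_biopsies=3) -> pd.DataFrame:
    """Construct a block table with the given per-class block counts."""
    rng = np.random.default_rng(seed)
    rows = []
    bid = 0
    for label, n in counts.items():
        per = np.array_split(np.arange(n), n_biopsies)
        for chunk in per:
            rows.append(pd.DataFrame({
                "biopsy_id": f"B{bid:04d}",
                "label": label,
                "tile_row": 10 * (np.arange(len(chunk)) // 25),
                "tile_col": 10 * (np.arange(len(chunk)) % 25),
                **{f"c_{f}": rng.uniform(0.1, 2.0, len(chunk)) for f in FLUOROPHORES},
            }))
            bid += 1
    return pd.concat(rows, ignore_index=True)


class TestRelabelWHO2021:
    @pytest.mark.parametrize(
        "tissue,idh,expected",
        [("AA", "wildtype", "GB"), ("AA", "mutant", "AA"), ("GB", "wildtype", "GB"),
         ("DA", "wildtype", "DA"), ("AA", "unknown", "AA")],
    )
    def test_rule(self, tissue, idh, expected):
        records = pd.DataFrame({"tissue_type": [tissue], "idh": [idh]})
        out, _ = relabel_who2021(records)
        assert out["tissue_type"].iloc[0] == expected

    def test_relabel_count_reported(self):
        records = pd.DataFrame({
            "tissue_type": ["AA", "AA", "AA", "GB", "DA"],
            "idh": ["wildtype", "wildtype", "mutant", "wildtype", "mutant"],
        })
        out, n = relabel_who2021(records)
        assert n == 2
        assert (out["tissue_type"] == "GB").sum() == 3

    def test_input_not_mutated(self):
        records = pd.DataFrame({"tissue_type": ["AA"], "idh": ["wildtype"]})
        relabel_who2021(records)
        assert records["tissue_type"].iloc[0] == "AA"


class TestFeatureTable:
    def test_exclusion_rule_keeps_task_feasible_classes(self):
        blocks = _roster({"A": 600, "B": 450, "C": 700})
        table = build_feature_table(blocks, samples_per_class=500, seed=0)
        assert table.included_classes == ("A", "C")
        assert table.excluded_classes == ("B",)

    def test_three_pixels_gives_fifteen_features(self):
        blocks = _roster({"A": 300, "B": 300})
        table = build_feature_table(blocks, pixels_per_sample=3,
                                    samples_per_class=100, seed=1)
        assert table.features.shape == (200, 15)
        assert len(table.feature_names) == 15

    def test_exact_balance_per_class(self):
        blocks = _roster({"A": 400, "B": 350, "C": 500})
        table = build_feature_table(blocks, samples_per_class=300, seed=2)
        counts = pd.Series(table.labels).value_counts()
        assert (counts == 300).all()

    def test_explicit_exclusion_flag(self):
        blocks = _roster({"A": 300, "AE": 300, "B": 300})
        table = build_feature_table(blocks, samples_per_class=200, seed=0,
                                    exclude=("AE",))
        assert "AE" not in table.included_classes
        assert "AE" not in set(table.labels)

    def test_all_mode_uses_smallest_class(self):
        blocks = _roster({"A": 320, "B": 260})
        table = build_feature_table(blocks, samples_per_class="all", seed=0)
        assert table.samples_per_class == 260
        assert len(table) == 520

    def test_fewer_than_two_survivors_infeasible(self):
        blocks = _roster({"A": 600, "B": 450})
        with pytest.raises(TaskInfeasibleError):
            build_feature_table(blocks, samples_per_class=550, seed=0)

    def test_neighbor_blocks_come_from_same_biopsy(self, small_margin_dataset):
        table = build_feature_table(small_margin_dataset, pixels_per_sample=2,
                                    samples_per_class=50, seed=3)
        # anchor and neighbor abundances must both exist in the anchor's biopsy
        blocks = small_margin_dataset.blocks
        ab_cols = [f"c_{f}" for f in FLUOROPHORES]
        for i in range(0, len(table), 37):
            bid = table.biopsy_ids[i]
            bb = blocks[blocks["biopsy_id"] == bid][ab_cols].to_numpy()
            anchor, neighbor = table.features[i, :5], table.features[i, 5:]
            assert (np.abs(bb - anchor).max(axis=1) < 1e-12).any()
            assert (np.abs(bb - neighbor).max(axis=1) < 1e-12).any()


class TestSplit:
    def test_stratified_20_percent_counts(self):
        blocks = _roster({"A": 700, "B": 700, "C": 700})
        table = build_feature_table(blocks, samples_per_class=500, seed=0)
        train, test = split_train_test(table, seed=1)
        test_counts = pd.Series(test.labels).value_counts()
        assert (test_counts == 100).all()
        train_counts = pd.Series(train.labels).value_counts()
        assert (train_counts == 400).all()

    def test_same_seed_same_split_and_partition(self):
        blocks = _roster({"A": 300, "B": 300})
        table = build_feature_table(blocks, samples_per_class=200, seed=0)
        tr1, te1 = split_train_test(table, seed=5)
        tr2, te2 = split_train_test(table, seed=5)
        np.testing.assert_array_equal(tr1.features, tr2.features)
        np.testing.assert_array_equal(te1.features, te2.features)
        assert len(tr1) + len(te1) == len(table)
        # disjoint: no row of test appears in train
        joint = np.vstack([tr1.features, te1.features])
        assert len(np.unique(joint, axis=0)) == len(joint)

    def test_grouped_split_keeps_biopsies_together(self, small_margin_dataset):
        table = build_feature_table(small_margin_dataset, samples_per_class=400, seed=0)
        train, test = split_train_test(table, seed=2, group_by_biopsy=True)
        assert not (set(train.biopsy_ids) & set(test.biopsy_ids))


class TestGrids:
    def test_published_grid_cardinalities(self):
        specs = table1_grids()
        by_algo = pd.Series([s.algorithm for s in specs]).value_counts().to_dict()
        assert by_algo == {
            "random_forest": 5 * 3 * 3 * 3,  # trees x criterion x min-split x features
            "knn": 4 * 2 * 2,
            "mlp": 3 * 4 * 2,
            "svm": 4,
            "adaboost": 1,
        }

    def test_every_spec_constructs_an_estimator(self):
        for spec in compact_grids():
            assert make_estimator(spec, seed=0) is not None


class TestCrossValidation:
    def _separable_table(self, n=120):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (n, 5)), rng.normal(5, 0.3, (n, 5))])
        y = np.array(["neg"] * n + ["pos"] * n)
        return FeatureTable(
            features=X, labels=y, biopsy_ids=np.array(["b"] * 2 * n),
            pixels_per_sample=1, samples_per_class=n,
            included_classes=("neg", "pos"), excluded_classes=(), seed=0,
        )

    def test_single_model_grid_returns_it(self):
        table = self._separable_table()
        spec = ModelSpec.of("knn", n_neighbors=3, weights="uniform", p=2)
        ranked = cross_validate_grid(table, [spec], seed=0)
        assert len(ranked) == 1 and ranked[0].spec == spec

    def test_perfectly_separable_reaches_full_accuracy(self):
        ranked = cross_validate_grid(self._separable_table(), compact_grids(), seed=0)
        assert ranked[0].mean_cv_accuracy == 1.0

    def test_ranking_is_deterministic(self):
        table = self._separable_table()
        r1 = cross_validate_grid(table, compact_grids(), seed=3)
        r2 = cross_validate_grid(table, compact_grids(), seed=3)
        assert [e.spec for e in r1] == [e.spec for e in r2]
        assert [e.mean_cv_accuracy for e in r1] == [e.mean_cv_accuracy for e in r2]


class _FixedScoreModel:
    """Stub classifier emitting predetermined class scores."""

    def __init__(self, classes, scores):
        self.classes_ = np.asarray(classes)
        self._scores = np.asarray(scores, dtype=float)

    def predict(self, X):
        return self.classes_[np.argmax(self._scores, axis=1)]

    def predict_proba(self, X):
        return self._scores


def _table_for(labels):
    labels = np.asarray(labels)
    return FeatureTable(
        features=np.zeros((len(labels), 5)), labels=labels,
        biopsy_ids=np.array([f"b{i}" for i in range(len(labels))]),
        pixels_per_sample=1, samples_per_class=0,
        included_classes=tuple(sorted(set(labels))), excluded_classes=(), seed=0,
    )


class TestEvaluate:
    def test_all_correct_predictions(self):
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        scores = np.eye(3)[[0, 0, 1, 1, 2, 2]]
        rep = evaluate(_FixedScoreModel(["a", "b", "c"], scores), _table_for(labels))
        assert rep.accuracy == 1.0
        assert np.all(rep.confusion == 2 * np.eye(3))
        assert all(v == 1.0 for v in rep.auc_per_class.values())
        assert rep.macro_auc == 1.0

    def test_auc_matches_concordant_pair_count(self):
        # scores 0.9, 0.8, 0.3, 0.2 with labels +,-,+,- : 3 of 4 pairs concordant
        labels = np.array(["pos", "neg", "pos", "neg"])
        pos_scores = np.array([0.9, 0.8, 0.3, 0.2])
        scores = np.column_stack([1 - pos_scores, pos_scores])
        rep = evaluate(_FixedScoreModel(["neg", "pos"], scores), _table_for(labels))
        assert rep.auc_per_class["pos"] == pytest.approx(0.75)

    def test_random_predictions_near_chance(self):
        rng = np.random.default_rng(10)
        k, n = 4, 2000
        labels = np.repeat([f"c{i}" for i in range(k)], n // k)
        scores = rng.random((n, k))
        rep = evaluate(_FixedScoreModel([f"c{i}" for i in range(k)], scores),
                       _table_for(labels))
        # binomial band around 1/k at 4 sigma
        sd = np.sqrt((1 / k) * (1 - 1 / k) / n)
        assert abs(rep.accuracy - 1 / k) < 4 * sd

    def test_missing_test_class_flagged(self):
        labels = np.array(["a", "a", "b", "b"])  # class "c" absent
        scores = np.eye(3)[[0, 0, 1, 1]]
        with pytest.warns(UserWarning, match="absent"):
            rep = evaluate(_FixedScoreModel(["a", "b", "c"], scores), _table_for(labels))
        assert rep.missing_test_classes == ("c",)
        assert np.isnan(rep.auc_per_class["c"])


class TestEndToEndProtocol:
    def test_strong_separation_recovers_classes(self, small_margin_dataset):
        # small but strongly separated configuration trains to high accuracy
        from hsfluor.simulate import simulate_dataset

        ds = simulate_dataset("margin", n_biopsies_per_class=4, seed=21, delta=2.0)
        table = build_feature_table(ds, pixels_per_sample=1,
                                    samples_per_class=300, seed=1)
        train, test = split_train_test(table, seed=2)
        ranked = cross_validate_grid(train, compact_grids()[:2], seed=3)
        model = select_and_fit(train, ranked, seed=3)
        rep = evaluate(model, test)
        assert rep.accuracy >= 0.9
        assert rep.macro_auc >= 0.95

    def test_monotone_benefit_of_more_samples(self):
        from hsfluor.simulate import simulate_dataset

        ds = simulate_dataset("margin", n_biopsies_per_class=6, seed=31, delta=0.6)
        accs = []
        for spc in (100, 400):
            table = build_feature_table(ds, samples_per_class=spc, seed=1)
            train, _ = split_train_test(table, seed=2)
            ranked = cross_validate_grid(train, compact_grids()[:1], seed=3)
            accs.append(ranked[0].mean_cv_accuracy)
        assert accs[1] >= accs[0] - 0.03  # non-decreasing within CV noise
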