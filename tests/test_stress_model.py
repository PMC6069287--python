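"""Feature assembly, confusion-matrix metrics, RF training, raster classification."""
import datetime as dt

import numpy as np
import pytest

from hmssi import (
    ConfigurationError,
    DegenerateLabelsError,
    FeatureTable,
    GrowthStage,
    IndexKind,
    InputError,
    RFConfig,
    SchemaError,
    StressLevel,
    assess,
    build_feature_table,
    classify_raster,
    compute_index_raster,
    load_model,
    save_model,
    train_model,
    variable_importance,
)
from hmssi.spectral_indices import IndexRaster
from hmssi.stress_model import (
    LEVEL_ORDER,
    area_percentages,
    read_classified_map,
    write_classified_map,
)

from conftest import make_geom

H, M, L = StressLevel.HIGH, StressLevel.MEDIUM, StressLevel.LOW

DATES = [
    (dt.date(2017, 7, 12), GrowthStage.BOOTING),
    (dt.date(2017, 7, 24), GrowthStage.BOOTING),
    (dt.date(2017, 8, 6), GrowthStage.FLOWERING),
    (dt.date(2017, 8, 21), GrowthStage.FLOWERING),
    (dt.date(2017, 9, 17), GrowthStage.MATURE),
    (dt.date(2017, 9, 30), GrowthStage.MATURE),
]


def hmssi_stack(rng, rows=10, cols=12, nodata_at=None):
    geom = make_geom(rows, cols)
    rasters = []
    for date, stage in DATES:
        values = rng.uniform(5.0, 50.0, size=(rows, cols))
        mask = np.zeros((rows, cols), dtype=bool)
        if nodata_at is not None:
            mask[nodata_at] = True
            values[nodata_at] = np.nan
        rasters.append(
            IndexRaster(values=values, geom=geom, index_kind=IndexKind.HMSSI,
                        source_date=date, growth_stage=stage, nodata_mask=mask)
        )
    return rasters


def separable_table(rng, n_per_class=60, p=6, gap=50.0, noise=1.0):
    """Classes separated by gaps much larger than the noise."""
    X, y = [], []
    for i, lv in enumerate(LEVEL_ORDER):
        X.append(rng.normal(loc=i * gap, scale=noise, size=(n_per_class, p)))
        y += [lv.value] * n_per_class
    return FeatureTable(
        X=np.vstack(X), y=np.array(y, dtype=object),
        feature_names=[d.isoformat() for d, _ in DATES[:p]],
        stage_subset=tuple(GrowthStage),
    )


class TestBuildFeatureTable:
    def test_whole_growth_has_six_columns(self, rng):
        rasters = hmssi_stack(rng)
        pixels = np.array([[1, 1], [2, 3], [4, 5]])
        table = build_feature_table(rasters, pixels, ["high", "medium", "low"])
        assert table.X.shape == (3, 6)
        assert table.feature_names == sorted(table.feature_names)

    def test_single_stage_has_two_columns(self, rng):
        rasters = hmssi_stack(rng)
        pixels = np.array([[1, 1], [2, 3]])
        table = build_feature_table(rasters, pixels, ["high", "low"], (GrowthStage.BOOTING,))
        assert table.X.shape == (2, 2)
        assert table.stage_subset == (GrowthStage.BOOTING,)

    def test_nodata_row_dropped_and_counted(self, rng):
        rasters = hmssi_stack(rng, nodata_at=(2, 3))
        pixels = np.array([[1, 1], [2, 3], [4, 5]])
        table = build_feature_table(rasters, pixels, ["high", "medium", "low"])
        assert len(table) == 2 and table.n_dropped == 1

    def test_missing_stage_raster_is_configuration_error(self, rng):
        rasters = [r for r in hmssi_stack(rng) if r.growth_stage is not GrowthStage.MATURE]
        with pytest.raises(ConfigurationError):
            build_feature_table(rasters, np.array([[0, 0]]), ["high"], (GrowthStage.MATURE,))

    def test_grid_mismatch_is_alignment_error(self, rng):
        from hmssi import AlignmentError

        rasters = hmssi_stack(rng)
        small = hmssi_stack(rng, rows=4, cols=4)
        with pytest.raises(AlignmentError):
            build_feature_table([rasters[0], small[1]], np.array([[0, 0]]), ["high"])


class TestAssess:
    def test_perfect_agreement(self):
        labels = ["high"] * 5 + ["medium"] * 5 + ["low"] * 5
        a = assess(labels, labels)
        assert a.overall_accuracy == 1.0 and a.kappa == 1.0
        assert all(v == 1.0 for v in a.users_accuracy.values())
        assert all(v == 1.0 for v in a.producers_accuracy.values())

    def test_two_class_hand_computed_matrix(self):
        # reference: 50 high, 50 medium; confusion [[40,10],[20,30]]
        ref = ["high"] * 50 + ["medium"] * 50
        pred = ["high"] * 40 + ["medium"] * 10 + ["high"] * 20 + ["medium"] * 30
        a = assess(ref, pred)
        assert a.overall_accuracy == pytest.approx(0.70)
        # pe = (50*60 + 50*40)/100^2 = 0.5 -> kappa = (0.7-0.5)/0.5 = 0.4
        assert a.kappa == pytest.approx(0.40)

    def test_absent_class_reported_not_applicable(self):
        ref = ["high", "high", "medium", "medium"]
        pred = ["high", "medium", "medium", "medium"]
        a = assess(ref, pred)
        assert np.isnan(a.users_accuracy[L]) and np.isnan(a.producers_accuracy[L])
        assert a.confusion_matrix.shape == (3, 3)
        assert a.confusion_matrix[2].sum() == 0
        d = a.to_dict()
        assert d["users_accuracy"]["low"] is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            assess(["high"], ["high", "low"])

    def test_oa_invariant_and_matrix_consistent_under_label_permutation(self, rng):
        levels = np.array([lv.value for lv in LEVEL_ORDER])
        ref = levels[rng.integers(0, 3, 200)]
        pred = levels[rng.integers(0, 3, 200)]
        base = assess(ref, pred)
        perm = {"high": "low", "medium": "high", "low": "medium"}
        swapped = assess([perm[r] for r in ref], [perm[p] for p in pred])
        assert swapped.overall_accuracy == base.overall_accuracy
        assert swapped.kappa == pytest.approx(base.kappa)
        assert swapped.confusion_matrix.sum() == base.confusion_matrix.sum()
        assert np.trace(swapped.confusion_matrix) == np.trace(base.confusion_matrix)

    def test_kappa_against_sklearn_on_random_vectors(self, rng):
        from sklearn.metrics import cohen_kappa_score

        levels = np.array([lv.value for lv in LEVEL_ORDER])
        for _ in range(50):
            ref = levels[rng.integers(0, 3, 60)]
            pred = levels[rng.integers(0, 3, 60)]
            if len(set(ref) | set(pred)) < 2:
                continue
            a = assess(ref, pred)
            assert a.kappa == pytest.approx(cohen_kappa_score(ref, pred))

    def test_kappa_one_iff_diagonal_with_positive_trace(self, rng):
        levels = np.array([lv.value for lv in LEVEL_ORDER])
        for _ in range(200):
            ref = levels[rng.integers(0, 3, 30)]
            pred = ref.copy()
            if rng.random() < 0.5:  # corrupt some predictions
                k = rng.integers(1, 10)
                idx = rng.choice(30, size=k, replace=False)
                pred[idx] = levels[rng.integers(0, 3, k)]
            a = assess(ref, pred)
            diagonal = (
                a.confusion_matrix.sum() == np.trace(a.confusion_matrix)
                and np.trace(a.confusion_matrix) > 0
            )
            assert (a.kappa == 1.0) == diagonal


class TestTrainModel:
    def test_separable_classes_classified_perfectly(self, rng):
        table = separable_table(rng)
        _, a = train_model(table, RFConfig(ntree=100, seed=0))
        assert a.overall_accuracy == 1.0 and a.kappa == 1.0

    def test_same_seed_reproduces_confusion_matrix(self, rng):
        table = separable_table(rng, gap=2.0, noise=1.5)
        _, a1 = train_model(table, RFConfig(ntree=100, seed=5))
        _, a2 = train_model(table, RFConfig(ntree=100, seed=5))
        assert np.array_equal(a1.confusion_matrix, a2.confusion_matrix)
        assert a1.oob_error == a2.oob_error

    def test_single_class_rejected(self, rng):
        table = FeatureTable(
            X=rng.normal(size=(20, 2)), y=np.array(["high"] * 20, dtype=object),
            feature_names=["a", "b"], stage_subset=(GrowthStage.BOOTING,),
        )
        with pytest.raises(DegenerateLabelsError):
            train_model(table, RFConfig(seed=0))

    def test_permuted_labels_give_chance_accuracy(self, rng):
        # averaged over seeds, holdout OA under the permutation null is ~1/3
        oas = []
        for seed in range(8):
            table = separable_table(np.random.default_rng(seed), n_per_class=50, p=2)
            perm = np.random.default_rng(100 + seed).permutation(len(table))
            shuffled = FeatureTable(
                X=table.X, y=table.y[perm], feature_names=table.feature_names,
                stage_subset=table.stage_subset,
            )
            _, a = train_model(shuffled, RFConfig(ntree=100, seed=seed))
            oas.append(a.overall_accuracy)
        n_total = 8 * 45  # 30% holdout of 150
        se = np.sqrt((1 / 3) * (2 / 3) / n_total)
        assert abs(np.mean(oas) - 1 / 3) < 3 * se

    def test_mtry_rule(self):
        assert RFConfig().mtry(6) == 2
        assert RFConfig().mtry(2) == 1
        assert RFConfig(mtry_rule="explicit", mtry_value=3).mtry(6) == 3
        with pytest.raises(ConfigurationError):
            RFConfig(mtry_rule="explicit", mtry_value=9).mtry(6)


class TestVariableImportance:
    def test_scores_sum_to_one(self, rng):
        table = separable_table(rng)
        model, _ = train_model(table, RFConfig(ntree=100, seed=0))
        scores = variable_importance(model)
        assert sum(scores.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in scores.values())

    def test_planted_informative_feature_wins(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 60
            X = rng.normal(size=(3 * n, 6))
            y = np.array(["high"] * n + ["medium"] * n + ["low"] * n, dtype=object)
            X[:, 2] += np.repeat([0.0, 3.0, 6.0], n)  # informative column
            table = FeatureTable(X=X, y=y, feature_names=list("abcdef"),
                                 stage_subset=tuple(GrowthStage))
            model, _ = train_model(table, RFConfig(ntree=100, seed=seed))
            scores = variable_importance(model)
            assert max(scores, key=scores.get) == "c"

    def test_duplicated_informative_feature_shares_score(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 60
            signal = np.repeat([0.0, 3.0, 6.0], n)
            X = rng.normal(size=(3 * n, 6))
            X[:, 0] += signal
            X[:, 1] += signal  # duplicate of the informative feature
            y = np.array(["high"] * n + ["medium"] * n + ["low"] * n, dtype=object)
            table = FeatureTable(X=X, y=y, feature_names=list("abcdef"),
                                 stage_subset=tuple(GrowthStage))
            model, _ = train_model(table, RFConfig(ntree=100, seed=seed))
            s = variable_importance(model)
            assert s["a"] + s["b"] > max(s["c"], s["d"], s["e"], s["f"])

    def test_permutation_importance_available(self, rng):
        table = separable_table(rng, p=3)
        model, _ = train_model(table, RFConfig(ntree=50, seed=0))
        scores = variable_importance(model, kind="permutation", table=table, n_repeats=3)
        assert set(scores) == set(table.feature_names)


class TestClassifyRaster:
    def _fitted_model(self, rng, rasters, truth):
        pixels = np.argwhere(truth > 0)
        labels = [LEVEL_ORDER[truth[r, c] - 1].value for r, c in pixels]
        table = build_feature_table(rasters, pixels, labels)
        model, _ = train_model(table, RFConfig(ntree=50, seed=0))
        return model

    def _stack_with_classes(self, rows=20, cols=15):
        """HMSSI stack whose values directly encode three separable classes."""
        geom = make_geom(rows, cols)
        truth = np.zeros((rows, cols), dtype=np.uint8)
        truth[:, :5] = 1
        truth[:, 5:10] = 2
        truth[:, 10:] = 3
        rng = np.random.default_rng(0)
        rasters = []
        for date, stage in DATES:
            values = np.choose(truth - 1, [10.0, 30.0, 60.0]) + rng.normal(0, 1, (rows, cols))
            rasters.append(
                IndexRaster(values=values, geom=geom, index_kind=IndexKind.HMSSI,
                            source_date=date, growth_stage=stage,
                            nodata_mask=np.zeros((rows, cols), dtype=bool))
            )
        return rasters, truth

    def test_counts_and_percentages(self, rng):
        rasters, truth = self._stack_with_classes()
        model = self._fitted_model(rng, rasters, truth)
        mask = truth > 0
        coded, summary = classify_raster(model, rasters, mask)
        assert summary.total == mask.sum()
        pct = summary.percentages()
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.1)
        # separable values: the classified map recovers the truth
        assert np.array_equal(coded[mask], truth[mask])
        assert (coded[~mask] == 0).all()

    def test_nodata_feature_excluded_from_denominator(self, rng):
        rasters, truth = self._stack_with_classes()
        rasters[3].nodata_mask[0, 0] = True
        model = self._fitted_model(rng, rasters, truth)
        mask = truth > 0
        coded, summary = classify_raster(model, rasters, mask)
        assert coded[0, 0] == 0
        assert summary.total == mask.sum() - 1

    def test_map_round_trip_preserves_area_summary(self, tmp_path, rng):
        rasters, truth = self._stack_with_classes()
        model = self._fitted_model(rng, rasters, truth)
        coded, summary = classify_raster(model, rasters, truth > 0)
        path = tmp_path / "classified.tif"
        write_classified_map(coded, rasters[0].geom, path)
        back, _ = read_classified_map(path)
        assert area_percentages(back).pixel_counts == summary.pixel_counts

    def test_feature_count_mismatch_is_schema_error(self, rng):
        rasters, truth = self._stack_with_classes()
        model = self._fitted_model(rng, rasters, truth)
        with pytest.raises(SchemaError):
            classify_raster(model, rasters[:2], truth > 0)

    def test_model_persistence_round_trip(self, tmp_path, rng):
        rasters, truth = self._stack_with_classes()
        model = self._fitted_model(rng, rasters, truth)
        save_model(model, tmp_path / "model.joblib")
        back = load_model(tmp_path / "model.joblib")
        assert back.feature_names == model.feature_names
        X = np.linspace(5, 65, 6 * 4).reshape(4, 6)
        assert np.array_equal(back.predict(X), model.predict(X))
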