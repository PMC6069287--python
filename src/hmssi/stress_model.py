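"""Multitemporal stress-level classification with random forests.

Per-pixel HMSSI values from the acquisitions of one or more growth stages
form the feature vector; a random forest (500 trees, mtry = floor(sqrt(p)))
predicts the three-level stress label. Accuracy is assessed on a stratified
holdout with the usual remote-sensing confusion-matrix statistics (overall
accuracy, Cohen's kappa, per-class user's/producer's accuracy), with the
forest's out-of-bag error reported alongside. Fitted models classify whole
rasters inside a rice mask and summarise class areas.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from ._geotiff import read_geotiff, write_geotiff
from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateLabelsError,
    InputError,
    SchemaError,
)
from .grids import GridGeometry
from .raster_core import CLASS_CODES, CODE_TO_LEVEL, GrowthStage, StressLevel
from .spectral_indices import IndexRaster

logger = logging.getLogger(__name__)

__all__ = [
    "LEVEL_ORDER",
    "FeatureTable",
    "RFConfig",
    "ClassificationAssessment",
    "AreaSummary",
    "StressModel",
    "build_feature_table",
    "train_model",
    "assess",
    "variable_importance",
    "classify_raster",
    "area_percentages",
    "write_classified_map",
    "read_classified_map",
    "save_model",
    "load_model",
]

#: Fixed class order for confusion matrices and vote tie-breaking.
LEVEL_ORDER = (StressLevel.HIGH, StressLevel.MEDIUM, StressLevel.LOW)
_LEVEL_TO_CODE = {lv: i for i, lv in enumerate(LEVEL_ORDER)}


@dataclass
class FeatureTable:
    """Per-pixel HMSSI features across acquisitions, with stress labels.

    Columns are ordered chronologically; rows with any invalid feature were
    dropped at build time (count in ``n_dropped``).
    """

    X: np.ndarray
    y: np.ndarray  # StressLevel values as strings
    feature_names: list[str]
    stage_subset: tuple[GrowthStage, ...]
    n_dropped: int = 0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise InputError("X must be (n, p) with one label per row")
        if self.X.shape[1] != len(self.feature_names):
            raise InputError("feature_names length must match X columns")
        if not np.all(np.isfinite(self.X)):
            raise InputError("feature table contains non-finite values")
        bad = set(map(str, self.y)) - {lv.value for lv in LEVEL_ORDER}
        if bad:
            raise InputError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class RFConfig:
    """Random-forest and validation settings.

    ntree=500 and mtry = floor(sqrt(p)) follow common remote-sensing
    practice for this model; the stratified holdout default is 30%.
    """

    ntree: int = 500
    mtry_rule: str = "sqrt_p"  # or "explicit"
    mtry_value: int | None = None
    seed: int = 0
    holdout_fraction: float = 0.3
    stratified: bool = True

    def mtry(self, p: int) -> int:
        if self.mtry_rule == "explicit":
            if self.mtry_value is None:
                raise ConfigurationError("mtry_rule='explicit' needs mtry_value")
            m = int(self.mtry_value)
        elif self.mtry_rule == "sqrt_p":
            m = max(1, math.floor(math.sqrt(p)))
        else:
            raise ConfigurationError(f"unknown mtry_rule {self.mtry_rule!r}")
        if m > p:
            raise ConfigurationError(f"mtry {m} exceeds feature count {p}")
        return m


@dataclass
class ClassificationAssessment:
    """Confusion matrix (rows = reference, cols = predicted) and derived scores.

    Per-class user's/producer's accuracy are NaN for classes absent from the
    corresponding matrix margin.
    """

    confusion_matrix: np.ndarray
    overall_accuracy: float
    kappa: float
    users_accuracy: dict[StressLevel, float]
    producers_accuracy: dict[StressLevel, float]
    oob_error: float | None = None
    variable_importance: dict[str, float] | None = None
    class_order: tuple[StressLevel, ...] = LEVEL_ORDER

    def to_dict(self) -> dict:
        def _per_class(d):
            return {
                lv.value: (None if np.isnan(v) else float(v)) for lv, v in d.items()
            }

        return {
            "class_order": [lv.value for lv in self.class_order],
            "confusion_matrix": self.confusion_matrix.astype(int).tolist(),
            "overall_accuracy": float(self.overall_accuracy),
            "kappa": float(self.kappa),
            "users_accuracy": _per_class(self.users_accuracy),
            "producers_accuracy": _per_class(self.producers_accuracy),
            "oob_error": None if self.oob_error is None else float(self.oob_error),
            "variable_importance": self.variable_importance,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class AreaSummary:
    """Pixel counts and percentages of classified rice pixels per level."""

    pixel_counts: dict[StressLevel, int]

    @property
    def total(self) -> int:
        return sum(self.pixel_counts.values())

    def percentages(self) -> dict[StressLevel, float]:
        if self.total == 0:
            raise InputError("no classified pixels to summarise")
        return {lv: 100.0 * n / self.total for lv, n in self.pixel_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        return pd.DataFrame(
            {
                "class": [lv.value for lv in LEVEL_ORDER],
                "pixels": [self.pixel_counts.get(lv, 0) for lv in LEVEL_ORDER],
                "percent": [round(pct.get(lv, 0.0), 2) for lv in LEVEL_ORDER],
            }
        )


def build_feature_table(
    hmssi_rasters: list[IndexRaster],
    pixels: np.ndarray,
    labels,
    stage_subset=None,
) -> FeatureTable:
    """Assemble per-pixel features from HMSSI rasters of the requested stages.

    One column per raster whose growth stage is in ``stage_subset`` (all
    stages when None), ordered chronologically. ``pixels`` is (n, 2)
    row/col; ``labels`` the matching stress levels. Rows with any nodata
    feature are dropped and counted.
    """
    if stage_subset is not None:
        stage_subset = tuple(GrowthStage(s) for s in stage_subset)
        selected = [r for r in hmssi_rasters if r.growth_stage in stage_subset]
        for stage in stage_subset:
            if not any(r.growth_stage is stage for r in selected):
                raise ConfigurationError(f"no raster for requested stage {stage.value!r}")
    else:
        selected = list(hmssi_rasters)
        stage_subset = tuple(sorted({r.growth_stage for r in selected}, key=lambda s: s.order))
    if not selected:
        raise ConfigurationError("empty stage subset")
    selected.sort(key=lambda r: r.source_date)
    geom = selected[0].geom
    for r in selected[1:]:
        if not r.geom.almost_equals(geom):
            raise AlignmentError("HMSSI rasters do not share a grid")

    pixels = np.asarray(pixels, dtype=int)
    labels = np.asarray([StressLevel(str(l)).value for l in labels], dtype=object)
    if pixels.shape[0] != labels.shape[0]:
        raise InputError("pixels and labels must have equal length")
    cols = [r.masked_values()[pixels[:, 0], pixels[:, 1]] for r in selected]
    X = np.column_stack(cols)
    keep = np.all(np.isfinite(X), axis=1)
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped:
        logger.info("build_feature_table: dropped %d rows with invalid features", n_dropped)
    return FeatureTable(
        X=X[keep],
        y=labels[keep],
        feature_names=[r.source_date.isoformat() for r in selected],
        stage_subset=stage_subset,
        n_dropped=n_dropped,
    )


def _po_pe(matrix: np.ndarray) -> tuple[float, float]:
    n = matrix.sum()
    po = np.trace(matrix) / n
    pe = float((matrix.sum(axis=1) * matrix.sum(axis=0)).sum()) / (n * n)
    return float(po), pe


def assess(reference, predicted) -> ClassificationAssessment:
    """Confusion-matrix assessment of predicted vs reference stress labels.

    Overall accuracy is trace/total; kappa is Cohen's, with expected
    agreement pe = sum_i(row_i * col_i)/n^2 from the full matrix; user's
    (column-wise) and producer's (row-wise) accuracies are per class.
    """
    ref = np.asarray([StressLevel(str(l)).value for l in reference], dtype=object)
    pred = np.asarray([StressLevel(str(l)).value for l in predicted], dtype=object)
    if ref.shape[0] != pred.shape[0]:
        raise InputError(f"length mismatch: {ref.shape[0]} reference vs {pred.shape[0]} predicted")
    if ref.shape[0] == 0:
        raise InputError("empty label vectors")
    k = len(LEVEL_ORDER)
    matrix = np.zeros((k, k), dtype=int)
    for r, p in zip(ref, pred):
        matrix[_LEVEL_TO_CODE[StressLevel(r)], _LEVEL_TO_CODE[StressLevel(p)]] += 1
    po, pe = _po_pe(matrix)
    kappa = 1.0 if po == 1.0 else (po - pe) / (1.0 - pe) if pe < 1.0 else 0.0
    col_tot = matrix.sum(axis=0)
    row_tot = matrix.sum(axis=1)
    users = {}
    producers = {}
    for lv, i in _LEVEL_TO_CODE.items():
        users[lv] = matrix[i, i] / col_tot[i] if col_tot[i] > 0 else float("nan")
        producers[lv] = matrix[i, i] / row_tot[i] if row_tot[i] > 0 else float("nan")
    return ClassificationAssessment(
        confusion_matrix=matrix,
        overall_accuracy=po,
        kappa=float(kappa),
        users_accuracy=users,
        producers_accuracy=producers,
    )


@dataclass
class StressModel:
    """A fitted forest plus the schema needed to apply it to rasters."""

    forest: RandomForestClassifier
    feature_names: list[str]
    stage_subset: tuple[GrowthStage, ...]
    config: RFConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"model expects {len(self.feature_names)} features "
                f"({self.feature_names}), got shape {X.shape}"
            )
        codes = self.forest.predict(X)
        return np.array([LEVEL_ORDER[int(c)].value for c in codes], dtype=object)


def train_model(table: FeatureTable, config: RFConfig) -> tuple[StressModel, ClassificationAssessment]:
    """Fit the forest and assess it on a stratified holdout.

    Labels are encoded in the fixed class order (high, medium, low) so
    probability ties in forest voting break deterministically by that
    order. OOB error (from the training split) rides along in the
    assessment. Deterministic for a fixed config seed.
    """
    if len(table) == 0:
        raise InputError("empty feature table")
    classes = sorted(set(map(str, table.y)))
    if len(classes) < 2:
        raise DegenerateLabelsError(f"need >= 2 classes, got {classes}")
    y_codes = np.array([_LEVEL_TO_CODE[StressLevel(str(l))] for l in table.y])
    X_train, X_test, y_train, y_test = train_test_split(
        table.X,
        y_codes,
        test_size=config.holdout_fraction,
        random_state=config.seed,
        stratify=y_codes if config.stratified else None,
    )
    p = table.X.shape[1]
    forest = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=config.mtry(p),
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
        bootstrap=True,
    )
    logger.info(
        "training RF: ntree=%d mtry=%d holdout=%.0f%% stratified=%s seed=%d",
        config.ntree, config.mtry(p), 100 * config.holdout_fraction, config.stratified, config.seed,
    )
    import warnings

    with warnings.catch_warnings():
        # tiny training sets can leave a few rows never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        forest.fit(X_train, y_train)
    model = StressModel(
        forest=forest,
        feature_names=list(table.feature_names),
        stage_subset=table.stage_subset,
        config=config,
    )
    ref = [LEVEL_ORDER[int(c)].value for c in y_test]
    pred = model.predict(X_test)
    assessment = assess(ref, pred)
    assessment.oob_error = float(1.0 - forest.oob_score_)
    assessment.variable_importance = variable_importance(model)
    return model, assessment


def variable_importance(model: StressModel, kind: str = "impurity", table: FeatureTable | None = None,
                        n_repeats: int = 10) -> dict[str, float]:
    """Per-feature importance scores.

    Default is the forest's mean impurity decrease, normalised to sum to 1.
    ``kind='permutation'`` computes permutation importance on a supplied
    feature table instead (not normalised; may be negative).
    """
    if not hasattr(model.forest, "estimators_") or not model.forest.estimators_:
        raise InputError("model is not fitted")
    if kind == "impurity":
        scores = np.asarray(model.forest.feature_importances_, dtype=float)
        total = scores.sum()
        if total > 0:
            scores = scores / total
        return dict(zip(model.feature_names, scores.tolist()))
    if kind == "permutation":
        if table is None:
            raise InputError("permutation importance needs a feature table")
        y_codes = np.array([_LEVEL_TO_CODE[StressLevel(str(l))] for l in table.y])
        result = permutation_importance(
            model.forest, table.X, y_codes, n_repeats=n_repeats,
            random_state=model.config.seed,
        )
        return dict(zip(model.feature_names, result.importances_mean.tolist()))
    raise ConfigurationError(f"unknown importance kind {kind!r}")


def classify_raster(
    model: StressModel,
    hmssi_rasters: list[IndexRaster],
    rice_mask: np.ndarray,
) -> tuple[np.ndarray, AreaSummary]:
    """Classify every rice pixel from a chronological HMSSI raster stack.

    Returns an 8-bit coded map (0 nodata, 1 high, 2 medium, 3 low) and the
    area summary over classified pixels. Pixels with any invalid feature
    are nodata and excluded from the summary denominator.
    """
    rasters = sorted(hmssi_rasters, key=lambda r: r.source_date)
    names = [r.source_date.isoformat() for r in rasters]
    if names != list(model.feature_names):
        raise SchemaError(
            f"raster stack dates {names} do not match model features {model.feature_names}"
        )
    geom = rasters[0].geom
    for r in rasters[1:]:
        if not r.geom.almost_equals(geom):
            raise AlignmentError("HMSSI rasters do not share a grid")
    rice_mask = np.asarray(rice_mask, dtype=bool)
    if rice_mask.shape != geom.shape:
        raise AlignmentError("rice mask shape does not match raster grid")

    stack = np.stack([r.masked_values() for r in rasters])  # (p, rows, cols)
    valid = rice_mask & np.all(np.isfinite(stack), axis=0)
    coded = np.zeros(geom.shape, dtype=np.uint8)
    if valid.any():
        X = stack[:, valid].T
        pred = model.predict(X)
        coded[valid] = [CLASS_CODES[StressLevel(p)] for p in pred]
    counts = {
        lv: int(np.count_nonzero(coded == code)) for lv, code in CLASS_CODES.items()
    }
    return coded, AreaSummary(pixel_counts=counts)


def area_percentages(coded_map: np.ndarray) -> AreaSummary:
    """Area summary recomputed from a coded classification map."""
    coded_map = np.asarray(coded_map)
    counts = {lv: int(np.count_nonzero(coded_map == code)) for lv, code in CLASS_CODES.items()}
    return AreaSummary(pixel_counts=counts)


def write_classified_map(coded_map: np.ndarray, geom: GridGeometry, path) -> None:
    write_geotiff(
        path,
        np.asarray(coded_map, dtype=np.uint8),
        geom,
        nodata=0,
        metadata={"class_codes": {lv.value: c for lv, c in CLASS_CODES.items()}},
    )


def read_classified_map(path) -> tuple[np.ndarray, GridGeometry]:
    array, geom, _nodata, _meta = read_geotiff(path)
    return array.astype(np.uint8), geom


def save_model(model: StressModel, path) -> None:
    """Persist the model with its schema to a single binary artifact."""
    payload = {
        "schema_version": 1,
        "feature_names": model.feature_names,
        "stage_subset": [s.value for s in model.stage_subset],
        "config": model.config.__dict__,
        "class_order": [lv.value for lv in LEVEL_ORDER],
        "class_codes": {lv.value: c for lv, c in CLASS_CODES.items()},
        "forest": model.forest,
    }
    joblib.dump(payload, path)


def load_model(path) -> StressModel:
    payload = joblib.load(path)
    if payload.get("schema_version") != 1:
        raise SchemaError(f"unsupported model schema: {payload.get('schema_version')}")
    return StressModel(
        forest=payload["forest"],
        feature_names=list(payload["feature_names"]),
        stage_subset=tuple(GrowthStage(s) for s in payload["stage_subset"]),
        config=RFConfig(**payload["config"]),
    )
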