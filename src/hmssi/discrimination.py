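"""Separability of stress levels by an index: ranges, overlaps, misjudgment.

For one index on one acquisition, each stress class contributes the sampled
index values of its pixels. A class's *range* is the closed [min, max]
interval of its samples (optionally percentile-trimmed); its *overlap
region* is the union of intersections of its range with the other classes'
ranges; and its *misjudgment rate* is the fraction of its samples falling
inside that overlap region — samples that could equally belong to another
class on value alone. Lower rates mean better separation.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .raster_core import GrowthStage, StressLevel
from .spectral_indices import IndexKind, IndexRaster

__all__ = [
    "ClassSampleSet",
    "OverlapReport",
    "class_ranges",
    "overlap_region",
    "misjudgment_rate",
    "class_samples_from_raster",
    "discrimination_report",
    "REPORT_COLUMNS",
]

LEVELS = (StressLevel.HIGH, StressLevel.MEDIUM, StressLevel.LOW)
REPORT_COLUMNS = ["index", "stage", "date", "class", "n", "misjudged", "rate_percent"]


@dataclass
class ClassSampleSet:
    """Per-class index samples for one index on one acquisition date.

    Non-finite (guarded/invalid) values are excluded from the samples at
    construction and counted per class in ``n_invalid``.
    """

    index_kind: IndexKind
    growth_stage: GrowthStage
    acquisition_date: _dt.date
    samples: dict[StressLevel, np.ndarray]
    n_invalid: dict[StressLevel, int] = field(default_factory=dict)

    def __post_init__(self):
        cleaned = {}
        for level in LEVELS:
            if level not in self.samples:
                raise InputError(f"missing samples for class {level.value!r}")
            values = np.asarray(self.samples[level], dtype=float).ravel()
            finite = values[np.isfinite(values)]
            self.n_invalid.setdefault(level, int(values.size - finite.size))
            if finite.size == 0:
                raise InputError(f"class {level.value!r} has no finite samples")
            cleaned[level] = finite
        self.samples = cleaned


@dataclass(frozen=True)
class ClassOverlap:
    """One class's row of an overlap report."""

    stress_level: StressLevel
    class_range: tuple[float, float]
    overlap_region: tuple[tuple[float, float], ...]
    misjudged_count: int
    sample_count: int

    @property
    def misjudgment_rate(self) -> float:
        return self.misjudged_count / self.sample_count


@dataclass(frozen=True)
class OverlapReport:
    """Misjudgment statistics for all three classes of one sample set."""

    index_kind: IndexKind
    growth_stage: GrowthStage
    acquisition_date: _dt.date
    per_class: dict[StressLevel, ClassOverlap]

    def rates(self) -> dict[StressLevel, float]:
        return {lv: co.misjudgment_rate for lv, co in self.per_class.items()}


def class_ranges(
    samples: ClassSampleSet, trim_percent: float = 0.0
) -> dict[StressLevel, tuple[float, float]]:
    """Closed [min, max] interval of each class's samples.

    ``trim_percent`` > 0 uses the [p, 100-p] percentiles instead of the full
    range; the default (0, full range) mirrors distribution-envelope overlap
    plots.
    """
    if not 0.0 <= trim_percent < 50.0:
        raise InputError("trim_percent must be in [0, 50)")
    out = {}
    for level, values in samples.samples.items():
        if values.size < 2:
            raise InputError(f"class {level.value!r} needs >= 2 finite samples, has {values.size}")
        if trim_percent > 0:
            lo, hi = np.percentile(values, [trim_percent, 100.0 - trim_percent])
        else:
            lo, hi = float(values.min()), float(values.max())
        out[level] = (float(lo), float(hi))
    return out


def _merge_intervals(intervals: list[tuple[float, float]]) -> tuple[tuple[float, float], ...]:
    """Normalise closed intervals to a disjoint, sorted union."""
    if not intervals:
        return ()
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:  # closed intervals: touching endpoints merge
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return tuple((lo, hi) for lo, hi in merged)


def overlap_region(
    target_class: StressLevel, ranges: dict[StressLevel, tuple[float, float]]
) -> tuple[tuple[float, float], ...]:
    """Union over other classes of the intersection with the target's range."""
    missing = [lv.value for lv in LEVELS if lv not in ranges]
    if missing:
        raise InputError(f"ranges missing classes: {missing}")
    t_lo, t_hi = ranges[target_class]
    pieces = []
    for level, (lo, hi) in ranges.items():
        if level is target_class:
            continue
        ilo, ihi = max(t_lo, lo), min(t_hi, hi)
        if ilo <= ihi:
            pieces.append((ilo, ihi))
    return _merge_intervals(pieces)


def _in_region(values: np.ndarray, region: tuple[tuple[float, float], ...]) -> np.ndarray:
    inside = np.zeros(values.shape, dtype=bool)
    for lo, hi in region:
        inside |= (values >= lo) & (values <= hi)  # closed-interval membership
    return inside


def misjudgment_rate(samples: ClassSampleSet, trim_percent: float = 0.0) -> OverlapReport:
    """Per-class misjudgment rates of one index on one acquisition.

    A sample is misjudged if it lies inside the overlap of its class's range
    with any other class's range (closed intervals; boundary samples count
    as misjudged).
    """
    ranges = class_ranges(samples, trim_percent=trim_percent)
    per_class = {}
    for level, values in samples.samples.items():
        region = overlap_region(level, ranges)
        misjudged = int(np.count_nonzero(_in_region(values, region)))
        per_class[level] = ClassOverlap(
            stress_level=level,
            class_range=ranges[level],
            overlap_region=region,
            misjudged_count=misjudged,
            sample_count=int(values.size),
        )
    return OverlapReport(
        index_kind=samples.index_kind,
        growth_stage=samples.growth_stage,
        acquisition_date=samples.acquisition_date,
        per_class=per_class,
    )


def class_samples_from_raster(
    raster: IndexRaster, pixels_by_level: dict[StressLevel, np.ndarray]
) -> ClassSampleSet:
    """Collect per-class samples of an index raster at given (row, col) pixels."""
    samples = {}
    for level, pixels in pixels_by_level.items():
        pixels = np.asarray(pixels, dtype=int)
        samples[StressLevel(level)] = raster.masked_values()[pixels[:, 0], pixels[:, 1]]
    return ClassSampleSet(
        index_kind=raster.index_kind,
        growth_stage=raster.growth_stage,
        acquisition_date=raster.source_date,
        samples=samples,
    )


def discrimination_report(
    rasters: list[IndexRaster],
    pixels_by_level: dict[StressLevel, np.ndarray],
    trim_percent: float = 0.0,
) -> pd.DataFrame:
    """Misjudgment-rate table over index rasters: one row per raster x class.

    All requested rasters are evaluated at the same class pixel sets.
    Rates are kept at full precision in ``rate`` and rounded to whole
    percents in ``rate_percent`` for the CSV layout.
    """
    if not rasters:
        raise ConfigurationError("no index rasters supplied")
    rows = []
    for raster in sorted(rasters, key=lambda r: (r.index_kind.value, r.source_date)):
        sset = class_samples_from_raster(raster, pixels_by_level)
        report = misjudgment_rate(sset, trim_percent=trim_percent)
        for level in LEVELS:
            co = report.per_class[level]
            rows.append(
                {
                    "index": raster.index_kind.value,
                    "stage": raster.growth_stage.value,
                    "date": raster.source_date.isoformat(),
                    "class": level.value,
                    "n": co.sample_count,
                    "misjudged": co.misjudged_count,
                    "rate": co.misjudgment_rate,
                    "rate_percent": int(round(100.0 * co.misjudgment_rate)),
                }
            )
    return pd.DataFrame(rows)


def write_report_csv(report: pd.DataFrame, path) -> None:
    report[REPORT_COLUMNS].to_csv(path, index=False, lineterminator="\n")
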