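"""Synthetic multitemporal reflectance campaigns with known stress structure.

The generator emulates the data layout of a three-area rice campaign:
six acquisition dates spanning three growth stages, three 1 km x 1 km study
areas at high/medium/low heavy-metal stress, a rice mask, and labelled
sample plots.

Stress enters in index space rather than through a canopy radiative
transfer model: each class has per-stage target means for CI_red-edge
(decreasing with stress) and PSRI (increasing with stress). Per pixel and
date, a shared mean-one lognormal factor f (illumination-like, log-sd
``shared_sigma``) and independent mean-one lognormal factors e_ci, e_psri
perturb the targets multiplicatively:

    CI = target_CI * f * e_ci        PSRI = target_PSRI * f * e_psri

so HMSSI = CI/PSRI = (target_CI/target_PSRI) * e_ci/e_psri — the shared
factor cancels in the ratio, which is exactly the mechanism that makes
the ratio index separate classes that the single indices cannot. Bands are
then back-solved (r783 from CI at fixed r705, r680 from PSRI at fixed
r500, r750) so the full band-level index chain is exercised end to end.
"""
from __future__ import annotations

import datetime as _dt
import importlib.resources
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._geotiff import write_geotiff
from .discrimination import class_samples_from_raster, misjudgment_rate
from .errors import CalibrationError, ConfigurationError, SamplingError
from .grids import GridGeometry
from .raster_core import (
    BandMap,
    GrowthStage,
    PlotTable,
    ReflectanceScene,
    StressLevel,
    sample_random_mask_pixels,
    write_scene,
)
from .spectral_indices import IndexKind, compute_index_raster

logger = logging.getLogger(__name__)

__all__ = [
    "StressClassSpec",
    "CampaignConfig",
    "GroundTruthBundle",
    "default_campaign_config",
    "generate_campaign",
    "generate_plots",
    "calibrate_to_misjudgment",
    "write_bundle",
]

LEVELS = (StressLevel.HIGH, StressLevel.MEDIUM, StressLevel.LOW)
AREA_LABELS = {StressLevel.HIGH: "A", StressLevel.MEDIUM: "B", StressLevel.LOW: "C"}


@dataclass(frozen=True)
class StressClassSpec:
    """Index-space targets and noise levels for one stress class.

    ``targets`` maps growth stage -> (mean CI, mean PSRI). Targets must be
    positive; PSRI targets are kept strictly positive so the multiplicative
    noise model stays well defined (the index code itself still handles
    negative PSRI).
    """

    stress_level: StressLevel
    targets: dict[GrowthStage, tuple[float, float]]
    cv_ci: float = 0.10
    cv_psri: float = 0.10
    shared_sigma: float = 0.15

    def __post_init__(self):
        for stage, (ci, psri) in self.targets.items():
            if ci <= 0 or psri <= 0:
                raise ConfigurationError(
                    f"{self.stress_level.value}/{stage.value}: targets must be > 0"
                )
        if min(self.cv_ci, self.cv_psri, self.shared_sigma) < 0:
            raise ConfigurationError("noise parameters must be >= 0")


@dataclass(frozen=True)
class CampaignConfig:
    """Full recipe for one synthetic campaign."""

    geom: GridGeometry
    areas: dict[StressLevel, tuple[int, int, int, int]]  # row0, col0, h, w
    acquisitions: tuple[tuple[_dt.date, GrowthStage], ...]
    class_specs: dict[StressLevel, StressClassSpec]
    plots_per_area: int = 100
    seed: int = 0
    r705_base: float = 0.04
    r500_base: float = 0.04
    r750_base: float = 0.42
    soil_concentrations: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.areas) != set(LEVELS) or set(self.class_specs) != set(LEVELS):
            raise ConfigurationError("areas and class_specs must cover high/medium/low")
        stages = [s for _, s in self.acquisitions]
        for stage in GrowthStage:
            if stages.count(stage) < 1:
                raise ConfigurationError(f"no acquisition for stage {stage.value!r}")
        dates = [d for d, _ in self.acquisitions]
        if dates != sorted(dates):
            raise ConfigurationError("acquisitions must be in chronological order")
        prev = -1
        for d, s in self.acquisitions:
            if s.order < prev:
                raise ConfigurationError("growth stages out of order along the season")
            prev = s.order
        for level, (r0, c0, h, w) in self.areas.items():
            if r0 < 0 or c0 < 0 or r0 + h > self.geom.rows or c0 + w > self.geom.cols:
                raise ConfigurationError(f"area {level.value!r} exceeds the grid")
            if h * w < self.plots_per_area:
                raise ConfigurationError(
                    f"area {level.value!r} has {h * w} cells < {self.plots_per_area} plots"
                )

    def with_noise(self, shared_sigma=None, cv_ci=None, cv_psri=None) -> "CampaignConfig":
        """Copy with noise parameters replaced on every class spec."""
        specs = {}
        for level, spec in self.class_specs.items():
            specs[level] = replace(
                spec,
                shared_sigma=spec.shared_sigma if shared_sigma is None else shared_sigma,
                cv_ci=spec.cv_ci if cv_ci is None else cv_ci,
                cv_psri=spec.cv_psri if cv_psri is None else cv_psri,
            )
        return replace(self, class_specs=specs)


@dataclass
class GroundTruthBundle:
    """Everything a downstream analysis needs, with known ground truth."""

    scenes: list[ReflectanceScene]
    rice_mask: np.ndarray
    truth_map: np.ndarray  # 0 non-rice, 1 high, 2 medium, 3 low
    plots: PlotTable
    config: CampaignConfig
    metadata: dict = field(default_factory=dict)

    def pixels_by_level(self, n_per_class: int, seed: int) -> dict[StressLevel, np.ndarray]:
        """Seeded uniform pixel samples within each class's area block."""
        from .raster_core import CLASS_CODES

        out = {}
        for i, level in enumerate(LEVELS):
            mask = self.truth_map == CLASS_CODES[level]
            out[level] = sample_random_mask_pixels(mask, n_per_class, seed + 1000 * i)
        return out


def _load_defaults() -> dict:
    text = (importlib.resources.files("hmssi.data") / "synthetic_defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_campaign_config(seed: int = 0, **overrides) -> CampaignConfig:
    """The packaged default campaign (see data/synthetic_defaults.yaml)."""
    cfg = _load_defaults()
    g = cfg["grid"]
    geom = GridGeometry(
        rows=g["rows"], cols=g["cols"], x0=g["x0"], y0=g["y0"],
        resolution=g["resolution_m"], crs=g["crs"],
    )
    areas = {StressLevel(k): tuple(v) for k, v in cfg["areas"].items()}
    acquisitions = tuple(
        (a["date"] if isinstance(a["date"], _dt.date) else _dt.date.fromisoformat(str(a["date"])),
         GrowthStage(a["stage"]))
        for a in cfg["acquisitions"]
    )
    noise = cfg["noise"]
    specs = {}
    for level in LEVELS:
        targets = {
            GrowthStage(stage): (
                float(t["ci"][level.value]),
                float(t["psri"][level.value]),
            )
            for stage, t in cfg["targets"].items()
        }
        specs[level] = StressClassSpec(
            stress_level=level,
            targets=targets,
            cv_ci=float(noise["cv_ci"]),
            cv_psri=float(noise["cv_psri"]),
            shared_sigma=float(noise["shared_sigma"]),
        )
    base = cfg["base_bands"]
    config = CampaignConfig(
        geom=geom,
        areas=areas,
        acquisitions=acquisitions,
        class_specs=specs,
        plots_per_area=int(cfg["plots_per_area"]),
        seed=seed,
        r705_base=float(base["r705"]),
        r500_base=float(base["r500"]),
        r750_base=float(base["r750"]),
        soil_concentrations=cfg.get("soil_concentrations", {}),
    )
    if overrides:
        config = replace(config, **overrides)
    return config


def _mean_one_lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Lognormal factor with E[factor] = 1 (mu = -sigma^2/2)."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _cv_to_sigma(cv: float) -> float:
    """Log-sd of a lognormal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv * cv)))


def generate_campaign(config: CampaignConfig) -> GroundTruthBundle:
    """Generate scenes, mask, truth map and plots for one campaign.

    Deterministic for a fixed config seed. Bands are clipped to [0, 1];
    a configuration whose back-solved bands clip on more than 20% of rice
    pixels is rejected as infeasible.
    """
    from .raster_core import CLASS_CODES

    geom = config.geom
    rng = np.random.default_rng(config.seed)

    truth = np.zeros(geom.shape, dtype=np.uint8)
    for level in LEVELS:
        r0, c0, h, w = config.areas[level]
        truth[r0:r0 + h, c0:c0 + w] = CLASS_CODES[level]
    rice_mask = truth > 0

    band_map = BandMap.sentinel2()
    scenes = []
    n_rice = int(rice_mask.sum())
    total_clipped = 0
    for date, stage in config.acquisitions:
        ci = np.full(geom.shape, np.nan)
        psri = np.full(geom.shape, np.nan)
        # background (non-rice) pixels get low-stress statistics; they are
        # outside the mask and never analysed, but keep bands plausible
        bg_spec = config.class_specs[StressLevel.LOW]
        for level, spec, region in (
            [(None, bg_spec, ~rice_mask)]
            + [(lv, config.class_specs[lv], truth == CLASS_CODES[lv]) for lv in LEVELS]
        ):
            n = int(region.sum())
            if n == 0:
                continue
            t_ci, t_psri = spec.targets[stage]
            f = _mean_one_lognormal(rng, spec.shared_sigma, n)
            e_ci = _mean_one_lognormal(rng, _cv_to_sigma(spec.cv_ci), n)
            e_psri = _mean_one_lognormal(rng, _cv_to_sigma(spec.cv_psri), n)
            ci[region] = t_ci * f * e_ci
            psri[region] = t_psri * f * e_psri

        r705 = np.full(geom.shape, config.r705_base)
        r500 = np.full(geom.shape, config.r500_base)
        r750 = np.full(geom.shape, config.r750_base)
        r783 = (ci + 1.0) * r705
        r680 = psri * r750 + r500
        bands = np.stack([r500, r680, r705, r750, r783])  # B2, B4, B5, B6, B7
        clipped = (bands < 0) | (bands > 1)
        n_clipped = int(np.count_nonzero(clipped.any(axis=0) & rice_mask))
        total_clipped += n_clipped
        if n_clipped:
            logger.info("%s: %d rice pixels clipped to [0, 1]", date, n_clipped)
        bands = np.clip(bands, 0.0, 1.0)
        scenes.append(
            ReflectanceScene(
                bands=bands,
                geom=geom,
                band_map=band_map,
                acquisition_date=date,
                growth_stage=stage,
                nodata_mask=np.zeros(geom.shape, dtype=bool),
            )
        )
    clip_fraction = total_clipped / (n_rice * len(config.acquisitions))
    if clip_fraction > 0.20:
        raise CalibrationError(
            f"band back-out clipped {100 * clip_fraction:.1f}% of rice pixels; "
            "config infeasible (targets or noise too large for the base bands)"
        )

    plots = generate_plots(config, truth)
    metadata = {
        "seed": config.seed,
        "soil_concentrations": config.soil_concentrations,
        "clipped_fraction": clip_fraction,
    }
    return GroundTruthBundle(
        scenes=scenes,
        rice_mask=rice_mask,
        truth_map=truth,
        plots=plots,
        config=config,
        metadata=metadata,
    )


def generate_plots(config: CampaignConfig, truth_map: np.ndarray) -> PlotTable:
    """Uniform seeded sample plots within each study-area block.

    ``plots_per_area`` cells per area, without replacement, labelled from
    the truth map; plot coordinates are the cell centres.
    """
    from .raster_core import CLASS_CODES

    rows = []
    for i, level in enumerate(LEVELS):
        mask = truth_map == CLASS_CODES[level]
        if int(mask.sum()) < config.plots_per_area:
            raise SamplingError(
                f"area {level.value!r} has {int(mask.sum())} cells, "
                f"needs {config.plots_per_area}"
            )
        pixels = sample_random_mask_pixels(mask, config.plots_per_area, config.seed + 7919 * (i + 1))
        x, y = config.geom.cell_center(pixels[:, 0], pixels[:, 1])
        area = AREA_LABELS[level]
        for j in range(pixels.shape[0]):
            rows.append(
                {
                    "plot_id": f"{area}{j + 1:03d}",
                    "x": float(x[j]),
                    "y": float(y[j]),
                    "stress_level": level.value,
                    "area_label": area,
                }
            )
    return PlotTable(pd.DataFrame(rows))


def _misjudgment_cells(config: CampaignConfig, seed: int, n_per_class: int = 100) -> dict:
    """All per-(index, date, class) misjudgment rates for one generated seed."""
    bundle = generate_campaign(replace(config, seed=seed))
    pixels = bundle.pixels_by_level(n_per_class, seed=seed + 31337)
    rates: dict[IndexKind, list[float]] = {k: [] for k in IndexKind}
    for scene in bundle.scenes:
        for kind in IndexKind:
            raster = compute_index_raster(scene, kind)
            sset = class_samples_from_raster(raster, pixels)
            report = misjudgment_rate(sset)
            rates[kind].extend(report.rates().values())
    return rates


def _rate_stats(config: CampaignConfig, seeds) -> dict:
    """Mean over seeds of {min, max, mean} cell rates per index kind."""
    acc = {k: {"min": [], "max": [], "mean": []} for k in IndexKind}
    for seed in seeds:
        cells = _misjudgment_cells(config, seed)
        for kind, values in cells.items():
            acc[kind]["min"].append(min(values))
            acc[kind]["max"].append(max(values))
            acc[kind]["mean"].append(float(np.mean(values)))
    return {
        kind: {stat: float(np.mean(vals)) for stat, vals in stats.items()}
        for kind, stats in acc.items()
    }


def calibrate_to_misjudgment(
    base_config: CampaignConfig,
    hmssi_max_rate: float = 0.30,
    single_index_min_rate: float = 0.80,
    seeds=range(5),
    max_iter: int = 50,
    tol: float = 0.015,
) -> CampaignConfig:
    """Tune generator noise until misjudgment rates sit in requested regimes.

    Two nested bisections, exploiting that the knobs are separable:

    1. the independent per-index CV controls HMSSI misjudgment (the shared
       factor cancels in the ratio) — bisect until the worst (max) HMSSI
       cell rate, averaged over seeds, reaches ``hmssi_max_rate``;
    2. the shared illumination sigma inflates CI and PSRI spread without
       touching HMSSI — bisect until the best-separated (min) CI/PSRI cell
       rate reaches ``single_index_min_rate``.

    Rates are evaluated on freshly generated campaigns over ``seeds`` and
    are monotone in both knobs on average, which bisection requires.
    """
    seeds = list(seeds)

    def hmssi_max(cv: float) -> float:
        cfg = base_config.with_noise(cv_ci=cv, cv_psri=cv)
        return _rate_stats(cfg, seeds)[IndexKind.HMSSI]["max"]

    lo, hi = 0.005, 0.60
    if hmssi_max(hi) < hmssi_max_rate:
        raise CalibrationError("HMSSI rate target unreachable: too high even at cv=0.6")
    cv = hi
    for _ in range(max_iter):
        cv = 0.5 * (lo + hi)
        rate = hmssi_max(cv)
        if abs(rate - hmssi_max_rate) < tol:
            break
        if rate < hmssi_max_rate:
            lo = cv
        else:
            hi = cv
    else:
        raise CalibrationError(
            f"cv bisection did not converge in {max_iter} iterations (last cv={cv:.4f})"
        )
    logger.info("calibrated independent cv=%.4f (HMSSI max rate ~%.3f)", cv, hmssi_max_rate)

    def single_min(sigma: float) -> float:
        cfg = base_config.with_noise(shared_sigma=sigma, cv_ci=cv, cv_psri=cv)
        stats = _rate_stats(cfg, seeds)
        return min(stats[IndexKind.CI_REDEDGE]["min"], stats[IndexKind.PSRI]["min"])

    lo_s, hi_s = 0.02, 1.0
    if single_min(hi_s) < single_index_min_rate:
        raise CalibrationError("CI/PSRI rate target unreachable even at sigma=1.0")
    sigma = hi_s
    if single_min(lo_s) < single_index_min_rate:
        for _ in range(max_iter):
            sigma = 0.5 * (lo_s + hi_s)
            rate = single_min(sigma)
            if abs(rate - single_index_min_rate) < tol:
                break
            if rate < single_index_min_rate:
                lo_s = sigma
            else:
                hi_s = sigma
        else:
            raise CalibrationError(
                f"sigma bisection did not converge in {max_iter} iterations"
            )
    else:
        sigma = lo_s
    logger.info("calibrated shared sigma=%.4f (CI/PSRI min rate ~%.3f)", sigma, single_index_min_rate)
    return base_config.with_noise(shared_sigma=sigma, cv_ci=cv, cv_psri=cv)


def write_bundle(bundle: GroundTruthBundle, outdir) -> dict:
    """Write scenes, mask, truth map, plots and a JSON manifest to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": bundle.config.seed,
        "crs": bundle.config.geom.crs,
        "scenes": [],
        "rice_mask": "rice_mask.tif",
        "truth_map": "truth_map.tif",
        "plots": "plots.csv",
        "soil_concentrations": bundle.config.soil_concentrations,
    }
    for scene in bundle.scenes:
        name = f"scene_{scene.acquisition_date.isoformat()}.tif"
        write_scene(scene, outdir / name)
        manifest["scenes"].append(
            {
                "path": name,
                "date": scene.acquisition_date.isoformat(),
                "stage": scene.growth_stage.value,
            }
        )
    write_geotiff(outdir / "rice_mask.tif", bundle.rice_mask.astype(np.uint8),
                  bundle.config.geom, nodata=None, metadata={"kind": "rice_mask"})
    write_geotiff(outdir / "truth_map.tif", bundle.truth_map, bundle.config.geom,
                  nodata=0, metadata={"kind": "truth_map"})
    bundle.plots.to_csv(outdir / "plots.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
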