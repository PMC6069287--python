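"""Generate a synthetic six-date campaign and inspect per-class index means.

Three 1 km x 1 km study areas (high/medium/low heavy-metal stress) are
observed on six dates across booting, flowering and mature stages. Stress
enters as index-space targets; bands are back-solved so the full band-level
chain is exercised.
"""
import numpy as np

from hmssi import IndexKind, StressLevel, compute_index_raster, default_campaign_config, generate_campaign
from hmssi.raster_core import CLASS_CODES

bundle = generate_campaign(default_campaign_config(seed=42))
print(f"{len(bundle.scenes)} scenes, {int(bundle.rice_mask.sum())} rice pixels, "
      f"{len(bundle.plots)} labelled plots\n")

print(f"{'date':12s} {'stage':10s}", *(f"{k.value:>22s}" for k in IndexKind))
for scene in bundle.scenes:
    row = [f"{scene.acquisition_date} {scene.growth_stage.value:10s}"]
    for kind in IndexKind:
        values = compute_index_raster(scene, kind).values
        means = [
            values[bundle.truth_map == CLASS_CODES[lv]].mean()
            for lv in (StressLevel.HIGH, StressLevel.MEDIUM, StressLevel.LOW)
        ]
        row.append(" ".join(f"{m:7.2f}" for m in means))
    print("  ".join(row))

print("\nColumns per index are the class means for high/medium/low stress:")
print("CI_red-edge increases from high to low stress, PSRI decreases, and")
print("HMSSI (their ratio) separates the classes by a much wider margin.")
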