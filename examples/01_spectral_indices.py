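"""Compute the three red-edge indices from a handful of band reflectances.

CI_red-edge rises with chlorophyll (falls under stress), PSRI rises with
senescence (rises under stress); their ratio HMSSI amplifies the contrast.
"""
from hmssi import compute_ci, compute_hmssi, compute_psri

# reflectances for a healthy and a stressed rice canopy (unitless, 0..1)
canopies = {
    "healthy": dict(r783=0.32, r705=0.062, r680=0.075, r500=0.040, r750=0.42),
    "stressed": dict(r783=0.22, r705=0.068, r680=0.120, r500=0.040, r750=0.40),
}

for name, b in canopies.items():
    ci = compute_ci(b["r783"], b["r705"])
    psri = compute_psri(b["r680"], b["r500"], b["r750"])
    hmssi = compute_hmssi(ci, psri)
    print(f"{name:9s} CI_red-edge={ci.value:6.3f}  PSRI={psri.value:6.3f}  HMSSI={hmssi.value:7.2f}")

print()
print("The stressed canopy has lower CI (less chlorophyll) and higher PSRI")
print("(more senescence); HMSSI compounds both, so the healthy:stressed HMSSI")
print("ratio is much larger than either single-index ratio.")
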