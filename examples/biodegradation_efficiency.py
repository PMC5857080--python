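"""Quantify n-alkane loss from GC-FID peak tables.

A C8-C20 chromatogram pair (abiotic control vs 7-day culture) is
simulated with known per-alkane reductions, matched to the standard
ladder by retention time, and scored as biodegradation efficiency
BE(%) = 100 - A_sample * 100 / A_control per alkane and pooled.
"""

from rsmdeg import ChromSimSpec, be_table, simulate_chromatograms
from rsmdeg.simulate import ALKANES

# strong removal of the shorter alkanes, weak on the long tail --
# the profile of an optimised dodecane-degrading culture
reductions = {a: min(1.0, max(0.0, 1.0 - 0.09 * (int(a[3:]) - 9)))
              for a in ALKANES}
reductions["n-C12"] = 0.9989  # validated optimum culture's dodecane loss

spec = ChromSimSpec(
    control_areas={a: 20.0 for a in ALKANES},
    reductions=reductions,
    area_noise_cv=0.0,
    seed=11,
)
control, sample, standard = simulate_chromatograms(spec)
result = be_table(sample, control, standard, rt_tol=0.05)

print(result.rows[["alkane", "a_ac", "a_s", "be_percent"]]
      .to_string(index=False, float_format=lambda v: f"{v:9.3f}"))
print(f"\nTotal BE over the ladder: {result.total_be_percent:.2f}%")
print("BE(n-C12) = 99.89% reads as near-complete dodecane removal "
      "relative to the abiotic control.")
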