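"""Fit the zone model on labeled (wt, delta) scores.

Four Gaussian clouds emulate how pathogenic-enriched and benign-enriched
variants separate in the (wt, delta) plane. The WSS elbow confirms four
clusters; zones A-D are named by descending pathogenic fraction and
frozen into axis-aligned thresholds; A/B map to PM1, D to BP8, C to no
evidence.
"""

from dolphin.fixtures import ScoreCloudSpec, generate_score_cloud
from dolphin.zones import assign_zone, evidence_label, fit_zones, wss_curve

points, _ = generate_score_cloud(ScoreCloudSpec(seed=5))
curve, suggested_k = wss_curve(points, range(1, 9), seed=5)
print("k :", "  ".join(f"{k}" for k, _ in curve))
print("WSS:", " ".join(f"{w:7.0f}" for _, w in curve))
print(f"elbow suggests k = {suggested_k}")

model = fit_zones(points, k=4, seed=5)
for zone in "ABCD":
    comp = model.training_composition[zone]
    total = comp["pathogenic"] + comp["benign"]
    print(f"zone {zone}: {100 * comp['pathogenic'] / total:4.1f}% pathogenic "
          f"(n={total})  evidence={evidence_label(model, zone)}")

for wt, delta in [(5.0, -10.0), (0.1, -0.2), (2.0, -3.0)]:
    zone = assign_zone(model, (wt, delta))
    print(f"(wt={wt:+.1f}, delta={delta:+.1f}) -> zone {zone} "
          f"-> {evidence_label(model, zone)}")
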