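"""Score a single prehospital observation set with NEWS2 and NEWS2-L.

A 74-year-old found after syncope: mildly tachypnoeic, borderline
saturation, hypothermic-ish, hypotensive, confused (GCS 14), venous
lactate 3.4 mmol/L.
"""

from news2l import VitalSigns, compute_news2, compute_news2_l

vitals = VitalSigns(
    respiratory_rate=22,
    spo2=93,
    on_supplemental_oxygen=False,
    temperature=35.7,
    systolic_bp=105,
    heart_rate=82,
    gcs=14,
)

breakdown = compute_news2(vitals)
composite = compute_news2_l(breakdown.total, lactate=3.4)

print("per-parameter weights:")
for name, weight in breakdown.sub_scores.items():
    print(f"  {name:<20} {weight}")
print(f"NEWS2 total        : {breakdown.total}")
print(f"any single 3       : {breakdown.any_single_three}")
print(f"urgent review (>5 or single 3): {breakdown.urgent_review}")
print(f"critical review (>7)          : {breakdown.critical_review}")
print(f"NEWS2-L (total + lactate)     : {composite.news2_l:.1f}")

# The total of 9 exceeds both escalation thresholds: this patient would
# trigger a critical-care review.  Adding the lactate pushes the composite
# to 12.4, above the 9.5 mortality cut-off reported for this score.
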