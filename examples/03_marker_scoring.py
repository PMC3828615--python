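"""Score one marker's diagnostic value: Sn, Sp and AUC = (Sp + Sn)/2.

Sensitivity is the fraction of tumor samples crossing the fold cut in the
marker's published direction; specificity uses leave-one-out ratios among
the normal samples; markers are conventionally called valuable when the
(Sp+Sn)/2 summary exceeds 0.7.
"""

from mirmarker import RatioProfile, Status, Tier
from mirmarker.evaluation import (
    auc_score, is_valuable, leave_one_out_normal_ratios,
    sensitivity_score, specificity_score,
)

# mir205, published UP: tumor-vs-pooled-normal ratios for 9 tumors
profile = RatioProfile(
    "mir205",
    ratios={f"t{i}": r for i, r in enumerate([3.2, 4.1, 5.0, 2.8, 1.6, 4.4, 2.5, 3.1, 6.0])},
)
# RPM of mir205 in four individual normal samples
normal_rpm = {"n1": 100.0, "n2": 120.0, "n3": 90.0, "n4": 310.0}

for tier in [Tier.SOFT, Tier.MEDIUM, Tier.STRICT]:
    sn = sensitivity_score(Status.UP, profile, tier)
    sp = specificity_score(Status.UP, leave_one_out_normal_ratios(normal_rpm), tier)
    auc = auc_score(sp, sn)
    print(f"{tier.name:6s} (cut {tier.up_cut:g}x): Sn = {sn:.2f}  Sp = {sp:.2f}  "
          f"AUC = {auc:.2f}  valuable: {is_valuable(auc)}")

print("\nSn can only shrink as the cut-off strictens; the marker is worth "
      "reporting only while (Sp+Sn)/2 stays above 0.7.")
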