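"""The three differential-expression callers on hand-built inputs.

Deep sequencing (DS): each tumor sample's RPM is divided by the pooled
normal's RPM and classified by vote at a fold cut-off tier.  SSH: the ratio
of normalized reads between the subtracted libraries, gated on 10 total
reads and a 1.5-fold change.  Microarray: Welch test on log2 intensities
(p < 0.01) joint with a 1.5-fold change of means.
"""

import pandas as pd

from mirmarker import (
    ArraySignalTable, CountTable, SshPair, Tier,
    ma_differential, per_sample_ratios, ssh_differential, vote_classify,
)

# --- DS: 3 tumors vs a pooled normal -------------------------------------
raw = pd.DataFrame(
    {
        "tumor_01": {"mir205": 120.0, "mir143": 4.0, "mir21": 30.0},
        "tumor_02": {"mir205": 90.0, "mir143": 6.0, "mir21": 9.0},
        "tumor_03": {"mir205": 100.0, "mir143": 30.0, "mir21": 35.0},
        "normal_pool": {"mir205": 30.0, "mir143": 25.0, "mir21": 28.0},
    }
)
counts = CountTable.from_raw(raw, total_mapped=pd.Series({c: 1000.0 for c in raw}))
profiles = per_sample_ratios(counts, ["tumor_01", "tumor_02", "tumor_03"], "normal_pool")
for mirna, profile in profiles.items():
    call = vote_classify(profile, Tier.SOFT)
    ratios = ", ".join(f"{r:.2f}" for r in profile.ratios.values())
    print(f"DS  {mirna}: ratios [{ratios}] -> {call.status.value} "
          f"({call.up_votes} up / {call.down_votes} down votes at the 2x tier)")

# --- SSH: subtracted library read counts ----------------------------------
for pair in [SshPair("mir205", 12, 4), SshPair("mir100", 8, 1), SshPair("mir21", 6, 6)]:
    call = ssh_differential(pair)
    verdict = call.status.value if call else "not assessed (fewer than 10 reads)"
    print(f"SSH {pair.mirna_id}: {pair.sr_bc:g}/{pair.sr_n:g} -> {verdict}")

# --- Microarray: tumor vs normal intensities -------------------------------
signals = pd.DataFrame(
    {
        "t1": {"mir205": 200.0}, "t2": {"mir205": 210.0},
        "t3": {"mir205": 190.0}, "t4": {"mir205": 205.0},
        "n1": {"mir205": 100.0}, "n2": {"mir205": 95.0},
        "n3": {"mir205": 105.0}, "n4": {"mir205": 100.0},
    }
)
table = ArraySignalTable(signals, ["t1", "t2", "t3", "t4"], ["n1", "n2", "n3", "n4"])
call = ma_differential(table)["mir205"]
print(f"MA  mir205: fold {call.fold:.2f}, p = {call.pvalue:.2e} -> {call.status.value}")
print("\nA call is directional only when its criteria are jointly met; "
      "everything else stays NEUTRAL or, on tied votes, MIXED.")
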