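"""Simulate the paperlike study design and measure truth recovery.

Generates 100 miRNAs (20 truly up 4-fold, 20 truly down 4-fold, 60
unchanged), draws negative-binomial counts for 9 tumor libraries and a
pooled normal of 6 members at 100,000 mapped reads each, runs the
deep-sequencing vote classifier at the 2x tier, and reports how much of the
planted truth the pipeline recovers.
"""

from mirmarker import (
    Tier, evaluate_recovery, generate_truth, per_sample_ratios,
    simulate_count_libraries, vote_classify,
)

truth = generate_truth(seed=0)
counts = simulate_count_libraries(
    truth, n_tumor=9, n_normal_members=6, depth=1e5, dispersion=0.05, seed=0
)
tumors = [s for s in counts.samples if s.startswith("tumor")]
profiles = per_sample_ratios(counts, tumors, "normal_pool")
calls = {m: vote_classify(p, Tier.SOFT) for m, p in profiles.items()}
res = evaluate_recovery(truth, calls)

print(f"directional miRNAs assessed: {res['n_directional_assessed']}")
print(f"true direction recovered:    {100 * res['directional_recovered']:.1f}%")
print(f"neutral miRNAs assessed:     {res['n_neutral_assessed']}")
print(f"neutral called directional:  {100 * res['neutral_called_directional']:.1f}%")
print("\nRecovery should be near-perfect for 4-fold effects at this depth; "
      "the residual false-direction rate on neutral miRNAs reflects the "
      "single-sample sensitivity of the vote rule under biological "
      "dispersion, not a software defect.")
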