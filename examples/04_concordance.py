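"""Concordance with the published catalogue on the worked 38-marker fixture.

The fixture's ratio profiles are constructed so that the deep-sequencing
vote classifier reproduces the bookkeeping of a typical validation study:
33 of 38 assessed markers agree with their published direction (86.8%,
conventionally printed as 87%), split 20 up / 15 down / 3 mixed.  The
congruence fixture then shows a three-assay comparison in which exactly one
marker (mir205) is called UP by every method.
"""

from mirmarker import Tier, concordance_summary, direction_tally, vote_classify
from mirmarker.fixtures import congruence_fixture, worked_ds_fixture

catalogue, profiles = worked_ds_fixture()
calls = {m: vote_classify(p, Tier.SOFT) for m, p in profiles.items()}
report = concordance_summary({"DS": calls}, catalogue)
s = report.summaries["DS"]
n_up, n_down, n_mixed, n_neutral = direction_tally(list(calls.values()))

print(f"DS vs published: {s.n_agree}/{s.n_assessed} markers agree "
      f"= {s.percent_agree:.1f}% (printed as {s.percent_agree:.0f}%)")
print(f"direction tally: {n_up} up, {n_down} down, {n_mixed} mixed, {n_neutral} neutral")

ccat, ccalls = congruence_fixture()
creport = concordance_summary(ccalls, ccat)
print("\ncongruence cells (methods that agree -> markers):")
for cell, markers in sorted(creport.congruence.items(), key=lambda kv: sorted(kv[0])):
    label = " + ".join(sorted(cell)) if cell else "(no two methods agree)"
    print(f"  {label}: {', '.join(markers)}")
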