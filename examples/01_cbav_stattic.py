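"""Comparative binding affinity values (CBAV) for a known pan-binder.

Takes the per-receptor top docking scores of stattic against the seven
human STAT SH2-domain models and computes its STAT3-CBAV vector: the
top STAT3 score minus the top score on each other STAT. Values near zero
mean the compound docks about equally well everywhere — the signature of
a cross-binder, which is exactly what this classic "STAT3 inhibitor"
turns out to be.
"""

from statscreen import aggregate_cbav, compute_cbav
from statscreen.selectivity import round2

top_scores = {
    "STAT1": 3.83,
    "STAT2": 4.65,
    "STAT3": 3.79,
    "STAT4": 2.90,
    "STAT5A": 3.53,
    "STAT5B": 3.64,
    "STAT6": 3.94,
}

profile = compute_cbav(top_scores, target="STAT3", compound_id="stattic")

print("STAT3-CBAV of stattic (target score minus off-target score):")
for receptor, value in profile.cbav.items():
    print(f"  vs {receptor:7s} {round2(value):+.2f}")
worst = aggregate_cbav(profile, "min_over_all")
print(f"worst-case CBAV: {round2(worst):+.2f}  (selection threshold is +3.00)")
print("every value is far below 3.0 -> stattic is not STAT3-specific")
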