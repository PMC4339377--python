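"""Ligand binding pose variation (LBPV) across the two SH2 sub-pockets.

Builds a 20-pose docking result reproducing the published stattic/STAT3
pattern — 14 poses clustered in the phosphotyrosine pocket (pY+0), 6 in
the hydrophobic side pocket (pY-X) — assigns each pose to a sub-pocket by
anchor contacts, and computes the per-class pose-conservation fraction:
the share of all 20 conformers within 0.5 A in-frame RMSD of the class's
top-scored pose.
"""

from statscreen import assign_all, compute_lbpv, emit_worked_example, lbpv_summary
from statscreen.pocket_geometry import PocketClass

pose_set, pocket = emit_worked_example()
assignments = assign_all(pose_set, pocket)
result = compute_lbpv(pose_set, assignments, rmsd_cluster=0.5)

counts = {cls: 0 for cls in PocketClass}
for a in assignments:
    counts[a.pocket_class] += 1
print(f"pose classes: {counts[PocketClass.PY0]} pY+0, {counts[PocketClass.PYX]} pY-X")
for cls in (PocketClass.PY0, PocketClass.PYX, PocketClass.BOTH):
    print(f"  LBPV[{cls.value:4s}] = {result.values[cls]:.2f}")
print(f"scalar LBPV (dominant cluster): {lbpv_summary(result):.2f}")
print("0.70 / 0.30: most conformers share one conserved position in pY+0,")
print("a minority cluster in pY-X — partial affinity for both cavities.")
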