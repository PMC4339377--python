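"""Selectivity statistics: CBAV and the LBPV family.

CBAV (comparative binding affinity value) of a compound, for a chosen
target receptor against another receptor of the panel, is the difference
of top docking scores

    CBAV_target,r = top_score(target) − top_score(r)      [−log10 K_D units]

so a large positive CBAV means the compound binds the target much more
tightly than receptor ``r``. LBPV (ligand binding pose variation) is the
fraction of a compound's output conformers lying within a cluster-RMSD
cutoff (default 0.5 Å, in-frame) of a top-scored reference pose,
partitioned by which sub-pocket the cluster occupies. The denominator is
always the *total* number of output conformers, so the per-class values
of one pose set sum to at most 1.

The reference pose is chosen per pocket class (best-scoring pose of that
class): a single global reference could never yield two nonzero class
values for clusters more than the cutoff apart, which the published
per-receptor value pairs require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .errors import ConsistencyError
from .pocket_geometry import PocketClass, PoseAssignment, pose_rmsd
from .pose_io import PoseSet

__all__ = [
    "SelectivityProfile",
    "LBPVResult",
    "compute_cbav",
    "aggregate_cbav",
    "compute_lbpv",
    "lbpv_summary",
    "round2",
]


def round2(value: float) -> float:
    """Round to 2 decimals, half-up, as printed in the report tables."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(eq=False)
class SelectivityProfile:
    """Per compound: top score per receptor plus the CBAV vector."""

    compound_id: str
    top_scores: dict[str, float]
    target_receptor: str
    cbav: dict[str, float] = field(default_factory=dict)


@dataclass(eq=False)
class LBPVResult:
    """Pose-conservation fractions per pocket class for one compound × receptor."""

    compound_id: str
    receptor_id: str
    n_poses: int
    values: dict[PocketClass, float]
    reference_pose: dict[PocketClass, int]


def compute_cbav(
    top_scores: Mapping[str, float],
    target: str,
    compound_id: str = "",
) -> SelectivityProfile:
    """CBAV vector of one compound: target top score minus each other receptor's.

    The target itself is excluded from the CBAV keys.
    """
    if target not in top_scores:
        raise KeyError(f"target receptor {target!r} not in top-score map")
    if len(top_scores) < 2:
        raise ConsistencyError("need at least two receptors to compare")
    t = float(top_scores[target])
    cbav = {
        r: t - float(s) for r, s in top_scores.items() if r != target
    }
    return SelectivityProfile(
        compound_id=compound_id,
        top_scores=dict(top_scores),
        target_receptor=target,
        cbav=cbav,
    )


def aggregate_cbav(
    profile: SelectivityProfile,
    mode: str = "min_over_all",
    competitor: str | None = None,
) -> float:
    """Reduce the CBAV vector to the scalar the filters threshold.

    ``min_over_all`` (the default) is the worst case over the whole panel;
    ``single_competitor`` reads off the CBAV against one named receptor.
    """
    if mode == "min_over_all":
        return min(profile.cbav.values())
    if mode == "single_competitor":
        if competitor not in profile.cbav:
            raise KeyError(
                f"competitor {competitor!r} not in CBAV map for "
                f"{profile.compound_id!r}"
            )
        return profile.cbav[competitor]
    raise ValueError(f"unknown aggregation mode {mode!r}")


def compute_lbpv(
    ps: PoseSet,
    assignments: Sequence[PoseAssignment],
    rmsd_cluster: float = 0.5,
    symmetry: bool = False,
) -> LBPVResult:
    """Pose-conservation fraction per pocket class.

    For each populated class the reference is that class's best-scoring
    pose (score ties broken by lowest pose_index); the class value is the
    number of same-class poses within ``rmsd_cluster`` (strict ``<``,
    in-frame RMSD) of the reference, divided by the total pose count.
    Unpopulated classes get 0. The reference always counts itself, so a
    populated class value is at least 1/n_poses.
    """
    if len(assignments) != len(ps.poses):
        raise ConsistencyError(
            f"{len(assignments)} assignments for {len(ps.poses)} poses"
        )
    if not rmsd_cluster > 0:
        raise ValueError("rmsd_cluster must be > 0")
    for pose, asg in zip(ps.poses, assignments):
        if pose.pose_index != asg.pose_index:
            raise ConsistencyError(
                f"assignment order mismatch at pose {pose.pose_index}"
            )

    n = len(ps.poses)
    values = {cls: 0.0 for cls in PocketClass}
    references: dict[PocketClass, int] = {}
    for cls in PocketClass:
        members = [
            pose
            for pose, asg in zip(ps.poses, assignments)
            if asg.pocket_class is cls
        ]
        if not members:
            continue
        ref = min(members, key=lambda p: (-p.score, p.pose_index))
        count = sum(
            1 for pose in members if pose_rmsd(pose, ref, symmetry=symmetry) < rmsd_cluster
        )
        values[cls] = count / n
        references[cls] = ref.pose_index
    return LBPVResult(
        compound_id=ps.compound_id,
        receptor_id=ps.receptor_id,
        n_poses=n,
        values=values,
        reference_pose=references,
    )


def lbpv_summary(result: LBPVResult) -> float:
    """Scalar LBPV of a compound × receptor: the dominant-cluster value.

    The maximum class value over the in-pocket classes (pY+0, pY-X, both);
    poses engaging neither pocket never contribute.
    """
    return max(
        result.values[cls]
        for cls in (PocketClass.PY0, PocketClass.PYX, PocketClass.BOTH)
    )
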