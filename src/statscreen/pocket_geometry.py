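"""In-frame ligand RMSD and sub-pocket assignment.

Poses from one docking run share the receptor coordinate frame, so pose
RMSD is computed *without* superposition: superposing would erase exactly
the binding-position differences that the pose-variation statistic
measures. Each pose is assigned to the phosphotyrosine pocket (pY+0), the
hydrophobic side pocket (pY-X), both, or neither, by the fraction of its
heavy atoms in contact with each pocket's anchor atoms.

The pY+0 / pY-X / both partition itself is the field's; the
contact-fraction rule that operationalizes it is this package's own
geometric model, and its two knobs
— contact radius and minimum contact fraction — are config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConsistencyError
from .pose_io import LigandPose, PocketModel, PoseSet

__all__ = ["PocketClass", "PoseAssignment", "pose_rmsd", "assign_pocket", "assign_all"]

# brute-force automorphism search is only attempted below this size
MAX_SYMMETRY_ATOMS = 60

# single-bond covalent radii (Å) for the elements docking ligands contain
_COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}


class PocketClass(Enum):
    """Which sub-pocket(s) a pose engages."""

    PY0 = "PY0"
    PYX = "PYX"
    BOTH = "BOTH"
    NONE = "NONE"


@dataclass(frozen=True)
class PoseAssignment:
    pose_index: int
    pocket_class: PocketClass
    contact_fraction_py0: float
    contact_fraction_pyx: float


def _check_same_ligand(a: LigandPose, b: LigandPose) -> None:
    if a.compound_id != b.compound_id:
        raise ConsistencyError(
            f"RMSD between different compounds: {a.compound_id!r} vs {b.compound_id!r}"
        )
    if a.n_atoms != b.n_atoms or a.elements != b.elements:
        raise ConsistencyError(
            f"compound {a.compound_id!r}: poses {a.pose_index}/{b.pose_index} "
            "differ in atom count or element sequence"
        )


def _bond_graph(coords: np.ndarray, elements: tuple[str, ...]):
    """Distance-based molecular graph (bond if within 1.25x summed covalent radii)."""
    import networkx as nx

    radii = np.array([_COVALENT_RADII.get(el, 0.77) for el in elements])
    dist = cdist(coords, coords)
    cutoff = 1.25 * (radii[:, None] + radii[None, :])
    graph = nx.Graph()
    for i, el in enumerate(elements):
        graph.add_node(i, element=el)
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    graph.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return graph


def _automorphisms(coords: np.ndarray, elements: tuple[str, ...]):
    """All element-preserving graph automorphisms of the ligand."""
    from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match

    graph = _bond_graph(coords, elements)
    matcher = GraphMatcher(
        graph, graph, node_match=categorical_node_match("element", None)
    )
    n = len(elements)
    for mapping in matcher.isomorphisms_iter():
        yield np.array([mapping[i] for i in range(n)], dtype=int)


def pose_rmsd(a: LigandPose, b: LigandPose, symmetry: bool = False) -> float:
    """In-frame heavy-atom RMSD between two poses of the same ligand.

    With ``symmetry=True`` the minimum over graph-automorphism atom
    relabelings of the ligand is returned (brute force; ligands are capped
    at 60 heavy atoms for this mode). Automorphisms are derived from a
    distance-based bond graph of the first pose.
    """
    _check_same_ligand(a, b)
    diff = a.coords - b.coords
    plain = float(np.sqrt((diff**2).sum(axis=1).mean()))
    if not symmetry:
        return plain
    if a.n_atoms > MAX_SYMMETRY_ATOMS:
        raise ConsistencyError(
            f"symmetry-corrected RMSD is limited to {MAX_SYMMETRY_ATOMS} heavy "
            f"atoms ({a.n_atoms} given)"
        )
    best = plain
    for perm in _automorphisms(a.coords, a.elements):
        diff = a.coords - b.coords[perm]
        best = min(best, float(np.sqrt((diff**2).sum(axis=1).mean())))
    return best


def assign_pocket(pose: LigandPose, pm: PocketModel) -> PoseAssignment:
    """Classify a pose by the fraction of its atoms in contact with each pocket.

    An atom is in contact with a pocket when within ``pm.contact_radius``
    of any of that pocket's anchor atoms. A pocket counts as engaged when
    the contact fraction reaches ``pm.min_contact_fraction``; if neither
    reaches it, the class falls back to the larger nonzero fraction
    (pY+0 wins exact ties), and to NONE when both fractions are zero.
    """
    if pose.receptor_id != pm.receptor_id:
        raise ConsistencyError(
            f"pose receptor {pose.receptor_id!r} does not match pocket model "
            f"{pm.receptor_id!r}"
        )
    fractions = {}
    for key in ("py0", "pyx"):
        dist = cdist(pose.coords, pm.anchors[key])
        in_contact = (dist <= pm.contact_radius).any(axis=1)
        fractions[key] = float(in_contact.mean())
    f0, fx = fractions["py0"], fractions["pyx"]
    mcf = pm.min_contact_fraction
    if f0 >= mcf and fx >= mcf:
        cls = PocketClass.BOTH
    elif f0 >= mcf:
        cls = PocketClass.PY0
    elif fx >= mcf:
        cls = PocketClass.PYX
    elif f0 > 0 or fx > 0:
        cls = PocketClass.PY0 if f0 >= fx else PocketClass.PYX
    else:
        cls = PocketClass.NONE
    return PoseAssignment(
        pose_index=pose.pose_index,
        pocket_class=cls,
        contact_fraction_py0=f0,
        contact_fraction_pyx=fx,
    )


def assign_all(ps: PoseSet, pm: PocketModel) -> list[PoseAssignment]:
    """One assignment per pose, order-aligned with ``ps.poses``."""
    return [assign_pocket(pose, pm) for pose in ps.poses]
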