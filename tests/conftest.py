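import numpy as np
import pytest

from statscreen import LigandPose, PocketModel, PoseSet

# Printed per-receptor top docking scores of stattic (the CBAV worked example)
STATTIC_TOP_SCORES = {
    "STAT1": 3.83,
    "STAT2": 4.65,
    "STAT3": 3.79,
    "STAT4": 2.90,
    "STAT5A": 3.53,
    "STAT5B": 3.64,
    "STAT6": 3.94,
}
STATTIC_CBAV = {
    "STAT1": -0.04,
    "STAT2": -0.86,
    "STAT4": 0.89,
    "STAT5A": 0.26,
    "STAT5B": 0.15,
    "STAT6": -0.15,
}

# NP_1_1 CBAV row of the published STAT1 hit table
NP_1_1_CBAV = {
    "STAT2": 3.33,
    "STAT3": 4.62,
    "STAT4": 6.4,
    "STAT5A": 7.17,
    "STAT5B": 3.83,
    "STAT6": 5.32,
}


def make_pose(coords, score=1.0, idx=0, cid="cpd", rid="R", elements=None):
    coords = np.asarray(coords, dtype=float)
    if elements is None:
        elements = ("C",) * coords.shape[0]
    return LigandPose(
        compound_id=cid,
        receptor_id=rid,
        pose_index=idx,
        score=score,
        coords=coords,
        elements=elements,
    )


def make_pose_set(coord_list, scores=None, cid="cpd", rid="R", elements=None):
    if scores is None:
        scores = [float(len(coord_list) - i) for i in range(len(coord_list))]
    poses = [
        make_pose(c, score=s, idx=i, cid=cid, rid=rid, elements=elements)
        for i, (c, s) in enumerate(zip(coord_list, scores))
    ]
    return PoseSet(compound_id=cid, receptor_id=rid, poses=poses)


def simple_pocket(rid="R", separation=10.0, radius=4.5, mcf=0.2):
    py0 = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    return PocketModel(
        receptor_id=rid,
        anchors={"py0": py0, "pyx": py0 + np.array([separation, 0.0, 0.0])},
        contact_radius=radius,
        min_contact_fraction=mcf,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def write_toy_pdb(path, residues):
    """Write a minimal PDB: residues is a list of
    (chain, resnum, resname, [(atom_name, element, xyz), ...])."""
    lines = []
    serial = 1
    for chain, resnum, resname, atoms in residues:
        for name, element, (x, y, z) in atoms:
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{resname:>3s} {chain}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
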