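"""Docking-pose and pocket-definition I/O.

Multi-pose docking output (SDF or multi-record MOL2) is read into
:class:`PoseSet` objects — one per compound × receptor — holding ordered
heavy-atom coordinates and a per-pose scalar score on the −log10(K_D)
scale (higher is better, as printed by docking engines' "total score").
Hydrogens are dropped on ingest so pose RMSD is insensitive to
protonation-output variants.

Receptor identity is not stored in pose files; it comes from the
per-receptor file mapping of the run configuration and is passed to
:func:`read_pose_file`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ConfigError,
    ConsistencyError,
    DataError,
    PocketDefinitionError,
    PoseFileError,
)

__all__ = [
    "LigandPose",
    "PoseSet",
    "PocketModel",
    "ScreeningConfig",
    "read_pose_file",
    "write_pose_file",
    "read_pocket_model",
    "top_pose",
    "truncate_poses",
]


@dataclass(frozen=True, eq=False)
class LigandPose:
    """One docked conformer: ordered heavy-atom coordinates plus its score.

    ``score`` is on the −log10(K_D) scale ("total score"); ``pose_index``
    is the record's order of appearance in the source file.
    """

    compound_id: str
    receptor_id: str
    pose_index: int
    score: float
    coords: np.ndarray
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise ConsistencyError(
                f"pose {self.pose_index} of {self.compound_id!r}: coords must "
                f"be a non-empty (n, 3) array, got shape {coords.shape}"
            )
        if len(self.elements) != coords.shape[0]:
            raise ConsistencyError(
                f"pose {self.pose_index} of {self.compound_id!r}: "
                f"{len(self.elements)} elements for {coords.shape[0]} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ConsistencyError(
                f"pose {self.pose_index} of {self.compound_id!r}: "
                "non-finite coordinates"
            )
        if self.pose_index < 0:
            raise ConsistencyError("pose_index must be >= 0")
        if not math.isfinite(self.score):
            raise DataError(
                f"pose {self.pose_index} of {self.compound_id!r}: "
                "missing or non-finite score"
            )

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(eq=False)
class PoseSet:
    """The ranked collection of conformers for one compound × receptor.

    All poses must describe the same ligand with the same atom ordering.
    ``deduplicated_min_rmsd``, when set, asserts that every pose pair is at
    least that far apart in-frame (the docking engine's minimum-RMSD
    output filter, 0.05 Å in the reference protocol).
    """

    compound_id: str
    receptor_id: str
    poses: list[LigandPose] = field(default_factory=list)
    deduplicated_min_rmsd: float | None = None

    def __post_init__(self) -> None:
        if not self.poses:
            raise ConsistencyError(f"PoseSet {self.compound_id!r}: no poses")
        ref = self.poses[0]
        seen: set[int] = set()
        for p in self.poses:
            if p.compound_id != self.compound_id or p.receptor_id != self.receptor_id:
                raise ConsistencyError(
                    f"pose {p.pose_index}: ids {p.compound_id!r}/{p.receptor_id!r} "
                    f"do not match set {self.compound_id!r}/{self.receptor_id!r}"
                )
            if p.n_atoms != ref.n_atoms or p.elements != ref.elements:
                raise ConsistencyError(
                    f"compound {self.compound_id!r}: pose {p.pose_index} has "
                    f"{p.n_atoms} atoms ({'/'.join(p.elements[:4])}...), expected "
                    f"{ref.n_atoms} matching pose {ref.pose_index}"
                )
            if p.pose_index in seen:
                raise ConsistencyError(
                    f"compound {self.compound_id!r}: duplicate pose_index "
                    f"{p.pose_index}"
                )
            seen.add(p.pose_index)
        if self.deduplicated_min_rmsd is not None:
            d = self.deduplicated_min_rmsd
            for i, a in enumerate(self.poses):
                for b in self.poses[i + 1 :]:
                    rmsd = float(
                        np.sqrt(((a.coords - b.coords) ** 2).sum(axis=1).mean())
                    )
                    if rmsd < d:
                        raise ConsistencyError(
                            f"compound {self.compound_id!r}: poses "
                            f"{a.pose_index}/{b.pose_index} closer than the "
                            f"declared minimum pose RMSD {d} ({rmsd:.4f} A)"
                        )

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


@dataclass(eq=False)
class PocketModel:
    """Anchor atoms of the two SH2 sub-pockets of one receptor.

    ``anchors`` maps the pocket-class keys ``"py0"`` (phosphotyrosine
    pocket) and ``"pyx"`` (hydrophobic side pocket) to (n, 3) arrays of
    anchor-atom coordinates — the heavy atoms of the protomol tripeptide
    fragment or of user-selected residues. A ligand atom is "in contact"
    with a pocket when within ``contact_radius`` of any anchor atom; a
    pose engages a pocket when at least ``min_contact_fraction`` of its
    atoms are in contact.
    """

    receptor_id: str
    anchors: dict[str, np.ndarray]
    contact_radius: float = 4.5
    min_contact_fraction: float = 0.2

    def __post_init__(self) -> None:
        for key in ("py0", "pyx"):
            if key not in self.anchors:
                raise PocketDefinitionError(
                    f"receptor {self.receptor_id!r}: missing {key!r} anchors"
                )
            arr = np.asarray(self.anchors[key], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
                raise PocketDefinitionError(
                    f"receptor {self.receptor_id!r}: {key!r} anchors must be a "
                    f"non-empty (n, 3) array"
                )
            self.anchors[key] = arr
        if not self.contact_radius > 0:
            raise PocketDefinitionError("contact_radius must be > 0")
        if not 0 <= self.min_contact_fraction <= 1:
            raise PocketDefinitionError("min_contact_fraction must be in [0, 1]")


@dataclass
class ScreeningConfig:
    """Thresholds and pose counts of the five-step screening procedure.

    Defaults follow the published protocol: CBAV selection threshold 3.0,
    LBPV specificity bands [0.8, 1.0] / [0.0, 0.2], pose-cluster RMSD
    0.5 Å, engine minimum inter-pose RMSD 0.05 Å, 3 pre-screen and 20
    re-screen poses per ligand.
    """

    target_receptor: str
    competitor_receptor: str | None = None
    cbav_min: float = 3.0
    lbpv_specific: float = 0.8
    lbpv_nonspecific: float = 0.2
    lbpv_offtarget_slack: float = 0.15
    rmsd_cluster: float = 0.5
    min_pose_rmsd: float = 0.05
    prescreen_poses: int = 3
    rescreen_poses: int = 20
    cbav_aggregation: str = "min_over_all"
    symmetry_rmsd: bool = False
    offtarget_lbpv_panel: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.lbpv_nonspecific < self.lbpv_specific <= 1:
            raise ConfigError(
                "need 0 <= lbpv_nonspecific < lbpv_specific <= 1, got "
                f"{self.lbpv_nonspecific} / {self.lbpv_specific}"
            )
        if not self.rmsd_cluster > self.min_pose_rmsd > 0:
            raise ConfigError(
                "need rmsd_cluster > min_pose_rmsd > 0, got "
                f"{self.rmsd_cluster} / {self.min_pose_rmsd}"
            )
        if not 1 <= self.prescreen_poses <= self.rescreen_poses:
            raise ConfigError(
                "need 1 <= prescreen_poses <= rescreen_poses, got "
                f"{self.prescreen_poses} / {self.rescreen_poses}"
            )
        if self.cbav_aggregation not in ("min_over_all", "single_competitor"):
            raise ConfigError(
                f"unknown cbav_aggregation {self.cbav_aggregation!r}"
            )
        if self.cbav_aggregation == "single_competitor" and not self.competitor_receptor:
            raise ConfigError(
                "single_competitor aggregation requires competitor_receptor"
            )


# ---------------------------------------------------------------------------
# pose file reading / writing


def _mol_to_pose(mol, compound_id, receptor_id, pose_index, score) -> LigandPose:
    conf = mol.GetConformer()
    coords, elements = [], []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1:  # drop hydrogens (and dummy atoms)
            continue
        pos = conf.GetAtomPosition(atom.GetIdx())
        coords.append((pos.x, pos.y, pos.z))
        elements.append(atom.GetSymbol())
    if not coords:
        raise PoseFileError(
            f"record {pose_index} ({compound_id!r}): no heavy atoms"
        )
    return LigandPose(
        compound_id=compound_id,
        receptor_id=receptor_id,
        pose_index=pose_index,
        score=score,
        coords=np.array(coords, dtype=float),
        elements=tuple(elements),
    )


def _parse_score(raw, record_idx: int, name: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise DataError(
            f"record {record_idx} ({name!r}): score {raw!r} is not numeric"
        ) from None
    if not math.isfinite(value):
        raise DataError(f"record {record_idx} ({name!r}): score is not finite")
    return value


def _read_sdf_records(path: Path, score_field: str):
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise PoseFileError(f"{path}: record {idx} failed to parse as SDF")
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not name:
            raise PoseFileError(f"{path}: record {idx} has no compound id")
        if not mol.HasProp(score_field):
            raise DataError(
                f"record {idx} ({name!r}): missing score field {score_field!r}"
            )
        yield idx, name, mol, _parse_score(mol.GetProp(score_field), idx, name)


_MOL2_SCORE_RE = re.compile(r"(?:^|\s)score\s*[=:]\s*([-+0-9.eE]+)")


def _read_mol2_records(path: Path, score_field: str, scores_path):
    from rdkit import Chem

    text = path.read_text()
    blocks = [
        "@<TRIPOS>MOLECULE" + chunk
        for chunk in text.split("@<TRIPOS>MOLECULE")[1:]
    ]
    if not blocks:
        raise PoseFileError(f"{path}: no @<TRIPOS>MOLECULE records found")

    sidecar: dict[tuple[str, int], float] = {}
    if scores_path is not None:
        sidecar = _read_score_sidecar(Path(scores_path))

    per_compound_count: dict[str, int] = {}
    for idx, block in enumerate(blocks):
        lines = block.splitlines()
        name = lines[1].strip() if len(lines) > 1 else ""
        if not name:
            raise PoseFileError(f"{path}: record {idx} has no compound id")
        mol = Chem.MolFromMol2Block(block, sanitize=False, removeHs=False)
        if mol is None:
            raise PoseFileError(f"{path}: record {idx} failed to parse as MOL2")
        local_idx = per_compound_count.get(name, 0)
        per_compound_count[name] = local_idx + 1
        if sidecar:
            try:
                score = sidecar[(name, local_idx)]
            except KeyError:
                raise DataError(
                    f"record {idx} ({name!r}): no sidecar score for pose "
                    f"{local_idx}"
                ) from None
        else:
            # MOLECULE-record comment line dialect: "score = <value>"
            match = None
            for line in lines[2:8]:
                if line.startswith("@<TRIPOS>"):
                    break
                match = _MOL2_SCORE_RE.search(line) or match
            if match is None:
                raise DataError(
                    f"record {idx} ({name!r}): no score comment and no "
                    "sidecar TSV given"
                )
            score = _parse_score(match.group(1), idx, name)
        yield idx, name, mol, score


def _read_score_sidecar(path: Path) -> dict[tuple[str, int], float]:
    """Sidecar TSV dialect: compound_id <TAB> pose_index <TAB> score."""
    out: dict[tuple[str, int], float] = {}
    for ln, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise PoseFileError(
                f"{path}: line {ln + 1}: expected 3 tab-separated fields"
            )
        out[(parts[0], int(parts[1]))] = _parse_score(parts[2], ln, parts[0])
    return out


def read_pose_file(
    path,
    format: str = "sdf",
    score_field: str = "docking_score",
    receptor_id: str = "",
    scores_path=None,
    min_pose_rmsd: float | None = None,
) -> list[PoseSet]:
    """Read a multi-pose docking output file into per-compound pose sets.

    Records are grouped by compound id (SDF title / MOL2 molecule name) in
    order of first appearance; within a set, ``pose_index`` follows file
    order. Hydrogens are dropped. ``receptor_id`` is attached from the run
    configuration's file mapping. For MOL2, scores come from a
    ``score = <x>`` comment line in the MOLECULE record or from a sidecar
    TSV (``scores_path``).
    """
    path = Path(path)
    if not path.exists():
        raise PoseFileError(f"pose file not found: {path}")
    if format == "sdf":
        records = _read_sdf_records(path, score_field)
    elif format == "mol2":
        records = _read_mol2_records(path, score_field, scores_path)
    else:
        raise ConfigError(f"unknown pose file format {format!r}")

    grouped: dict[str, list[LigandPose]] = {}
    for idx, name, mol, score in records:
        poses = grouped.setdefault(name, [])
        poses.append(
            _mol_to_pose(mol, name, receptor_id, pose_index=len(poses), score=score)
        )
    return [
        PoseSet(
            compound_id=cid,
            receptor_id=receptor_id,
            poses=poses,
            deduplicated_min_rmsd=min_pose_rmsd,
        )
        for cid, poses in grouped.items()
    ]


def write_pose_file(pose_sets: Iterable[PoseSet], path, score_field: str = "docking_score") -> None:
    """Write pose sets as a multi-record SDF (no bonds, heavy atoms only).

    Round-trips compound ids, scores, atom order and coordinates (to the
    1e-4 Å precision of the molblock coordinate field).
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for ps in pose_sets:
            for pose in ps.poses:
                mol = Chem.RWMol()
                for sym in pose.elements:
                    mol.AddAtom(Chem.Atom(sym))
                conf = Chem.Conformer(pose.n_atoms)
                for i, (x, y, z) in enumerate(pose.coords):
                    conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
                mol.AddConformer(conf)
                out = mol.GetMol()
                for atom in out.GetAtoms():
                    atom.SetNoImplicit(True)
                out.SetProp("_Name", pose.compound_id)
                out.SetProp(score_field, repr(float(pose.score)))
                writer.write(out)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# pocket model reading

_SELECTION_RE = re.compile(r"^([^:]+):(-?\d+)(?:-(-?\d+))?$")


def _resolve_selection(structure, sel: str) -> list[tuple[float, float, float]]:
    m = _SELECTION_RE.match(sel.strip())
    if m is None:
        raise PocketDefinitionError(
            f"selection {sel!r}: expected 'chain:resnum' or 'chain:start-end'"
        )
    chain_name, start = m.group(1), int(m.group(2))
    end = int(m.group(3)) if m.group(3) is not None else start
    coords: list[tuple[float, float, float]] = []
    found_chain = False
    for model in structure:
        for chain in model:
            if chain.name != chain_name:
                continue
            found_chain = True
            for residue in chain:
                num = residue.seqid.num
                if start <= num <= end:
                    for atom in residue:
                        if atom.element.name != "H":
                            p = atom.pos
                            coords.append((p.x, p.y, p.z))
        break  # first model only
    if not found_chain:
        raise PocketDefinitionError(f"selection {sel!r}: chain {chain_name!r} not found")
    if not coords:
        raise PocketDefinitionError(
            f"selection {sel!r}: no residues {start}-{end} in chain {chain_name!r}"
        )
    return coords


def read_pocket_model(
    structure_path,
    selections: Mapping[str, Sequence[str]],
    contact_radius: float = 4.5,
    min_contact_fraction: float = 0.2,
    receptor_id: str = "",
) -> PocketModel:
    """Build a two-sub-pocket model from a PDB structure and residue selections.

    ``selections`` maps ``"py0"`` and ``"pyx"`` to lists of
    ``chain:resnum`` or ``chain:start-end`` strings; the anchors of each
    class are the union of the selected residues' heavy atoms.
    """
    import gemmi

    structure = gemmi.read_structure(str(Path(structure_path)))
    anchors: dict[str, np.ndarray] = {}
    for key in ("py0", "pyx"):
        sels = selections.get(key)
        if not sels:
            raise PocketDefinitionError(f"empty selection for pocket class {key!r}")
        coords: list[tuple[float, float, float]] = []
        for sel in sels:
            coords.extend(_resolve_selection(structure, sel))
        anchors[key] = np.array(coords, dtype=float)
    return PocketModel(
        receptor_id=receptor_id,
        anchors=anchors,
        contact_radius=contact_radius,
        min_contact_fraction=min_contact_fraction,
    )


# ---------------------------------------------------------------------------
# ranking helpers


def _score_order(ps: PoseSet) -> list[LigandPose]:
    # score descending, pose_index ascending as the deterministic tie-break
    return sorted(ps.poses, key=lambda p: (-p.score, p.pose_index))


def top_pose(ps: PoseSet) -> LigandPose:
    """The highest-scoring pose; ties broken by lowest pose_index."""
    return _score_order(ps)[0]


def truncate_poses(ps: PoseSet, k: int) -> PoseSet:
    """Keep the k best-scoring poses (all of them if fewer exist)."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    kept = _score_order(ps)[:k]
    kept.sort(key=lambda p: p.pose_index)  # preserve file order within the set
    return PoseSet(
        compound_id=ps.compound_id,
        receptor_id=ps.receptor_id,
        poses=kept,
        deduplicated_min_rmsd=ps.deduplicated_min_rmsd,
    )
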