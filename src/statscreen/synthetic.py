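"""Ground-truth-labeled synthetic docking campaigns.

The generator emulates the *outputs* of a two-tier docking campaign — a
fast pre-screen (3 poses/ligand) and an accurate re-screen (20
poses/ligand) against a panel of homologous receptors, each with two
sub-pocket anchor clusters — without any docking engine. Three compound
roles are planted:

* target-specific — high scores on the target receptor only, with a
  tight pose cluster bridging both of the target's sub-pockets; diffuse,
  low-scoring poses elsewhere;
* cross-binders — high scores on every receptor with only moderately
  clustered poses;
* decoys — low scores and diffuse poses everywhere.

Scores live on the −log10(K_D) scale in the regime real campaigns report
(roughly 3–15) and are drawn from a *truncated* normal (±1.5σ): with the
default on/off separation Δ = 4.0 and σ = 0.3 the worst-case CBAV of a
planted specific is then at least Δ − 3σ = 3.1, strictly above the 3.0
selection threshold, so planted labels are recoverable by construction
rather than by chance. Pose jitter is the RMS displacement (Å) of a pose
from its cluster reference position.

Each compound × receptor × tier gets its own RNG stream derived from the
campaign seed by a stable hash, so subsetting compounds never shifts
other compounds' data and equal seeds give byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .pipeline import ScreenInputs
from .pose_io import LigandPose, PocketModel, PoseSet, write_pose_file

__all__ = [
    "CampaignSpec",
    "GroundTruth",
    "Campaign",
    "generate_campaign",
    "write_campaign",
    "emit_worked_example",
    "LIGAND_TEMPLATE",
    "LIGAND_ELEMENTS",
]

_PANEL = ("STAT1", "STAT2", "STAT3", "STAT4", "STAT5A", "STAT5B", "STAT6")

# rigid 10-heavy-atom zig-zag scaffold, ~12.6 A long, centered at the origin
_RAW_TEMPLATE = np.array(
    [[1.4 * i, 0.4 * (-1) ** i, 0.0] for i in range(10)], dtype=float
)
LIGAND_TEMPLATE = _RAW_TEMPLATE - _RAW_TEMPLATE.mean(axis=0)
LIGAND_ELEMENTS = ("C", "C", "N", "C", "C", "O", "C", "C", "N", "C")

_PY0_ANCHOR_OFFSETS = np.array(
    [[0.0, 0.0, 0.0], [0.9, 0.4, 0.1], [-0.6, 0.8, -0.3], [0.3, -0.9, 0.5]]
)


@dataclass
class CampaignSpec:
    """Study conditions of one synthetic campaign."""

    seed: int = 0
    n_receptors: int = 7
    n_compounds: int = 200
    n_specific_per_target: int = 5
    n_cross_binders: int = 5
    target_receptor: str = "STAT1"
    competitor_receptor: str = "STAT3"
    prescreen_poses: int = 3
    rescreen_poses: int = 20
    mu_on: float = 12.0
    delta: float = 4.0
    mu_decoy: float = 5.0
    sigma: float = 0.3
    score_truncation_sigmas: float = 1.5
    jitter_tight: float = 0.15
    jitter_moderate: float = 1.0
    jitter_diffuse: float = 2.5
    rmsd_cluster: float = 0.5
    anchor_separation: float = 10.0
    contact_radius: float = 4.5
    min_contact_fraction: float = 0.2

    @property
    def mu_off(self) -> float:
        return self.mu_on - self.delta

    @property
    def receptors(self) -> tuple[str, ...]:
        if self.n_receptors <= len(_PANEL):
            return _PANEL[: self.n_receptors]
        return _PANEL + tuple(
            f"STAT{i}" for i in range(8, self.n_receptors + 1)
        )

    def __post_init__(self) -> None:
        if self.n_specific_per_target + self.n_cross_binders > self.n_compounds:
            raise ConfigError("more planted compounds than compounds")
        if not self.jitter_tight < self.rmsd_cluster < self.jitter_diffuse:
            raise ConfigError(
                "need jitter_tight < rmsd_cluster < jitter_diffuse, got "
                f"{self.jitter_tight} / {self.rmsd_cluster} / {self.jitter_diffuse}"
            )
        if self.anchor_separation < 2 * self.contact_radius:
            raise ConfigError(
                f"anchor separation {self.anchor_separation} A smaller than twice "
                f"the contact radius {self.contact_radius} A: the two sub-pockets "
                "would overlap"
            )
        if self.n_receptors < 2:
            raise ConfigError("need at least two receptors")
        if self.target_receptor not in self.receptors:
            raise ConfigError(f"target {self.target_receptor!r} not in panel")


@dataclass
class GroundTruth:
    """Planted compound labels: SPECIFIC(target) / CROSS_BINDER / DECOY."""

    labels: dict[str, str]
    target_receptor: str

    def of(self, label: str) -> list[str]:
        return [cid for cid, lab in self.labels.items() if lab == label]


@dataclass(eq=False)
class Campaign:
    spec: CampaignSpec
    pockets: dict[str, PocketModel]
    prescreen: dict[str, dict[str, PoseSet]]
    rescreen: dict[str, dict[str, PoseSet]]
    ground_truth: GroundTruth

    def inputs(self) -> ScreenInputs:
        return ScreenInputs(
            prescreen=self.prescreen, rescreen=self.rescreen, pockets=self.pockets
        )


def _rng(seed: int, tier: int, compound_id: str, receptor_id: str) -> np.random.Generator:
    """One stream per (campaign seed, tier, compound, receptor), stable under subsetting."""
    return np.random.default_rng(
        np.random.SeedSequence(
            [
                int(seed) & 0x7FFFFFFF,
                tier,
                zlib.crc32(compound_id.encode()),
                zlib.crc32(receptor_id.encode()),
            ]
        )
    )


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float, bound: float) -> float:
    while True:
        z = rng.standard_normal()
        if abs(z) <= bound:
            return mu + sigma * z


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _default_pocket(receptor_id: str, spec_sep: float, radius: float, mcf: float) -> PocketModel:
    return PocketModel(
        receptor_id=receptor_id,
        anchors={
            "py0": _PY0_ANCHOR_OFFSETS.copy(),
            "pyx": _PY0_ANCHOR_OFFSETS + np.array([spec_sep, 0.0, 0.0]),
        },
        contact_radius=radius,
        min_contact_fraction=mcf,
    )


def _bridging_center(sep: float) -> np.ndarray:
    return np.array([sep / 2.0, 0.0, 0.0])


def _make_poses(
    rng: np.random.Generator,
    compound_id: str,
    receptor_id: str,
    n_poses: int,
    mu: float,
    spec: CampaignSpec,
    placement: str,
) -> PoseSet:
    """Generate one tier's poses: 'tight'/'moderate' translation-jittered
    clusters at the bridging position, or 'diffuse' randomly rotated poses."""
    center = _bridging_center(spec.anchor_separation)
    jitter = {
        "tight": spec.jitter_tight,
        "moderate": spec.jitter_moderate,
        "diffuse": spec.jitter_diffuse,
    }[placement]
    poses = []
    for i in range(n_poses):
        score = _truncated_normal(rng, mu, spec.sigma, spec.score_truncation_sigmas)
        shift = rng.standard_normal(3) * (jitter / np.sqrt(3.0))
        if placement == "diffuse":
            coords = LIGAND_TEMPLATE @ _random_rotation(rng).T + center + shift
        else:
            coords = LIGAND_TEMPLATE + center + shift
        poses.append(
            LigandPose(
                compound_id=compound_id,
                receptor_id=receptor_id,
                pose_index=i,
                score=score,
                coords=coords,
                elements=LIGAND_ELEMENTS,
            )
        )
    return PoseSet(compound_id=compound_id, receptor_id=receptor_id, poses=poses)


def generate_campaign(spec: CampaignSpec) -> Campaign:
    """Generate a full labeled campaign (pockets, both pose tiers, truth)."""
    receptors = spec.receptors
    n_dec = spec.n_compounds - spec.n_specific_per_target - spec.n_cross_binders
    labels: dict[str, str] = {}
    for i in range(spec.n_compounds):
        cid = f"CPD_{i + 1:04d}"
        if i < spec.n_specific_per_target:
            labels[cid] = "SPECIFIC"
        elif i < spec.n_specific_per_target + spec.n_cross_binders:
            labels[cid] = "CROSS_BINDER"
        else:
            labels[cid] = "DECOY"
    assert sum(1 for v in labels.values() if v == "DECOY") == n_dec

    pockets = {
        rid: _default_pocket(
            rid, spec.anchor_separation, spec.contact_radius, spec.min_contact_fraction
        )
        for rid in receptors
    }

    tiers = {0: ("prescreen", spec.prescreen_poses), 1: ("rescreen", spec.rescreen_poses)}
    stage_sets: dict[str, dict[str, dict[str, PoseSet]]] = {
        "prescreen": {rid: {} for rid in receptors},
        "rescreen": {rid: {} for rid in receptors},
    }
    for cid, label in labels.items():
        for rid in receptors:
            if label == "SPECIFIC":
                on_target = rid == spec.target_receptor
                mu = spec.mu_on if on_target else spec.mu_off
                placement = "tight" if on_target else "diffuse"
            elif label == "CROSS_BINDER":
                mu, placement = spec.mu_on, "moderate"
            else:
                mu, placement = spec.mu_decoy, "diffuse"
            for tier, (stage, n_poses) in tiers.items():
                rng = _rng(spec.seed, tier, cid, rid)
                stage_sets[stage][rid][cid] = _make_poses(
                    rng, cid, rid, n_poses, mu, spec, placement
                )
    return Campaign(
        spec=spec,
        pockets=pockets,
        prescreen=stage_sets["prescreen"],
        rescreen=stage_sets["rescreen"],
        ground_truth=GroundTruth(labels=labels, target_receptor=spec.target_receptor),
    )


def write_campaign(campaign: Campaign, out_dir, score_field: str = "docking_score") -> Path:
    """Write a campaign to disk in the dialects the pose reader consumes.

    Produces per-receptor pre-screen/re-screen SDF files, the ground
    truth TSV, and a ready-to-run ``run.yaml``; returns the run-config
    path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = campaign.spec
    receptors_cfg: dict[str, dict] = {}
    for rid in spec.receptors:
        entry: dict = {}
        for stage, sets in (("prescreen", campaign.prescreen), ("rescreen", campaign.rescreen)):
            fname = f"{rid}_{stage}.sdf"
            ordered = [sets[rid][cid] for cid in sorted(sets[rid])]
            write_pose_file(ordered, out_dir / fname, score_field=score_field)
            entry[stage] = fname
        pm = campaign.pockets[rid]
        entry["pocket"] = {
            "anchors": {
                "py0": [[float(v) for v in row] for row in pm.anchors["py0"]],
                "pyx": [[float(v) for v in row] for row in pm.anchors["pyx"]],
            },
            "contact_radius": pm.contact_radius,
            "min_contact_fraction": pm.min_contact_fraction,
        }
        receptors_cfg[rid] = entry

    with open(out_dir / "ground_truth.tsv", "w") as fh:
        for cid in sorted(campaign.ground_truth.labels):
            label = campaign.ground_truth.labels[cid]
            target = spec.target_receptor if label == "SPECIFIC" else ""
            fh.write(f"{cid}\t{label}\t{target}\n")

    run_cfg = {
        "score_field": score_field,
        "pose_format": "sdf",
        "output_dir": "results",
        "receptors": receptors_cfg,
        "screening": {
            "target_receptor": spec.target_receptor,
            "competitor_receptor": spec.competitor_receptor,
            "rmsd_cluster": spec.rmsd_cluster,
            "prescreen_poses": spec.prescreen_poses,
            "rescreen_poses": spec.rescreen_poses,
        },
    }
    config_path = out_dir / "run.yaml"
    config_path.write_text(yaml.safe_dump(run_cfg, sort_keys=True))
    return config_path


def emit_worked_example(
    jitter: float = 0.12, seed: int = 0, n_py0: int = 14, n_pyx: int = 6
) -> tuple[PoseSet, PocketModel]:
    """A 20-pose set reproducing the published stattic/STAT3 pose pattern.

    14 poses form a tight cluster (pairwise in-frame RMSD well under the
    0.5 Å cutoff at the default jitter) in the phosphotyrosine pocket and
    6 in the hydrophobic side pocket; scores descend with the pY+0
    reference on top, so pose-variation analysis yields 14/20 = 0.70 for
    pY+0 and 6/20 = 0.30 for pY-X. Displacement magnitudes are drawn in
    [0.3·jitter, jitter], so raising ``jitter`` beyond the cluster cutoff
    strictly disperses both clusters.
    """
    pm = _default_pocket("STAT3", spec_sep=10.0, radius=4.5, mcf=0.2)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x57A77]))
    # orient the scaffold along y so it engages a single pocket
    rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    template = LIGAND_TEMPLATE @ rot.T
    centers = {
        "py0": pm.anchors["py0"].mean(axis=0),
        "pyx": pm.anchors["pyx"].mean(axis=0),
    }
    poses = []
    plan = [("py0", 10.0, n_py0), ("pyx", 8.0, n_pyx)]
    idx = 0
    for key, top_score, count in plan:
        for j in range(count):
            if j == 0:
                shift = np.zeros(3)  # the class reference sits exactly on the anchors
            else:
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                shift = direction * (jitter * rng.uniform(0.3, 1.0))
            poses.append(
                LigandPose(
                    compound_id="stattic",
                    receptor_id="STAT3",
                    pose_index=idx,
                    score=top_score - 0.1 * j,
                    coords=template + centers[key] + shift,
                    elements=LIGAND_ELEMENTS,
                )
            )
            idx += 1
    return PoseSet(compound_id="stattic", receptor_id="STAT3", poses=poses), pm
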