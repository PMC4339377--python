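"""The five-step comparative screening procedure.

Stages: (1) pre-screen ingest (fast docking, 3 poses/ligand), (2) primary
CBAV filter at the selection threshold, (3) re-screen ingest for the
survivors (accurate docking, 20 poses/ligand), (4) secondary CBAV filter,
(5) pose-conservation (LBPV) validation with classification and ranking.
The package has no docking engine — both ingest stages consume externally
produced (or synthetically generated) pose files.

Classification combines the two statistics: high worst-case CBAV plus a
conserved target binding pose predicts target specificity; low CBAV plus
a diffuse pose ensemble indicates cross-binding; everything in between is
left indeterminate. The published hit tables include "specific" compounds
with off-target LBPV slightly above the nominal 0.2 band, so the
off-target test allows a configurable slack (default 0.15) on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

from .errors import ConfigError, DataError
from .pocket_geometry import assign_all
from .pose_io import (
    PocketModel,
    PoseSet,
    ScreeningConfig,
    read_pocket_model,
    read_pose_file,
    top_pose,
    truncate_poses,
)
from .selectivity import (
    LBPVResult,
    SelectivityProfile,
    aggregate_cbav,
    compute_cbav,
    compute_lbpv,
    lbpv_summary,
    round2,
)

__all__ = [
    "Classification",
    "HitRecord",
    "StageLog",
    "ScreenInputs",
    "ScreenResult",
    "primary_filter",
    "secondary_filter",
    "classify",
    "rank_hits",
    "run_screen",
    "run_pipeline",
    "write_report",
]


class Classification(Enum):
    SPECIFIC = "SPECIFIC"
    CROSS_BINDING = "CROSS_BINDING"
    INDETERMINATE = "INDETERMINATE"


@dataclass
class StageLog:
    stage: str
    input_count: int
    output_count: int


@dataclass(eq=False)
class HitRecord:
    """A compound's full triage outcome."""

    compound_id: str
    target_receptor: str
    top_affinity: float
    cbav: dict[str, float]
    cbav_aggregate: float
    lbpv_target: float
    lbpv_offtarget: dict[str, float]
    classification: Classification
    rank: int = 0


@dataclass(eq=False)
class ScreenInputs:
    """In-memory inputs of one screening run.

    ``prescreen`` and ``rescreen`` map receptor id → compound id →
    PoseSet; ``pockets`` maps receptor id → PocketModel. Built directly
    (e.g. from the synthetic campaign generator) or from files via
    :func:`load_screen_inputs`.
    """

    prescreen: dict[str, dict[str, PoseSet]]
    rescreen: dict[str, dict[str, PoseSet]]
    pockets: dict[str, PocketModel]

    @property
    def receptors(self) -> list[str]:
        return list(self.prescreen)


@dataclass(eq=False)
class ScreenResult:
    records: list[HitRecord]
    logs: list[StageLog]
    prescreen_profiles: list[SelectivityProfile]
    rescreen_profiles: list[SelectivityProfile]
    lbpv: dict[tuple[str, str], LBPVResult]


def _cbav_filter(
    profiles: list[SelectivityProfile], cfg: ScreeningConfig, stage: str
) -> tuple[list[str], StageLog]:
    kept = [
        p.compound_id
        for p in profiles
        if aggregate_cbav(p, cfg.cbav_aggregation, cfg.competitor_receptor)
        >= cfg.cbav_min
    ]
    return kept, StageLog(stage=stage, input_count=len(profiles), output_count=len(kept))


def primary_filter(
    profiles: list[SelectivityProfile], cfg: ScreeningConfig
) -> tuple[list[str], StageLog]:
    """Keep compounds whose aggregate CBAV clears the selection threshold."""
    return _cbav_filter(profiles, cfg, "primary_filter")


def secondary_filter(
    profiles: list[SelectivityProfile], cfg: ScreeningConfig
) -> tuple[list[str], StageLog]:
    """Same contract as the primary filter, applied to re-screen profiles."""
    return _cbav_filter(profiles, cfg, "secondary_filter")


def classify(
    cbav_aggregate: float,
    lbpv_target: float,
    lbpv_offtarget: dict[str, float],
    cfg: ScreeningConfig,
) -> Classification:
    """Label a candidate as target-specific, cross-binding or indeterminate."""
    max_off = max(lbpv_offtarget.values()) if lbpv_offtarget else 0.0
    if (
        cbav_aggregate >= cfg.cbav_min
        and lbpv_target >= cfg.lbpv_specific
        and max_off <= cfg.lbpv_nonspecific + cfg.lbpv_offtarget_slack
    ):
        return Classification.SPECIFIC
    if cbav_aggregate <= cfg.cbav_min and lbpv_target <= cfg.lbpv_nonspecific:
        return Classification.CROSS_BINDING
    return Classification.INDETERMINATE


def rank_hits(records: list[HitRecord], cfg: ScreeningConfig) -> list[HitRecord]:
    """Order hits by CBAV against the competitor (or the aggregate CBAV).

    Sort key: competitor CBAV descending, then top affinity descending,
    then compound id; ranks are assigned 1..n.
    """
    comp = cfg.competitor_receptor

    def key(rec: HitRecord):
        if comp is not None:
            if comp not in rec.cbav:
                raise ConfigError(
                    f"competitor {comp!r} missing from CBAV map of "
                    f"{rec.compound_id!r}"
                )
            primary = rec.cbav[comp]
        else:
            primary = rec.cbav_aggregate
        return (-primary, -rec.top_affinity, rec.compound_id)

    ranked = sorted(records, key=key)
    for i, rec in enumerate(ranked, start=1):
        rec.rank = i
    return ranked


def _profiles_from_stage(
    stage_sets: dict[str, dict[str, PoseSet]],
    cfg: ScreeningConfig,
    max_poses: int,
) -> list[SelectivityProfile]:
    compounds: list[str] = []
    for per_receptor in stage_sets.values():
        for cid in per_receptor:
            if cid not in compounds:
                compounds.append(cid)
    profiles = []
    for cid in sorted(compounds):
        scores = {}
        for rid, per_receptor in stage_sets.items():
            if cid not in per_receptor:
                raise DataError(
                    f"compound {cid!r} has no pose set for receptor {rid!r}"
                )
            scores[rid] = top_pose(truncate_poses(per_receptor[cid], max_poses)).score
        profiles.append(compute_cbav(scores, cfg.target_receptor, compound_id=cid))
    return profiles


def run_screen(inputs: ScreenInputs, cfg: ScreeningConfig) -> ScreenResult:
    """Execute the five stages on in-memory inputs and return ranked hits."""
    if cfg.target_receptor not in inputs.prescreen:
        raise ConfigError(
            f"target receptor {cfg.target_receptor!r} has no pre-screen data"
        )
    logs: list[StageLog] = []

    # 1. pre-screen ingest
    pre_profiles = _profiles_from_stage(inputs.prescreen, cfg, cfg.prescreen_poses)
    logs.append(
        StageLog("prescreen", input_count=len(pre_profiles), output_count=len(pre_profiles))
    )

    # 2. primary CBAV filter
    survivors, log = primary_filter(pre_profiles, cfg)
    logs.append(log)

    # 3. re-screen ingest, restricted to survivors
    missing = [
        f"{cid}@{rid}"
        for rid in inputs.rescreen
        for cid in survivors
        if cid not in inputs.rescreen[rid]
    ]
    if missing:
        raise DataError(
            "survivors absent from re-screen pose sets: " + ", ".join(sorted(missing))
        )
    rescreen = {
        rid: {cid: sets[cid] for cid in survivors}
        for rid, sets in inputs.rescreen.items()
    }
    logs.append(StageLog("rescreen", input_count=len(survivors), output_count=len(survivors)))

    # 4. secondary CBAV filter
    if survivors:
        re_profiles = _profiles_from_stage(rescreen, cfg, cfg.rescreen_poses)
    else:
        re_profiles = []
    finalists, log = secondary_filter(re_profiles, cfg)
    logs.append(log)
    finalist_profiles = {p.compound_id: p for p in re_profiles if p.compound_id in finalists}

    # 5. LBPV validation, classification, ranking
    if cfg.offtarget_lbpv_panel:
        off_receptors = [r for r in inputs.rescreen if r != cfg.target_receptor]
    elif cfg.competitor_receptor is not None:
        off_receptors = [cfg.competitor_receptor]
    else:
        off_receptors = []

    lbpv_results: dict[tuple[str, str], LBPVResult] = {}
    records: list[HitRecord] = []
    for cid in finalists:
        profile = finalist_profiles[cid]
        per_receptor_lbpv: dict[str, float] = {}
        for rid in [cfg.target_receptor, *off_receptors]:
            ps = truncate_poses(inputs.rescreen[rid][cid], cfg.rescreen_poses)
            pm = inputs.pockets[rid]
            result = compute_lbpv(
                ps,
                assign_all(ps, pm),
                rmsd_cluster=cfg.rmsd_cluster,
                symmetry=cfg.symmetry_rmsd,
            )
            lbpv_results[(cid, rid)] = result
            per_receptor_lbpv[rid] = lbpv_summary(result)
        agg = aggregate_cbav(profile, cfg.cbav_aggregation, cfg.competitor_receptor)
        lbpv_off = {r: per_receptor_lbpv[r] for r in off_receptors}
        records.append(
            HitRecord(
                compound_id=cid,
                target_receptor=cfg.target_receptor,
                top_affinity=profile.top_scores[cfg.target_receptor],
                cbav=dict(profile.cbav),
                cbav_aggregate=agg,
                lbpv_target=per_receptor_lbpv[cfg.target_receptor],
                lbpv_offtarget=lbpv_off,
                classification=classify(
                    agg, per_receptor_lbpv[cfg.target_receptor], lbpv_off, cfg
                ),
            )
        )
    records = rank_hits(records, cfg)
    logs.append(
        StageLog("lbpv_validation", input_count=len(finalists), output_count=len(records))
    )
    return ScreenResult(
        records=records,
        logs=logs,
        prescreen_profiles=pre_profiles,
        rescreen_profiles=re_profiles,
        lbpv=lbpv_results,
    )


# ---------------------------------------------------------------------------
# file-based entry point


def _load_pocket(entry: dict, rid: str, base: Path) -> PocketModel:
    radius = float(entry.get("contact_radius", 4.5))
    mcf = float(entry.get("min_contact_fraction", 0.2))
    if "anchors" in entry:  # direct coordinate lists (synthetic campaigns)
        return PocketModel(
            receptor_id=rid,
            anchors={k: entry["anchors"][k] for k in ("py0", "pyx")},
            contact_radius=radius,
            min_contact_fraction=mcf,
        )
    return read_pocket_model(
        base / entry["structure"],
        selections={"py0": entry["py0"], "pyx": entry["pyx"]},
        contact_radius=radius,
        min_contact_fraction=mcf,
        receptor_id=rid,
    )


def load_screen_inputs(config: dict, base: Path) -> tuple[ScreenInputs, ScreeningConfig]:
    """Build screen inputs from a parsed run-configuration mapping."""
    cfg = ScreeningConfig(**config["screening"])
    fmt = config.get("pose_format", "sdf")
    score_field = config.get("score_field", "docking_score")
    prescreen: dict[str, dict[str, PoseSet]] = {}
    rescreen: dict[str, dict[str, PoseSet]] = {}
    pockets: dict[str, PocketModel] = {}
    for rid, entry in config["receptors"].items():
        pockets[rid] = _load_pocket(entry["pocket"], rid, base)
        for stage, target in (("prescreen", prescreen), ("rescreen", rescreen)):
            sets = read_pose_file(
                base / entry[stage],
                format=fmt,
                score_field=score_field,
                receptor_id=rid,
                scores_path=(base / entry[f"{stage}_scores"])
                if f"{stage}_scores" in entry
                else None,
            )
            target[rid] = {ps.compound_id: ps for ps in sets}
    return ScreenInputs(prescreen=prescreen, rescreen=rescreen, pockets=pockets), cfg


def write_report(result: ScreenResult, report_path, stage_log_path) -> None:
    """Write the ranked hit table and the stage log as TSV (2-decimal values)."""
    import pandas as pd

    receptors = sorted({r for rec in result.records for r in rec.cbav})
    rows = []
    for rec in result.records:
        row = {
            "compound_id": rec.compound_id,
            "rank": rec.rank,
            "top_affinity": f"{round2(rec.top_affinity):.2f}",
        }
        for rid in receptors:
            row[f"cbav_{rid}"] = f"{round2(rec.cbav[rid]):.2f}"
        row["cbav_aggregate"] = f"{round2(rec.cbav_aggregate):.2f}"
        row["lbpv_target"] = f"{round2(rec.lbpv_target):.2f}"
        row["lbpv_offtarget"] = ";".join(
            f"{rid}={round2(v):.2f}" for rid, v in sorted(rec.lbpv_offtarget.items())
        )
        row["classification"] = rec.classification.value
        rows.append(row)
    columns = (
        ["compound_id", "rank", "top_affinity"]
        + [f"cbav_{rid}" for rid in receptors]
        + ["cbav_aggregate", "lbpv_target", "lbpv_offtarget", "classification"]
    )
    pd.DataFrame(rows, columns=columns).to_csv(report_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {"stage": log.stage, "input_count": log.input_count, "output_count": log.output_count}
            for log in result.logs
        ]
    ).to_csv(stage_log_path, sep="\t", index=False)


def run_pipeline(run_config) -> ScreenResult:
    """Run the full procedure from a YAML run configuration file.

    Writes ``hits.tsv`` and ``stage_log.tsv`` into the configured output
    directory (default: next to the config file) and returns the result.
    Deterministic for identical inputs.
    """
    run_config = Path(run_config)
    config = yaml.safe_load(run_config.read_text())
    base = run_config.parent
    inputs, cfg = load_screen_inputs(config, base)
    result = run_screen(inputs, cfg)
    out_dir = base / config.get("output_dir", ".")
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(result, out_dir / "hits.tsv", out_dir / "stage_log.tsv")
    return result
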