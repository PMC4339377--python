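import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from statscreen import (
    CampaignSpec,
    Classification,
    ConfigError,
    PocketClass,
    ScreeningConfig,
    assign_all,
    compute_lbpv,
    emit_worked_example,
    generate_campaign,
    read_pose_file,
    run_screen,
    top_pose,
    write_campaign,
)


def _spec(**kw):
    base = dict(seed=5, n_compounds=10, n_specific_per_target=2, n_cross_binders=2)
    base.update(kw)
    return CampaignSpec(**base)


class TestDeterminism:
    def test_same_seed_same_campaign_objects(self):
        a, b = generate_campaign(_spec()), generate_campaign(_spec())
        for rid in a.spec.receptors:
            for cid, ps in a.rescreen[rid].items():
                other = b.rescreen[rid][cid]
                assert [p.score for p in ps.poses] == [p.score for p in other.poses]
                for pa, pb in zip(ps.poses, other.poses):
                    assert np.array_equal(pa.coords, pb.coords)

    def test_same_seed_hash_equal_files(self, tmp_path):
        for name in ("one", "two"):
            write_campaign(generate_campaign(_spec()), tmp_path / name)
        for f in sorted((tmp_path / "one").iterdir()):
            a = hashlib.sha256(f.read_bytes()).hexdigest()
            b = hashlib.sha256((tmp_path / "two" / f.name).read_bytes()).hexdigest()
            assert a == b, f.name

    def test_different_seeds_differ(self):
        a = generate_campaign(_spec(seed=1))
        b = generate_campaign(_spec(seed=2))
        ps_a = a.rescreen["STAT1"]["CPD_0001"]
        ps_b = b.rescreen["STAT1"]["CPD_0001"]
        assert [p.score for p in ps_a.poses] != [p.score for p in ps_b.poses]

    def test_subsetting_compounds_leaves_others_untouched(self):
        small = generate_campaign(_spec(n_compounds=6))
        large = generate_campaign(_spec(n_compounds=10))
        ps_s = small.rescreen["STAT2"]["CPD_0003"]
        ps_l = large.rescreen["STAT2"]["CPD_0003"]
        assert [p.score for p in ps_s.poses] == [p.score for p in ps_l.poses]
        for pa, pb in zip(ps_s.poses, ps_l.poses):
            assert np.array_equal(pa.coords, pb.coords)


class TestGeneratedFiles:
    def test_files_parse_cleanly_and_match_memory(self, tmp_path):
        camp = generate_campaign(_spec())
        write_campaign(camp, tmp_path)
        for rid in camp.spec.receptors:
            sets = read_pose_file(tmp_path / f"{rid}_rescreen.sdf", receptor_id=rid)
            assert {ps.compound_id for ps in sets} == set(camp.rescreen[rid])
            for ps in sets:
                orig = camp.rescreen[rid][ps.compound_id]
                assert len(ps) == len(orig)
                assert np.abs(ps.poses[0].coords - orig.poses[0].coords).max() < 1e-4

    def test_ground_truth_tsv_partitions_compounds(self, tmp_path):
        camp = generate_campaign(_spec())
        write_campaign(camp, tmp_path)
        rows = [
            line.split("\t")
            for line in (tmp_path / "ground_truth.tsv").read_text().splitlines()
        ]
        assert len(rows) == 10
        labels = {r[0]: r[1] for r in rows}
        assert sorted(labels.values()).count("SPECIFIC") == 2
        assert sorted(labels.values()).count("CROSS_BINDER") == 2
        assert sorted(labels.values()).count("DECOY") == 6

    def test_overlapping_pockets_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            _spec(anchor_separation=6.0, contact_radius=4.5)


class TestScoreModel:
    def test_closed_form_matches_monte_carlo_for_iid_differences(self, rng):
        # score-model math: with per-receptor score differences iid
        # N(delta, sigma*sqrt(2)), the chance that the worst of 6 clears the
        # 3.0 threshold has the closed form Phi((delta-3)/(sigma*sqrt(2)))^6
        delta, sigma = 4.0, 0.3
        closed = stats.norm.cdf((delta - 3.0) / (sigma * np.sqrt(2))) ** 6
        draws = rng.normal(delta, sigma * np.sqrt(2), size=(10_000, 6))
        mc = (draws.min(axis=1) >= 3.0).mean()
        assert mc == pytest.approx(closed, abs=0.01)
        assert closed > 0.9

    def test_truncated_generator_always_separates_at_default_delta(self, rng):
        # the generator truncates at +/-1.5 sigma, so the worst-case CBAV of a
        # planted specific is at least delta - 3*sigma = 3.1 > 3.0; verify by
        # an independent truncated-normal simulation of the top-of-k scores
        tn = stats.truncnorm(-1.5, 1.5)
        reps = 10_000
        on = 12.0 + 0.3 * tn.rvs((reps, 3), random_state=rng).max(axis=1)
        off = 8.0 + 0.3 * tn.rvs((reps, 6, 3), random_state=rng).max(axis=2).max(axis=1)
        assert ((on - off) >= 3.0).mean() == 1.0
        assert (on - off).min() >= 4.0 - 2 * 1.5 * 0.3 - 1e-9

    def test_planted_specific_cbav_clears_threshold(self):
        camp = generate_campaign(_spec())
        spec_ids = camp.ground_truth.of("SPECIFIC")
        for cid in spec_ids:
            scores = {
                rid: top_pose(camp.prescreen[rid][cid]).score
                for rid in camp.spec.receptors
            }
            diffs = [scores["STAT1"] - scores[r] for r in scores if r != "STAT1"]
            assert min(diffs) >= 3.0

    def test_scores_within_reported_regime(self):
        camp = generate_campaign(_spec())
        all_scores = [
            p.score
            for rid in camp.spec.receptors
            for ps in camp.rescreen[rid].values()
            for p in ps.poses
        ]
        assert 3.0 < min(all_scores) and max(all_scores) < 15.0


class TestPoseClusters:
    def test_tight_jitter_keeps_cluster_within_cutoff(self):
        # jitter 0.15 A (RMS displacement) => pose-to-reference in-frame RMSD
        # follows (sqrt(2)*0.15/sqrt(3)) * chi_3; P(< 0.5) is essentially 1
        s = 0.15 / np.sqrt(3)
        p_within = stats.chi2.cdf((0.5 / (np.sqrt(2) * s)) ** 2, df=3)
        assert p_within > 0.999
        camp = generate_campaign(_spec())
        for cid in camp.ground_truth.of("SPECIFIC"):
            ps = camp.rescreen["STAT1"][cid]
            pm = camp.pockets["STAT1"]
            result = compute_lbpv(ps, assign_all(ps, pm))
            assert result.values[PocketClass.BOTH] >= 0.8

    def test_offtarget_poses_are_diffuse(self):
        camp = generate_campaign(_spec())
        for cid in camp.ground_truth.of("SPECIFIC"):
            ps = camp.rescreen["STAT3"][cid]
            result = compute_lbpv(ps, assign_all(ps, camp.pockets["STAT3"]))
            values = [result.values[c] for c in
                      (PocketClass.PY0, PocketClass.PYX, PocketClass.BOTH)]
            assert max(values) <= 0.35

    def test_degrading_separation_kills_recall(self):
        cfg = ScreeningConfig(target_receptor="STAT1", competitor_receptor="STAT3")
        camp = generate_campaign(_spec(delta=1.0))
        result = run_screen(camp.inputs(), cfg)
        called = {
            r.compound_id
            for r in result.records
            if r.classification is Classification.SPECIFIC
        }
        planted = set(camp.ground_truth.of("SPECIFIC"))
        recall = len(called & planted) / len(planted)
        assert recall < 0.5


class TestWorkedExample:
    def test_pattern_counts_by_construction(self):
        ps, pm = emit_worked_example()
        classes = [a.pocket_class for a in assign_all(ps, pm)]
        assert classes.count(PocketClass.PY0) == 14
        assert classes.count(PocketClass.PYX) == 6

    def test_scores_descend_with_py0_reference_on_top(self):
        ps, _ = emit_worked_example()
        assert top_pose(ps).pose_index == 0
        py0_scores = [p.score for p in ps.poses[:14]]
        assert py0_scores == sorted(py0_scores, reverse=True)

    def test_raising_jitter_strictly_drops_values(self):
        tight, pm = emit_worked_example(jitter=0.12)
        loose, pm2 = emit_worked_example(jitter=2.0)
        v_tight = compute_lbpv(tight, assign_all(tight, pm)).values
        v_loose = compute_lbpv(loose, assign_all(loose, pm2)).values
        for cls in (PocketClass.PY0, PocketClass.PYX):
            assert v_loose[cls] < v_tight[cls]
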