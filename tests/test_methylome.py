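"""Coverage-file handling, context calls, segmentation and DMR calling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myomics import methylome as M
from myomics import synthetic
from conftest import interval_jaccard


class TestCovIO:
    def test_level_from_counts(self, tmp_path):
        p = tmp_path / "a.cov"
        p.write_text("chr1\t100\t100\t75\t3\t1\n")
        track = M.read_cov(p)
        assert track.loc[0, "level"] == 0.75

    def test_zero_read_line_rejected(self, tmp_path):
        p = tmp_path / "a.cov"
        p.write_text("chr1\t100\t100\t0\t0\t0\n")
        with pytest.raises(ValueError, match="zero total reads"):
            M.read_cov(p)

    def test_percentage_mismatch_warns(self, tmp_path, caplog):
        p = tmp_path / "a.cov"
        p.write_text("chr1\t100\t100\t10\t3\t1\n")  # counts say 75%
        with caplog.at_level("WARNING"):
            M.read_cov(p)
        assert "disagrees" in caplog.text

    def test_round_trip(self, tmp_path, methylome_data):
        track = methylome_data[0]["M3_1"]
        path = tmp_path / "t.cov"
        M.write_cov(path, track)
        back = M.read_cov(path)
        pd.testing.assert_frame_equal(
            back, track.reset_index(drop=True), check_dtype=False)


class TestContext:
    def test_cg(self):
        assert M.classify_context({"c": "AACGT"}, [("c", 3, "+")]) == ["CG"]

    def test_chg(self):
        assert M.classify_context({"c": "ACAGT"}, [("c", 2, "+")]) == ["CHG"]

    def test_chh_and_minus_strand(self):
        assert M.classify_context({"c": "ACATT"}, [("c", 2, "+")]) == ["CHH"]
        # minus-strand C pairs with G on the plus strand: plus "CG" at 1-2
        assert M.classify_context({"c": "ACGTT"}, [("c", 3, "-")]) == ["CG"]

    def test_matches_brute_force_triplets(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        positions = [i + 1 for i, b in enumerate(seq) if b == "C"]
        got = M.classify_context({"c": seq}, [("c", p, "+") for p in positions])
        for p, ctx in zip(positions, got):
            trip = seq[p - 1: p + 2]
            if len(trip) >= 2 and trip[1] == "G":
                expect = "CG"
            elif len(trip) == 3 and trip[2] == "G":
                expect = "CHG"
            else:
                expect = "CHH"
            assert ctx == expect

    def test_out_of_bounds_position(self):
        with pytest.raises(IndexError):
            M.classify_context({"c": "ACGT"}, [("c", 9, "+")])


class TestSnpFilter:
    def test_snp_at_c_position_removed(self):
        t = M.make_track("chr1", [100, 200], [3, 3], [1, 1])
        out = M.filter_snp_cpgs(t, {("chr1", 100)})
        assert list(out["pos"]) == [200]

    def test_snp_at_g_position_removed(self):
        t = M.make_track("chr1", [100], [3], [1])
        assert len(M.filter_snp_cpgs(t, {("chr1", 101)})) == 0

    def test_empty_snp_set_identity(self, methylome_data):
        t = methylome_data[0]["D3_1"]
        pd.testing.assert_frame_equal(M.filter_snp_cpgs(t, set()), t)

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(10_000, size=300, replace=False)) + 1
        t = M.make_track("chr1", pos, np.full(300, 2), np.full(300, 2))
        snps = {("chr1", int(p)) for p in rng.choice(10_000, 100) + 1}
        out = M.filter_snp_cpgs(t, snps)
        expect = [p for p in pos if ("chr1", p) not in snps
                  and ("chr1", p + 1) not in snps]
        assert list(out["pos"]) == expect


class TestSegmentation:
    def test_uniform_high_track_single_hmd(self):
        pos = np.arange(100, 5100, 50)
        t = M.make_track("chr1", pos, np.full(pos.size, 9), np.full(pos.size, 1))
        segs = M.segment_methylome(t)
        assert len(segs) == 1 and segs[0].klass == "HMD"

    def test_low_run_of_40_becomes_umr(self):
        pos = np.arange(100, 100 + 50 * 200, 50)
        meth = np.full(pos.size, 18)
        meth[80:120] = 1  # 40 CpGs at 5%
        t = M.make_track("chr1", pos, meth, 20 - meth)
        segs = M.segment_methylome(t)
        umrs = [s for s in segs if s.klass == "UMR"]
        assert len(umrs) == 1
        assert umrs[0].n_cpg == pytest.approx(40, abs=3)

    def test_planted_plan_recovered(self, methylome_data):
        tracks, seg_truth, _ = methylome_data
        segs = M.segment_methylome(tracks["D3_1"])
        for klass in M.SEGMENT_CLASSES:
            truth_iv = [(r.start, r.end) for r in seg_truth.itertuples()
                        if r.klass == klass]
            rec_iv = [(s.start, s.end) for s in segs if s.klass == klass]
            assert interval_jaccard(truth_iv, rec_iv) >= 0.8, klass

    def test_segments_tile_covered_genome(self, methylome_data):
        segs = M.segment_methylome(methylome_data[0]["M12_2"])
        assert M.segments_tile(segs)
        classes = {s.klass for s in segs}
        assert classes <= set(M.SEGMENT_CLASSES)

    def test_lower_cutoff_never_increases_low_bp(self, methylome_data):
        track = methylome_data[0]["D3_1"]
        def low_bp(cutoff):
            segs = M.segment_methylome(
                track, M.SegmentationParams(low_cutoff=cutoff))
            return sum(s.end - s.start for s in segs
                       if s.klass in ("UMR", "LMR"))
        assert low_bp(0.3) <= low_bp(0.5) <= low_bp(0.7)

    def test_empty_track_empty_segmentation(self):
        t = M.make_track("chr1", np.array([], int), np.array([], int),
                         np.array([], int))
        assert M.segment_methylome(t) == []


class TestMergeLmrUmr:
    def _segs(self, lmr_means, umr_means):
        out = []
        for i, m in enumerate(lmr_means):
            out.append(M.Segment("chr1", 100 * i, 100 * i + 50, "LMR", 5, m))
        for i, m in enumerate(umr_means):
            out.append(M.Segment("chr2", 100 * i, 100 * i + 50, "UMR", 40, m))
        return out

    def test_merge_applied_unconditionally(self):
        merged, p = M.merge_lmr_umr(self._segs([0.1, 0.2], [0.3, 0.4]))
        assert all(s.klass != "UMR" for s in merged)
        assert p < 1.0

    def test_identical_distributions_p_near_one(self):
        merged, p = M.merge_lmr_umr(self._segs([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]))
        assert p > 0.5

    def test_exact_p_matches_enumeration(self):
        """Exact rank-sum p equals full enumeration of group assignments."""
        lmr, umr = [0.05, 0.12, 0.2], [0.15, 0.25, 0.3, 0.35]
        _, p = M.merge_lmr_umr(self._segs(lmr, umr))
        pooled = lmr + umr
        ranks = stats.rankdata(pooled)
        observed = ranks[:3].sum()
        stat_null = [sum(c) for c in itertools.combinations(ranks, 3)]
        mean_null = np.mean(stat_null)
        extreme = np.mean([abs(s - mean_null) >= abs(observed - mean_null) - 1e-12
                           for s in stat_null])
        assert p == pytest.approx(extreme, abs=1e-12)

    def test_absent_class_p_undefined(self):
        merged, p = M.merge_lmr_umr(self._segs([0.1], []))
        assert np.isnan(p) and merged[0].klass == "LMR"


class TestDMRs:
    def test_identical_groups_no_dmrs(self, methylome_data):
        tracks, _, _ = methylome_data
        a = [tracks["D3_1"]]
        assert M.call_dmrs(a, [tracks["D3_1"].copy()]) == []

    def test_planted_dmrs_recovered_within_two_cpgs(self, methylome_data):
        tracks, _, dmr_truth = methylome_data
        ga = [t for k, t in tracks.items() if k.split("_")[0] in ("D3", "M3")]
        gb = [t for k, t in tracks.items() if k.split("_")[0] in ("M6", "M12")]
        dmrs = M.call_dmrs(ga, gb)
        pos = np.sort(tracks["D3_1"]["pos"].to_numpy())
        for row in dmr_truth.itertuples():
            hits = [d for d in dmrs if d.start < row.end and row.start < d.end]
            assert hits, f"planted DMR {row.start}-{row.end} missed"
            s = min(d.start for d in hits)
            e = max(d.end for d in hits)
            err_start = abs(np.searchsorted(pos, s) - np.searchsorted(pos, row.start))
            err_end = abs(np.searchsorted(pos, e) - np.searchsorted(pos, row.end))
            assert max(err_start, err_end) <= 2

    def test_sign_coherence_by_construction(self, methylome_data):
        tracks, _, _ = methylome_data
        ga = [tracks["D3_1"], tracks["D3_2"]]
        gb = [tracks["M12_1"], tracks["M12_2"]]
        for d in M.call_dmrs(ga, gb):
            assert d.delta != 0  # merged CpGs share one sign, so delta cannot cancel

    def test_no_common_positions_empty(self):
        a = M.make_track("chr1", [100], [3], [1])
        b = M.make_track("chr2", [100], [3], [1])
        assert M.call_dmrs([a], [b]) == []

    def test_null_false_positive_control(self):
        """Without planted DMRs the caller stays near zero calls (20 seeds)."""
        counts = []
        for seed in range(20):
            c = synthetic.SimConfig(
                seed=seed, n_cpgs=2000, chrom_length_bp=100_000,
                segment_plan=(("HMD", 100_000, 0.8),), n_dmrs=0)
            tracks, _, _ = synthetic.make_methylome(c)
            ga = [t for k, t in tracks.items() if k.split("_")[0] in ("D3", "M3")]
            gb = [t for k, t in tracks.items() if k.split("_")[0] in ("M6", "M12")]
            counts.append(len(M.call_dmrs(ga, gb)))
        assert np.mean(counts) <= 1.0


class TestFlankProfile:
    def test_uniform_track_inside_equals_flank(self):
        pos = np.arange(100, 3000, 50)
        t = M.make_track("chr1", pos, np.full(pos.size, 8), np.full(pos.size, 2))
        dmr = M.DMRRecord("chr1", 1000, 1500, 10, 0.8, 0.8, 0.01)
        prof = M.dmr_flank_profile([dmr], {"D3": t})
        assert prof.loc[0, "inside_mean"] == pytest.approx(prof.loc[0, "flank_mean"])

    def test_planted_low_dmr_inside_below_flank(self, methylome_data):
        tracks, _, dmr_truth = methylome_data
        dmrs = [M.DMRRecord(r.chrom, r.start, r.end, r.n_cpg, r.target_a,
                            r.target_b, 0.0) for r in dmr_truth.itertuples()]
        prof = M.dmr_flank_profile(dmrs, {"M12": tracks["M12_1"]})
        below = (prof["inside_mean"] < prof["flank_mean"]).mean()
        assert below >= 0.95

    def test_means_equal_brute_force(self, methylome_data):
        tracks, _, dmr_truth = methylome_data
        t = tracks["M6_1"]
        r = dmr_truth.iloc[0]
        dmr = M.DMRRecord(r.chrom, r.start, r.end, r.n_cpg, 0, 0, 0)
        prof = M.dmr_flank_profile([dmr], {"x": t}, flank_bp=500)
        inside = t[(t.pos > r.start) & (t.pos <= r.end)]["level"].mean()
        assert prof.loc[0, "inside_mean"] == pytest.approx(inside)


class TestChromosomeMeans:
    def test_means_equal_direct_averaging(self, methylome_data):
        tracks, _, _ = methylome_data
        stage_tracks = {"D3": [tracks["D3_1"], tracks["D3_2"]],
                        "M12": [tracks["M12_1"], tracks["M12_2"]]}
        means, tests = M.chromosome_mean_meth(stage_tracks)
        expect = tracks["D3_1"]["level"].mean()
        got = means.query("stage == 'D3' and replicate == 0")["mean_meth"].item()
        assert got == pytest.approx(expect)

    def test_identical_stages_no_significant_pairs(self, methylome_data):
        t = methylome_data[0]["D3_1"]
        stage_tracks = {"A": [t, t.copy()], "B": [t.copy(), t.copy()]}
        _, tests = M.chromosome_mean_meth(stage_tracks)
        assert (tests["qvalue"] > 0.05).all()

    def test_shifted_chromosome_flagged(self):
        rng = np.random.default_rng(6)
        def mk(shift=0.0):
            pos = np.arange(100, 100 + 50 * 400, 50)
            p = np.clip(0.5 + shift + rng.normal(0, 0.01), 0, 1)
            cov = np.full(pos.size, 30)
            m = rng.binomial(30, p, size=pos.size)
            return M.make_track("chr1", pos, m, cov - m)
        stage_tracks = {"A": [mk(), mk()], "B": [mk(0.2), mk(0.2)]}
        _, tests = M.chromosome_mean_meth(stage_tracks)
        assert (tests["qvalue"] < 0.05).any()

    def test_single_replicate_means_only(self, methylome_data):
        t = methylome_data[0]["D3_1"]
        means, tests = M.chromosome_mean_meth({"A": [t], "B": [t]})
        assert len(means) == 2 and tests.empty
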