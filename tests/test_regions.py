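"""Interval IO, four-way annotation, consensus peaks and DAR calling."""

import numpy as np
import pandas as pd
import pytest

from myomics import regions as rg
from myomics import synthetic


class TestIO:
    def test_bed_line_coordinates(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        (iv,) = rg.read_bed(p)
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 100, 200)

    def test_gtf_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n')
        (g,) = rg.read_gene_models(p)
        assert (g.start, g.end, g.tss) == (100, 200, 100)

    def test_minus_strand_tss(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\tgene\t101\t200\t.\t-\t.\tgene_id "g1";\n')
        (g,) = rg.read_gene_models(p)
        assert g.tss == 199

    def test_bed_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        ivs = []
        for i in range(1000):
            s = int(rng.integers(0, 1_000_000))
            ivs.append(rg.GenomicInterval(f"chr{1 + i % 3}", s,
                                          s + int(rng.integers(1, 500)),
                                          "+-."[i % 3], f"iv{i}", float(i)))
        path = tmp_path / "r.bed"
        rg.write_bed(path, ivs)
        assert rg.read_bed(path) == ivs

    def test_narrowpeak_round_trip(self, tmp_path, peak_data):
        peaks = peak_data[0]["D3_1"]
        path = tmp_path / "p.narrowPeak"
        rg.write_narrowpeak(path, peaks)
        got = rg.read_narrowpeak(path)
        assert [(p.chrom, p.start, p.end, p.name) for p in got] == \
            [(p.chrom, p.start, p.end, p.name) for p in peaks]

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\nchr1\tnope\t5\n")
        with pytest.raises(rg.ParseError, match="bad.bed:2"):
            rg.read_bed(p)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            rg.GenomicInterval("chr1", 200, 100)


def brute_force_annotation(peak, genes, promoter_bp=3000, downstream_bp=3000):
    """Independent per-feature overlap oracle for the four-way annotation."""
    mid = (peak.start + peak.end) // 2
    found = []
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        if g.strand != "-":
            prom = range(g.tss - promoter_bp, g.tss)
            down = range(g.end, g.end + downstream_bp)
        else:
            prom = range(g.tss + 1, g.tss + 1 + promoter_bp)
            down = range(g.start - downstream_bp, g.start)
        if mid in prom:
            found.append("promoter")
        if g.start <= mid < g.end:
            found.append("gene_body")
        if mid in down:
            found.append("downstream")
    for feat, cat in (("promoter", "upstream"), ("gene_body", "gene_body"),
                      ("downstream", "downstream")):
        if feat in found:
            return cat
    return "distal"


@pytest.fixture(scope="module")
def genes():
    return [
        rg.GeneModel("gplus", "chr1", 10_000, 14_000, "+",
                     exons=((10_000, 10_500), (13_000, 14_000))),
        rg.GeneModel("gminus", "chr1", 30_000, 34_000, "-"),
        rg.GeneModel("gother", "chr2", 10_000, 14_000, "+"),
    ]


class TestAnnotation:
    def test_upstream_of_plus_tss(self, genes):
        ann = rg.annotate_feature(rg.GenomicInterval("chr1", 9_400, 9_600), genes)
        assert ann.category == "upstream"
        assert ann.nearest_gene == "gplus"

    def test_intron_overlapping_other_promoter_is_upstream(self):
        """Promoter precedence beats intron when features overlap."""
        host = rg.GeneModel("host", "chr1", 0, 50_000, "+",
                            exons=((0, 100), (49_000, 50_000)))
        nested = rg.GeneModel("nested", "chr1", 20_000, 25_000, "+")
        peak = rg.GenomicInterval("chr1", 18_400, 18_600)  # intron of host,
        ann = rg.annotate_feature(peak, [host, nested])    # promoter of nested
        assert ann.category == "upstream"

    def test_minus_strand_promoter_mirrored(self, genes):
        ann = rg.annotate_feature(rg.GenomicInterval("chr1", 34_400, 34_600),
                                  genes)
        assert ann.category == "upstream"
        assert ann.nearest_gene == "gminus"

    def test_every_peak_gets_exactly_one_category(self, genes):
        rng = np.random.default_rng(1)
        peaks = [rg.GenomicInterval("chr1", int(s), int(s) + 200)
                 for s in rng.integers(0, 60_000, size=100)]
        anns = rg.annotate_peaks(peaks, genes)
        assert len(anns) == 100
        assert all(a.category in rg.CATEGORIES for a in anns)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        genes = []
        for i in range(50):
            s = int(rng.integers(0, 480_000))
            genes.append(rg.GeneModel(f"g{i:02d}", "chr1", s,
                                      s + int(rng.integers(500, 8000)),
                                      "+" if rng.random() < 0.5 else "-"))
        peaks = [rg.GenomicInterval("chr1", int(s), int(s) + 300)
                 for s in rng.integers(0, 500_000, size=500)]
        for p in peaks:
            assert rg.annotate_feature(p, genes).category == \
                brute_force_annotation(p, genes)

    def test_empty_gene_set_everything_distal(self):
        ann = rg.annotate_feature(rg.GenomicInterval("chr1", 0, 100), [])
        assert ann.category == "distal" and ann.nearest_gene == ""


class TestConsensus:
    def test_identical_replicates_identity(self):
        peaks = [rg.GenomicInterval("chr1", 100 * i, 100 * i + 50)
                 for i in range(1, 5)]
        cons = rg.consensus_peaks([peaks, list(peaks)])
        assert [(p.start, p.end) for p in cons] == \
            [(p.start, p.end) for p in peaks]

    def test_disjoint_replicates_empty(self):
        a = [rg.GenomicInterval("chr1", 0, 100)]
        b = [rg.GenomicInterval("chr1", 500, 600)]
        assert rg.consensus_peaks([a, b]) == []

    def test_recovers_planted_core_exactly(self, peak_data):
        rep_sets, _, core, _ = peak_data
        cons = rg.consensus_peaks([rep_sets["M6_1"], rep_sets["M6_2"]])
        assert {p.name for p in cons} == {p.name for p in core}

    def test_monotone_in_min_frac(self, peak_data):
        rep_sets, _, _, _ = peak_data
        reps = [rep_sets["D3_1"], rep_sets["D3_2"]]
        sizes = [len(rg.consensus_peaks(reps, min_frac=f))
                 for f in (0.25, 0.5, 0.9)]
        assert sizes == sorted(sizes, reverse=True)


class TestCpGIslands:
    def test_all_inside(self):
        peaks = [rg.GenomicInterval("chr1", 10, 20)]
        islands = [rg.GenomicInterval("chr1", 0, 100)]
        assert rg.cpg_island_overlap_fraction(peaks, islands) == 1.0

    def test_none_overlapping(self):
        peaks = [rg.GenomicInterval("chr1", 10, 20)]
        islands = [rg.GenomicInterval("chr1", 50, 100)]
        assert rg.cpg_island_overlap_fraction(peaks, islands) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        peaks = [rg.GenomicInterval("chr1", int(s), int(s) + 100)
                 for s in rng.integers(0, 10_000, 50)]
        islands = [rg.GenomicInterval("chr1", int(s), int(s) + 300)
                   for s in rng.integers(0, 10_000, 20)]
        expect = np.mean([any(p.overlap_len(i) > 0 for i in islands)
                          for p in peaks])
        assert rg.cpg_island_overlap_fraction(peaks, islands) == expect

    def test_empty_peaks_error(self):
        with pytest.raises(ValueError, match="empty"):
            rg.cpg_island_overlap_fraction([], [])


class TestDifferentialRegions:
    def test_identical_groups_no_dars(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(300, size=(100, 8)),
                              index=[f"chr1:{i}-{i + 100}" for i in range(100)],
                              columns=[f"s{j}" for j in range(8)])
        dars = rg.differential_regions(counts, [f"s{j}" for j in range(4)],
                                       [f"s{j}" for j in range(4, 8)])
        assert dars == []

    def test_planted_effect_recovered(self, cfg, peak_data):
        _, counts, _, dar_truth = peak_data
        early = [c for c in counts.columns if c.split("_")[0] in ("D3", "M3")]
        late = [c for c in counts.columns if c.split("_")[0] in ("M6", "M12")]
        dars = rg.differential_regions(counts, early, late, "D3-M12")
        called = {d.region.name for d in dars}
        planted = set(dar_truth.peak_id)
        assert len(called & planted) / len(planted) >= 0.9
        ratios = [d.log2_ratio for d in dars if d.region.name in planted]
        assert np.mean(ratios) == pytest.approx(-cfg.dar_effect_log2, abs=0.2)

    def test_permuted_labels_controls_false_positives(self):
        """Average DAR count under label permutation stays near zero."""
        fps = []
        for seed in range(5):
            c = synthetic.SimConfig(seed=seed, n_dars=1, dar_effect_log2=0.0,
                                    n_core_peaks=150)
            _, counts, _, _ = synthetic.make_peaks(c)
            cols = list(counts.columns)
            rng = np.random.default_rng(seed)
            rng.shuffle(cols)
            fps.append(len(rg.differential_regions(counts, cols[:4], cols[4:])))
        assert np.mean(fps) <= 0.1 * 150 * 0.2  # well under the FDR budget

    def test_zero_variance_region_p_one(self):
        counts = pd.DataFrame({"a1": [5, 100], "a2": [5, 100],
                               "b1": [5, 100], "b2": [5, 100]},
                              index=["chr1:0-10", "chr1:20-30"])
        dars = rg.differential_regions(counts, ["a1", "a2"], ["b1", "b2"],
                                       fdr_lt=1.1)
        flat = [d for d in dars if d.region.name == "chr1:0-10"]
        assert all(d.pvalue == 1.0 for d in flat)


class TestDarSummary:
    def _mk(self, vals, cats, comp="D3-M3"):
        dars = [rg.DARRecord(rg.GenomicInterval("chr1", i * 10, i * 10 + 5),
                             comp, v, 0.01, 0.01) for i, v in enumerate(vals)]
        anns = [rg.PeakAnnotation(d.region, c, "g", 0)
                for d, c in zip(dars, cats)]
        return dars, anns

    def test_all_negative_decreased_fraction_one(self):
        dars, anns = self._mk([-1, -2, -0.5], ["distal"] * 3)
        (s,) = rg.dar_summary(dars, anns)
        assert s.decreased_fraction == 1.0

    def test_single_gene_body_dar_proportions(self):
        dars, anns = self._mk([1.0], ["gene_body"])
        (s,) = rg.dar_summary(dars, anns)
        assert s.category_proportions == {"upstream": 0, "gene_body": 1.0,
                                          "downstream": 0, "distal": 0}

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(4)
        cats = rng.choice(rg.CATEGORIES, size=40)
        dars, anns = self._mk(rng.normal(size=40), cats)
        (s,) = rg.dar_summary(dars, anns)
        assert sum(s.category_proportions.values()) == pytest.approx(1.0)
        expect = {c: (cats == c).mean() for c in rg.CATEGORIES}
        assert s.category_proportions == pytest.approx(expect)
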