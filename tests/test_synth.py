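"""The synthetic evidence generator: structural expansion, counts, BAMs."""
import numpy as np
import pytest

import startyper as st
from startyper import pipeline, synth
from startyper.depth_cn import depth_from_count, normalize
from startyper.synth import SimulationError, SimulationSpec, expand_genotype


class TestExpandGenotype:
    def test_reference_diplotype(self, defs38):
        t = expand_genotype("*1/*1", defs38)
        assert t.cn_total == 4 and t.cn_spacer == 2
        assert t.n_full_d6 == 2 and t.n_d7 == 2
        assert not t.variant_copies

    def test_na12878_structure(self, defs38):
        t = expand_genotype("*3/*68+*4", defs38)
        assert t.cn_total == 5 and t.cn_spacer == 3
        assert t.segment_cn["exon1"] == 3
        assert all(t.segment_cn[f"exon{k}"] == 2 for k in range(2, 10))
        assert t.variant_copies["g.100C>T"] == 2

    def test_homozygous_deletion(self, defs38):
        t = expand_genotype("*5/*5", defs38)
        assert t.cn_total == 2 and t.n_full_d6 == 0
        assert all(v == 0 for v in t.segment_cn.values())

    def test_fusion_deletes_separate_cyp2d7(self, defs38):
        t = expand_genotype("*1/*13", defs38)
        assert t.cn_total == 3 and t.cn_spacer == 1 and t.n_d7 == 1

    def test_conversion_allele_retains_cyp2d7(self, defs38):
        t = expand_genotype("*1/*4.013+*4", defs38)
        assert t.cn_total == 5 and t.cn_spacer == 2

    def test_unknown_allele_rejected(self, defs38):
        with pytest.raises(SimulationError):
            expand_genotype("*999/*1", defs38)


class TestSimulateCounts:
    def test_same_seed_reproduces_bundle(self):
        a = st.simulate_counts(SimulationSpec(genotype="*1/*5", seed=7))
        b = st.simulate_counts(SimulationSpec(genotype="*1/*5", seed=7))
        assert a.d6d7_count == b.d6d7_count
        assert a.spacer_count == b.spacer_count
        assert a.site_support == b.site_support
        assert a.variant_counts == b.variant_counts

    def test_different_seed_differs(self):
        a = st.simulate_counts(SimulationSpec(genotype="*1/*5", seed=7))
        b = st.simulate_counts(SimulationSpec(genotype="*1/*5", seed=8))
        assert a.d6d7_count != b.d6d7_count

    def test_exact_mode_is_seed_free_expectation(self, model38):
        a = st.simulate_counts(SimulationSpec(genotype="*1/*5", seed=1,
                                              exact=True))
        b = st.simulate_counts(SimulationSpec(genotype="*1/*5", seed=2,
                                              exact=True))
        assert a.d6d7_count == b.d6d7_count
        value = normalize(depth_from_count(a.d6d7_count, a.read_length,
                                           model38.d6_length), a.baseline).value
        assert value == pytest.approx(3.0, abs=0.05)

    def test_deletion_depth_concentrates_near_three(self, model38):
        values = []
        for seed in range(20):
            b = st.simulate_counts(SimulationSpec(genotype="*1/*5", seed=seed))
            values.append(normalize(depth_from_count(
                b.d6d7_count, b.read_length, model38.d6_length),
                b.baseline).value)
        assert abs(float(np.median(values)) - 3.0) < 0.2

    def test_no_sv_site_support_is_balanced(self):
        """Binomial p=1/2 at every site for a 2+2 sample."""
        b = st.simulate_counts(SimulationSpec(genotype="*1/*1", seed=3))
        ratios = [s.n_d6 / (s.n_d6 + s.n_d7) for s in b.site_support]
        in_band = sum(0.35 <= r <= 0.65 for r in ratios)
        assert in_band >= 0.9 * len(ratios)

    def test_homozygous_deletion_has_no_d6_reads(self):
        b = st.simulate_counts(SimulationSpec(genotype="*5/*5", seed=3,
                                              error_rate=0.0))
        assert all(s.n_d6 == 0 for s in b.site_support)

    def test_counts_tsv_round_trip(self, tmp_path):
        bundle = st.simulate_counts(SimulationSpec(genotype="*3/*68+*4",
                                                   seed=11))
        synth.write_counts(bundle, str(tmp_path))
        reloaded = synth.load_counts(str(tmp_path))
        r1 = pipeline.call_from_counts(bundle)
        r2 = pipeline.call_from_counts(reloaded)
        assert r1.genotype == r2.genotype == "*3/*68+*4"


@pytest.fixture(scope="module")
def bam_run(tmp_path_factory):
    def _run(genotype, seed):
        d = str(tmp_path_factory.mktemp("bam"))
        out = synth.simulate_bam(SimulationSpec(genotype=genotype,
                                                seed=seed), d)
        result = pipeline.call_from_bam(
            out["bam"], out["model"], out["baseline_regions"],
            panel=out["panel"], defs=out["defs"])
        return out, result
    return _run


class TestSimulateBam:
    def test_reference_round_trip(self, bam_run):
        _out, r = bam_run("*1/*1", 21)
        assert r.genotype == "*1/*1"

    def test_hybrid_sample_round_trip(self, bam_run):
        _out, r = bam_run("*3/*68+*4", 22)
        assert r.genotype is not None
        assert st.genotype_match(r.genotype, "*3/*68+*4")
        assert r.total_cn.cn_total == 5 and r.total_cn.cn_spacer == 3

    def test_deletion_bam_total_cn(self, bam_run):
        _out, r = bam_run("*1/*5", 23)
        assert r.total_cn.cn_total == 3
        assert r.genotype == "*1/*5"

    def test_mapq0_reads_present_in_homology_regions(self, bam_run):
        import pysam
        out, _r = bam_run("*1/*1", 24)
        model = out["model"]
        lo, hi = model.homology_regions[0]
        with pysam.AlignmentFile(out["bam"]) as aln:
            mapqs = [read.mapping_quality
                     for read in aln.fetch(model.chrom, lo, hi)]
        assert 0 in mapqs
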