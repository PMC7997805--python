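"""Depth normalization, GC correction and the Gaussian-mixture CN caller."""
import math

import numpy as np
import pytest

import startyper as st
from startyper import depth_cn
from startyper.depth_cn import (GenomeBaseline, NormalizedDepth,
                                call_integer_cn, cn_posteriors, gc_correct,
                                normalize)


@pytest.fixture(scope="module")
def flat_baseline():
    rng = np.random.default_rng(7)
    return GenomeBaseline(depths=np.full(200, 30.0),
                          gc=rng.uniform(0.3, 0.7, 200))


class TestNormalize:
    def test_diploid_depth_scores_two(self, flat_baseline):
        assert normalize(30.0, flat_baseline).value == pytest.approx(2.0)

    def test_scale_is_linear_in_depth(self, flat_baseline):
        assert normalize(60.0, flat_baseline).value == pytest.approx(4.0)

    def test_zero_baseline_is_fatal(self):
        bad = GenomeBaseline(depths=np.zeros(10), gc=np.full(10, 0.5))
        with pytest.raises(depth_cn.DepthError):
            normalize(30.0, bad)


class TestGCCorrect:
    def test_identity_when_bin_matches_global_median(self, flat_baseline):
        corrected, flags = gc_correct(30.0, 0.5, flat_baseline)
        assert corrected == pytest.approx(30.0)
        assert not flags

    def test_factor_clamped_with_flag(self):
        # one heavily suppressed GC bin -> raw factor 3, clamped to 2
        gc = np.array([0.30] * 20 + [0.60] * 80)
        depths = np.array([10.0] * 20 + [30.0] * 80)
        base = GenomeBaseline(depths=depths, gc=gc)
        corrected, flags = gc_correct(10.0, 0.30, base)
        assert "gc_factor_clamped" in flags
        assert corrected == pytest.approx(10.0 * 2.0)

    def test_empty_bin_falls_back_with_flag(self, flat_baseline):
        corrected, flags = gc_correct(30.0, 0.26, GenomeBaseline(
            depths=np.full(10, 30.0), gc=np.full(10, 0.6)))
        assert corrected == 30.0 and "gc_bin_empty" in flags

    def test_simulated_bias_recovered_within_five_percent(self):
        # depth suppressed x0.8 in the gene's GC bin; correction undoes it
        bias = {0.55: 0.8}
        bundle = st.simulate_counts(st.SimulationSpec(
            genotype="*1/*1", seed=5, gc_bias=bias, exact=True))
        raw = depth_cn.depth_from_count(bundle.d6d7_count, bundle.read_length,
                                        st.load_region_model().d6_length)
        corrected, _ = gc_correct(raw, bundle.gc_d6d7, bundle.baseline)
        value = normalize(corrected, bundle.baseline).value
        assert value == pytest.approx(4.0, rel=0.05)


class TestIntegerCNCall:
    @pytest.mark.parametrize("value,expected", [
        (5.02, 5), (0.0, 0), (2.04, 2), (7.1, 7),
    ])
    def test_calls_nearest_integer(self, value, expected):
        cn, post = call_integer_cn(value)
        assert cn == expected and post > 0.95

    def test_midpoint_no_calls(self):
        cn, post = call_integer_cn(4.5)
        assert cn is None and post == pytest.approx(0.5, abs=0.01)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(1)
        for value in rng.uniform(0, 10, 200):
            assert cn_posteriors(value).sum() == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_depth(self):
        grid = np.linspace(0, 10, 400)
        calls = [call_integer_cn(v)[0] for v in grid]
        called = [(v, c) for v, c in zip(grid, calls) if c is not None]
        for (v1, c1), (v2, c2) in zip(called, called[1:]):
            assert c1 <= c2

    def test_matches_independent_gaussian_posterior(self):
        """Dense-grid oracle: hand-computed normal posteriors, no scipy."""
        rng = np.random.default_rng(3)
        for value in rng.uniform(0, 10, 300):
            weights = [math.exp(-((value - k) ** 2) / (2 * 0.25 ** 2))
                       for k in range(11)]
            total = sum(weights)
            oracle = max(range(11), key=lambda k: weights[k])
            cn, post = call_integer_cn(float(value))
            assert post == pytest.approx(weights[oracle] / total, abs=1e-9)
            if weights[oracle] / total >= 0.95:
                assert cn == oracle
            else:
                assert cn is None


@pytest.fixture(scope="module")
def micro_bam(tmp_path_factory):
    import pysam
    path = str(tmp_path_factory.mktemp("bam") / "micro.bam")
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "ctg", "LN": 10000}]}
    # (pos0, mapq, flag): MAPQ0 counts; dup/secondary/outside do not
    reads = [(100, 0, 0), (150, 60, 0), (200, 60, 1024),
             (250, 60, 256), (5000, 60, 0)]
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (pos, mapq, flag) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigartuples = [(0, 100)]
            a.query_sequence = "A" * 100
            a.flag = flag
            bam.write(a)
    pysam.index(path)
    return path


class TestReadCounting:
    def test_counts_primary_reads_including_mapq0(self, micro_bam):
        import pysam
        with pysam.AlignmentFile(micro_bam) as aln:
            assert depth_cn.count_region_reads(aln, "ctg", 1, 1000) == 2

    def test_start_in_region_rule_and_empty_region(self, micro_bam):
        import pysam
        with pysam.AlignmentFile(micro_bam) as aln:
            assert depth_cn.count_region_reads(aln, "ctg", 140, 160) == 1
            assert depth_cn.count_region_reads(aln, "ctg", 900, 899) == 0


class TestCohortRecovery:
    def test_histogram_modes_at_every_simulated_cn(self):
        """Simulated cohort reproduces depth peaks at each true total CN."""
        by_cn = {2: "*5/*5", 3: "*1/*5", 4: "*1/*1", 5: "*1x2/*1",
                 6: "*1x2/*1x2", 7: "*1x3/*1x2"}
        model = st.load_region_model()
        for cn, genotype in by_cn.items():
            values = []
            for seed in range(50):
                b = st.simulate_counts(st.SimulationSpec(
                    genotype=genotype, seed=seed * 13 + cn))
                raw = depth_cn.depth_from_count(
                    b.d6d7_count, b.read_length, model.d6_length)
                values.append(normalize(raw, b.baseline).value)
            assert round(float(np.median(values))) == cn
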