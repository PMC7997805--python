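"""Per-site paralog apportioning, segment consensus and SV typing."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import startyper as st
from startyper.paralog_cn import (SVCall, SegmentProfile, SiteSupport,
                                  binomial_cn_posteriors, call_site_cn,
                                  consensus_segments, detect_sv,
                                  enumerate_sv_partitions)
from startyper.resources import SEGMENT_ORDER


def brute_force_loglik(n_d6: int, n: int, cn_total: int) -> list:
    """Independent likelihood enumeration (pure math, no scipy)."""
    out = []
    for i in range(cn_total + 1):
        p = min(max(i / cn_total, 0.01), 0.99)
        out.append(n_d6 * math.log(p) + (n - n_d6) * math.log(1 - p))
    return out


class TestCallSiteCN:
    @pytest.mark.parametrize("cn_total,n6,n7,expected", [
        (5, 20, 30, 2),     # p=0.4 maximizes the binomial likelihood
        (4, 50, 50, 2),     # symmetric split
        (3, 150, 0, 3),     # all-D6 boundary under the error clamp
    ])
    def test_worked_examples(self, cn_total, n6, n7, expected):
        sc = call_site_cn(SiteSupport(0, n6, n7), cn_total)
        assert sc.called_cn == expected

    def test_zero_total_cn_is_trivial(self):
        sc = call_site_cn(SiteSupport(0, 0, 0), 0)
        assert sc.called_cn == 0 and sc.posterior == 1.0

    def test_low_depth_is_uninformative(self):
        assert call_site_cn(SiteSupport(0, 4, 3), 4).called_cn is None

    def test_raw_cn_is_count_ratio_times_total(self):
        sc = call_site_cn(SiteSupport(0, 30, 70), 5)
        assert sc.raw_cn == pytest.approx(1.5)

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(n6=hst.integers(0, 200), n7=hst.integers(0, 200),
           cn=hst.integers(1, 8))
    def test_matches_brute_force_enumeration(self, n6, n7, cn):
        """The chosen CN attains the exhaustively enumerated maximum
        likelihood (ties between symmetric splits are both maximal)."""
        sc = call_site_cn(SiteSupport(0, n6, n7), cn)
        if n6 + n7 >= 10:
            lls = brute_force_loglik(n6, n6 + n7, cn)
            assert lls[sc.ml_cn] == pytest.approx(max(lls), abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(n6=hst.integers(0, 150), n7=hst.integers(0, 150),
           cn=hst.integers(1, 8))
    def test_paralog_relabel_symmetry(self, n6, n7, cn):
        """Swapping the D6/D7 labels flips the call to cn_total - cn."""
        a = call_site_cn(SiteSupport(0, n6, n7), cn)
        b = call_site_cn(SiteSupport(0, n7, n6), cn)
        if a.ml_cn is not None and n6 != n7:
            assert b.ml_cn == cn - a.ml_cn

    def test_posteriors_normalized(self):
        post = binomial_cn_posteriors(20, 50, 6)
        assert post.sum() == pytest.approx(1.0, abs=1e-9)


def _uniform_supports(panel, cn_d6, cn_total, depth_per_copy=15):
    out = []
    for site in panel:
        n = cn_total * depth_per_copy
        n6 = round(n * cn_d6 / cn_total)
        out.append(SiteSupport(site.site_id, n6, n - n6))
    return out


class TestConsensus:
    def test_unanimous_segment(self, panel38):
        supports = _uniform_supports(panel38, 2, 4)
        cns = [call_site_cn(s, 4) for s in supports]
        prof = consensus_segments(cns, panel38, supports, 4)
        assert all(prof.cn[seg] == 2 for seg in SEGMENT_ORDER)
        assert all(prof.agreement[seg] == 1.0 for seg in SEGMENT_ORDER)

    def test_adjacent_5050_split_no_calls(self, panel38):
        """Sites split half-and-half between two adjacent CNs leave the
        segment uncalled (pooled evidence sits exactly between integers)."""
        supports, per_seg = [], {}
        for site in panel38:
            i = per_seg.get(site.segment, 0)
            per_seg[site.segment] = i + 1
            n6 = 30 if i % 2 == 0 else 45   # CN2-like vs CN3-like of 5
            supports.append(SiteSupport(site.site_id, n6, 75 - n6))
        cns = [call_site_cn(s, 5) for s in supports]
        prof = consensus_segments(cns, panel38, supports, 5)
        even = [seg for seg, n in per_seg.items() if n % 2 == 0]
        assert even
        assert all(prof.cn[seg] is None for seg in even)
        # vote-only mode (no pooled counts) no-calls every split segment
        prof2 = consensus_segments(cns, panel38)
        assert all(prof2.cn[seg] is None for seg in SEGMENT_ORDER)

    def test_too_few_informative_sites_no_call(self, panel38):
        supports = [SiteSupport(s.site_id, 2, 1) for s in panel38]  # depth < 10
        cns = [call_site_cn(s, 4) for s in supports]
        prof = consensus_segments(cns, panel38, supports, 4)
        assert all(prof.cn[seg] is None for seg in SEGMENT_ORDER)

    def test_na12878_exon1_step(self, na12878):
        segs = na12878.segments.cn
        assert segs["exon1"] == 3
        assert all(segs[f"exon{k}"] == 2 for k in range(2, 10))


def _profile(mapping):
    cn = {seg: mapping.get(seg, mapping.get("default")) for seg in SEGMENT_ORDER}
    return SegmentProfile(cn=cn, n_sites={s: 10 for s in SEGMENT_ORDER},
                          agreement={s: 1.0 for s in SEGMENT_ORDER})


class TestDetectSV:
    def test_reference_configuration(self):
        sv = detect_sv(_profile({"default": 2}), 4, 2)
        assert (sv.cn_full_d6, sv.cn_full_d7) == (2, 2)
        assert not sv.d6_d7_hybrids and not sv.d7_d6_hybrids

    def test_deletion_carrier(self):
        sv = detect_sv(_profile({"default": 1}), 3, 2)
        assert sv.cn_full_d6 == 1 and sv.cn_full_d7 == 2 and not sv.no_call

    def test_exon1_step_yields_d6_d7_hybrid(self):
        prof = _profile({"default": 2, "exon1": 3, "5p_flank": 3})
        sv = detect_sv(prof, 5, 3)
        assert sv.cn_full_d6 == 2 and sv.cn_full_d7 == 2
        assert sv.d6_d7_hybrids == (1,)

    def test_step_down_yields_d7_d6_hybrid(self):
        prof = _profile({"default": 2, "exon1": 1, "5p_flank": 1})
        sv = detect_sv(prof, 4, 2)
        assert sv.d7_d6_hybrids == (2,) and sv.cn_full_d6 == 1

    def test_spacer_conflict_no_calls(self):
        # uniform CN 2 but spacer arithmetic demands 3 CYP2D6-like 3' ends
        sv = detect_sv(_profile({"default": 2}), 5, 2)
        assert sv.no_call and "partition" in sv.diagnostic

    def test_uncalled_segment_no_calls(self):
        prof = _profile({"default": 2})
        prof.cn["exon5"] = None
        sv = detect_sv(prof, 4, 2)
        assert sv.no_call

    @pytest.mark.parametrize("genotype", [
        "*1/*1", "*1/*5", "*1x2/*2", "*1/*13", "*36+*10/*1", "*3/*68+*4",
        "*13+*2/*1", "*13/*68", "*36+*36+*10/*1", "*1/*4.013+*4",
    ])
    def test_partition_conservation(self, genotype, call_counts):
        """Every emitted SVCall partitions CN(total) exactly."""
        r = call_counts(genotype, seed=9)
        sv = r.sv
        assert not sv.no_call
        assert sv.n_units == sv.cn_total
        assert sv.cn_d6_3prime == sv.cn_total - sv.cn_spacer

    def test_all_enumerated_partitions_satisfy_invariant(self):
        prof = _profile({"default": 1})
        for sv in enumerate_sv_partitions(prof, 3, 2):
            assert sv.n_units == 3
            assert sv.cn_full_d7 + len(sv.d6_d7_hybrids) == 2
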