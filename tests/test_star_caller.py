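"""Diplotype resolution, ranking, phenotype translation, genotype matching."""
import pytest

from startyper.nomenclature import genotype_match
from startyper.paralog_cn import SVCall
from startyper.star_caller import (DiplotypeCall, enumerate_haplotypes,
                                   resolve_diplotype, translate_phenotype)


def _sv(full_d6, full_d7, d6d7=(), d7d6=(), cn_total=None, cn_spacer=None):
    cn_total = cn_total if cn_total is not None else \
        full_d6 + full_d7 + len(d6d7) + len(d7d6)
    cn_spacer = cn_spacer if cn_spacer is not None else full_d7 + len(d6d7)
    return SVCall(full_d6, full_d7, tuple(d6d7), tuple(d7d6),
                  cn_total, cn_spacer)


def _cns(defs, present):
    cns = {v: 0 for v in defs.variants}
    cns.update(present)
    return cns


class TestEnumerate:
    def test_variant_free_sample_yields_star1(self, defs38):
        cands = enumerate_haplotypes(_sv(2, 2), _cns(defs38, {}), defs38)
        names = {c.alleles for c in cands}
        assert ("*1",) in names and () in names   # () is the *5 chromosome

    def test_hybrid_plus_star4_variants_allows_tandem(self, defs38):
        cns = _cns(defs38, {"g.100C>T": 2, "g.1847G>A": 1, "g.4181G>C": 1})
        cands = enumerate_haplotypes(_sv(1, 2, d6d7=(1,)), cns, defs38)
        assert any(set(c.alleles) == {"*4", "*68"} for c in cands)

    def test_respects_sv_availability(self, defs38):
        cands = enumerate_haplotypes(_sv(2, 2), _cns(defs38, {}), defs38)
        assert not any("*68" in c.alleles for c in cands)


class TestResolve:
    def test_reference_diplotype(self, defs38):
        call = resolve_diplotype(_sv(2, 2), _cns(defs38, {}), defs38)
        assert call.genotype == "*1/*1" and call.filter == "PASS"
        assert "*1x2/*5" in call.alternatives

    def test_deletion_carrier(self, defs38):
        call = resolve_diplotype(_sv(1, 2), _cns(defs38, {}), defs38)
        assert call.genotype == "*1/*5" and call.filter == "PASS"

    def test_na12878_worked_example(self, defs38):
        cns = _cns(defs38, {"g.100C>T": 2, "g.1847G>A": 1,
                            "g.2549delA": 1, "g.4181G>C": 1})
        call = resolve_diplotype(_sv(2, 2, d6d7=(1,)), cns, defs38)
        assert call.genotype == "*3/*68+*4" and call.filter == "PASS"

    def test_unexplained_variant_residue_no_calls(self, defs38):
        call = resolve_diplotype(_sv(2, 2), _cns(defs38, {"g.1847G>A": 2}),
                                 defs38)
        assert call.filter == "no_call" and call.genotype is None
        assert "g.1847G>A" in call.diagnostic

    def test_sv_no_call_propagates(self, defs38):
        sv = SVCall(0, 0, (), (), 4, 2, no_call=True, diagnostic="x")
        assert resolve_diplotype(sv, _cns(defs38, {}), defs38).filter == "no_call"

    def test_ambiguous_phasing_flagged_with_alternatives(self, defs38):
        # three full genes carrying *2 and *4 defining variants: the extra
        # copy cannot be phased -> tied arrangements differ only lexically
        cns = _cns(defs38, {"g.100C>T": 1, "g.1847G>A": 1,
                            "g.2851C>T": 1, "g.4181G>C": 2})
        call = resolve_diplotype(_sv(3, 2), cns, defs38)
        assert call.filter == "more_than_one_possible_genotype"
        assert call.alternatives

    def test_exact_cover_soundness(self, defs38):
        """Re-deriving implied variant copies from the winning genotype
        reproduces the called CNs exactly."""
        cns = _cns(defs38, {"g.100C>T": 2, "g.1847G>A": 1,
                            "g.2549delA": 1, "g.4181G>C": 1})
        call = resolve_diplotype(_sv(2, 2, d6d7=(1,)), cns, defs38)
        implied = {}
        for hap in call.haplotypes:
            for name in hap:
                for v in defs38[name].defining_variants:
                    implied[v] = implied.get(v, 0) + 1
        assert implied == {v: c for v, c in cns.items() if c}

    def test_deterministic(self, defs38):
        cns = _cns(defs38, {"g.2851C>T": 1, "g.4181G>C": 1})
        calls = [resolve_diplotype(_sv(2, 2), cns, defs38) for _ in range(3)]
        assert len({c.genotype for c in calls}) == 1
        assert len({c.alternatives for c in calls}) == 1


class TestPhenotype:
    def _call(self, h1, h2):
        return DiplotypeCall("x", (h1, h2), "PASS")

    def test_two_normal_alleles(self, defs38):
        p = translate_phenotype(self._call(("*1",), ("*1",)), defs38)
        assert p.activity_score_sum == 2.0 and p.category == "normal"

    def test_double_deletion_is_poor(self, defs38):
        p = translate_phenotype(self._call((), ()), defs38)
        assert p.activity_score_sum == 0.0 and p.category == "poor"

    def test_duplication_counted_per_copy(self, defs38):
        p = translate_phenotype(self._call(("*1", "*1"), ("*1",)), defs38)
        assert p.activity_score_sum == 3.0 and p.category == "ultrarapid"

    def test_intermediate_band(self, defs38):
        p = translate_phenotype(self._call(("*10",), ("*4",)), defs38)
        assert p.activity_score_sum == pytest.approx(0.25)
        assert p.category == "intermediate"

    def test_unknown_function_is_indeterminate(self, defs38):
        p = translate_phenotype(self._call(("*22",), ("*1",)), defs38)
        assert p.activity_score_sum is None and p.category == "indeterminate"

    def test_no_call_is_indeterminate(self, defs38):
        p = translate_phenotype(DiplotypeCall(None, None, "no_call"), defs38)
        assert p.category == "indeterminate"


class TestGenotypeMatch:
    @pytest.mark.parametrize("a,b,expected", [
        ("*1+*36/*36+*10", "*1/*36+*36+*10", True),   # phasing ignored
        ("*1/*2", "*1/*4", False),
        ("*2x2/*1", "*2/*1+*2", True),                # same multiset
        ("*3/*68+*4", "*68+*4/*3", True),
        ("*1/*5", "*1/*1", False),
    ])
    def test_multiset_rule(self, a, b, expected):
        assert genotype_match(a, b) is expected

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            genotype_match("*1/bogus", "*1/*1")
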