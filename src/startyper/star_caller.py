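"""Resolve structural and small-variant calls into a star-allele diplotype.

The resolver performs an exact-cover search: it assigns a star allele to
every structural gene unit of the SVCall (full CYP2D6 copies and fusion
genes) such that the summed defining-variant multiset of the assigned
alleles equals the called variant copy numbers EXACTLY, then partitions the
units onto two chromosomes.  *1 absorbs variant-free full copies; an empty
chromosome is the *5 deletion.  Covers are collected across every SV
partition the depth evidence admits, so structures that are
depth-equivalent (e.g. biallelic *13/*68) are arbitrated by the variant
evidence.

Ranking among exact covers: (1) avoid deletion-bearing phasings,
(2) chromosomes arranged as known tandem conventions (*68+*4, *36+*10, ...)
preferred, (3) fewer distinct alleles, (4) likelihood of indecisively
genotyped variants, (5) fewer fusions, then lexicographic.  Ambiguity
surviving all evidence-bearing criteria is reported via the
more_than_one_possible_genotype filter with alternatives listed.
"""
from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

from .nomenclature import (allele_sort_key, format_genotype, format_haplotype,
                           genotype_match)  # noqa: F401  (re-exported)
from .paralog_cn import SVCall
from .resources import AlleleTable, StarAlleleDefinition, StructuralUnit

MAX_UNITS_PER_CHROMOSOME = 4


@dataclass(frozen=True)
class HaplotypeCandidate:
    alleles: tuple[str, ...]

    def __str__(self):
        return "+".join(self.alleles) if self.alleles else "*5"


@dataclass(frozen=True)
class DiplotypeCall:
    genotype: str | None
    haplotypes: tuple[tuple[str, ...], tuple[str, ...]] | None
    filter: str                       # PASS | more_than_one_possible_genotype | no_call
    alternatives: tuple[str, ...] = ()
    diagnostic: str = ""
    sv_used: SVCall | None = None

    @property
    def allele_multiset(self) -> Counter:
        if self.haplotypes is None:
            return Counter()
        c = Counter(self.haplotypes[0]) + Counter(self.haplotypes[1])
        if not self.haplotypes[0]:
            c["*5"] += 1
        if not self.haplotypes[1]:
            c["*5"] += 1
        return c


@dataclass(frozen=True)
class PhenotypeCall:
    activity_score_sum: float | None
    category: str                     # poor|intermediate|normal|ultrarapid|indeterminate


# --------------------------------------------------------------------------
# candidate enumeration / exact cover
# --------------------------------------------------------------------------

def _slot_key(structure: StructuralUnit) -> tuple:
    if structure.kind == "full_d6":
        return ("full_d6",)
    if structure.kind == "d6_d7":
        return ("d6_d7", structure.through_exon)
    return ("d7_d6", structure.from_exon)


def _slots_for(sv: SVCall) -> list[tuple]:
    slots = [("full_d6",)] * sv.cn_full_d6
    slots += [("d6_d7", k) for k in sv.d6_d7_hybrids]
    slots += [("d7_d6", k) for k in sv.d7_d6_hybrids]
    return slots


def _callable_alleles(defs: AlleleTable) -> list[StarAlleleDefinition]:
    out = [a for a in defs.alleles.values() if not a.is_deletion]
    out.sort(key=lambda a: allele_sort_key(a.name))
    return out


def _wild_variants(variant_cns: dict[str, int | None]) -> set[str]:
    """Variants whose CN no-called: indecisive evidence, excluded from the
    exactness equality rather than vetoing alleles that carry them."""
    return {v for v, c in variant_cns.items() if c is None}


def _unit_covers(sv: SVCall, variant_cns: dict[str, int | None],
                 defs: AlleleTable, limit: int = 200) -> list[Counter]:
    """Allele multisets over the SV's gene units whose summed defining
    variants equal the called variant CNs exactly."""
    required = Counter({v: c for v, c in variant_cns.items()
                        if c is not None and c > 0})
    wild = _wild_variants(variant_cns)
    slots = _slots_for(sv)
    by_type: dict[tuple, list[StarAlleleDefinition]] = {}
    for a in _callable_alleles(defs):
        by_type.setdefault(_slot_key(a.structure), []).append(a)
    # group identical slots so assignments are multiset-unique
    slot_counts = Counter(slots)
    slot_types = sorted(slot_counts)
    results: list[Counter] = []

    def rec(ti: int, remaining: Counter, acc: Counter):
        if len(results) >= limit:
            return
        if ti == len(slot_types):
            if not +remaining:
                results.append(acc.copy())
            return
        stype, count = slot_types[ti], slot_counts[slot_types[ti]]
        cands = by_type.get(stype, [])
        # choose a multiset of `count` alleles from cands (non-decreasing index)
        def choose(ci: int, left: int, rem: Counter):
            if len(results) >= limit:
                return
            if left == 0:
                rec(ti + 1, rem, acc)
                return
            if ci == len(cands):
                return
            a = cands[ci]
            need = Counter(v for v in a.defining_variants if v not in wild)
            # option: use allele a (possibly again)
            if all(rem.get(v, 0) >= n for v, n in need.items()):
                acc[a.name] += 1
                choose(ci, left - 1, rem - need)
                acc[a.name] -= 1
            choose(ci + 1, left, rem)
        choose(0, count, remaining)

    rec(0, required, Counter())
    return results


def enumerate_haplotypes(sv: SVCall, variant_cns: dict[str, int | None],
                         defs: AlleleTable,
                         max_units: int = MAX_UNITS_PER_CHROMOSOME
                         ) -> list[HaplotypeCandidate]:
    """All single-chromosome arrangements whose implied variants are a
    sub-multiset of the calls and whose SV units exist in the SVCall."""
    avail = Counter(_slots_for(sv))
    called = Counter({v: c for v, c in variant_cns.items()
                      if c is not None and c > 0})
    wild = _wild_variants(variant_cns)
    cands = _callable_alleles(defs)
    out: list[HaplotypeCandidate] = [HaplotypeCandidate(())]  # *5

    def rec(ci: int, units: list[str], used_slots: Counter, used_vars: Counter):
        if len(units) >= max_units or ci == len(cands):
            return
        a = cands[ci]
        sk = _slot_key(a.structure)
        need = Counter(v for v in a.defining_variants if v not in wild)
        if used_slots[sk] < avail.get(sk, 0) and \
                all(called.get(v, 0) >= used_vars.get(v, 0) + n
                    for v, n in need.items()):
            units.append(a.name)
            used_slots[sk] += 1
            for v, n in need.items():
                used_vars[v] += n
            out.append(HaplotypeCandidate(tuple(units)))
            rec(ci, units, used_slots, used_vars)
            units.pop()
            used_slots[sk] -= 1
            for v, n in need.items():
                used_vars[v] -= n
        rec(ci + 1, units, used_slots, used_vars)

    rec(0, [], Counter(), Counter())
    uniq = {c.alleles: c for c in out}
    return sorted(uniq.values(), key=lambda c: (len(c.alleles), c.alleles))


# --------------------------------------------------------------------------
# diplotype resolution
# --------------------------------------------------------------------------

def _expand_cover(cover: Counter, defs: AlleleTable) -> list[str]:
    units: list[str] = []
    for name in sorted(cover, key=allele_sort_key):
        units.extend([name] * cover[name])
    return units


def _chromosome_splits(units: list[str], defs: AlleleTable, full_d7: int):
    """Unordered splits of the unit list into two chromosomes, filtered by
    the separate-CYP2D7 count implied by fusion alleles."""
    n = len(units)
    seen = set()
    for r in range(0, n // 2 + 1):
        for idx in itertools.combinations(range(n), r):
            h1 = tuple(sorted((units[i] for i in idx), key=allele_sort_key))
            h2 = tuple(sorted((units[i] for i in range(n) if i not in idx),
                              key=allele_sort_key))
            if len(h1) > MAX_UNITS_PER_CHROMOSOME or \
                    len(h2) > MAX_UNITS_PER_CHROMOSOME:
                continue
            key = tuple(sorted((h1, h2)))
            if key in seen:
                continue
            seen.add(key)
            if _implied_d7(h1, defs) + _implied_d7(h2, defs) != full_d7:
                continue
            yield h1, h2


def _implied_d7(hap: tuple[str, ...], defs: AlleleTable) -> int:
    """Separate CYP2D7 copies on a chromosome: one, unless a deletion-fusion
    allele (*13 class) removed it."""
    for name in hap:
        st = defs[name].structure
        if st is not None and st.kind == "d7_d6" and st.fused:
            return 0
    return 1


def _tandem_score(h1, h2, defs: AlleleTable) -> int:
    """+1 per chromosome arranged as a known tandem convention, -1 per
    unconventional multi-unit chromosome; homogeneous duplications neutral."""
    score = 0
    for hap in (h1, h2):
        if len(hap) < 2 or len(set(hap)) == 1:
            continue
        if any(Counter(p) == Counter(hap) for p in defs.tandems):
            score += 1
        else:
            score -= 1
    return score


def _rank_tuple(pair, defs: AlleleTable) -> tuple:
    h1, h2 = pair
    has_empty = int(len(h1) == 0 or len(h2) == 0)
    return (has_empty, -_tandem_score(h1, h2, defs), len(set(h1) | set(h2)))


def resolve_diplotype(sv: SVCall, variant_cns: dict[str, int | None],
                      defs: AlleleTable,
                      variant_evidence: dict | None = None
                      ) -> DiplotypeCall:
    """Exact-cover search over unordered haplotype pairs (see module doc).

    No-called variants do not veto alleles that carry them; instead every
    exact cover (over the confidently called variants) is scored by the
    binomial log-likelihood of the no-called variants' observed read
    counts under the copy numbers the cover implies, entering the ranking
    after the tandem-convention and parsimony criteria
    (``variant_evidence`` maps g_label -> (n_alt, n_ref, site_total_cn)).
    """
    if sv.no_call:
        return DiplotypeCall(None, None, "no_call",
                             diagnostic=f"SV no-call: {sv.diagnostic}")
    wild = _wild_variants(variant_cns)
    pairs = []      # ((h1, h2), wild loglik, n hybrids, partition)
    for partition in (sv, *sv.alternatives):
        n_hyb = len(partition.d6_d7_hybrids) + len(partition.d7_d6_hybrids)
        for cover in _unit_covers(partition, variant_cns, defs):
            ll = _wild_loglik(cover, wild, variant_evidence, defs)
            units = _expand_cover(cover, defs)
            for h1, h2 in _chromosome_splits(units, defs, partition.cn_full_d7):
                pairs.append(((h1, h2), ll, n_hyb, partition))
    if pairs:
        # drop covers decisively contradicted by the no-called variants'
        # read evidence (likelihood ratio > e^10 against)
        best_ll = max(ll for _p, ll, _n, _sv in pairs)
        pairs = [it for it in pairs if it[1] >= best_ll - 10.0]

        def key(item):
            (h1, h2), ll, n_hyb, _part = item
            return (*_rank_tuple((h1, h2), defs), -ll, n_hyb,
                    _hap_pair_key(h1, h2))

        ranked = sorted(pairs, key=key)
        genotypes = []
        for (h1, h2), *_rest in ranked:
            g = format_genotype(h1, h2, defs.tandems)
            if g not in genotypes:
                genotypes.append(g)
        top = ranked[0][0]
        top_g = format_genotype(top[0], top[1], defs.tandems)
        alts = tuple(g for g in genotypes if g != top_g)[:8]
        if len(genotypes) == 1:
            status = "PASS"
        else:
            second = next(item for item in ranked
                          if format_genotype(item[0][0], item[0][1],
                                             defs.tandems) != top_g)
            strictly_better = key(ranked[0])[:-1] < key(second)[:-1]
            status = "PASS" if strictly_better else "more_than_one_possible_genotype"
        return DiplotypeCall(genotype=top_g, haplotypes=(top[0], top[1]),
                             filter=status, alternatives=alts,
                             sv_used=ranked[0][3])
    unexplained = {v: c for v, c in variant_cns.items()
                   if c is not None and c > 0}
    return DiplotypeCall(None, None, "no_call",
                         diagnostic="no haplotype pair reproduces the evidence "
                                    f"exactly; called variants: {unexplained}, "
                                    f"sv: {sv}")


def _hap_pair_key(h1, h2):
    from .nomenclature import allele_sort_key as k
    return tuple(sorted(([k(u) for u in h1], [k(u) for u in h2])))


def _wild_loglik(cover: Counter, wild: set,
                 variant_evidence: dict | None, defs: AlleleTable) -> float:
    """Binomial log-likelihood of no-called variants' counts given the
    copies implied by an allele cover (0.0 when no evidence is supplied)."""
    if not wild or not variant_evidence:
        return 0.0
    from scipy.stats import binom as _binom
    total = 0.0
    implied: Counter = Counter()
    for name, count in cover.items():
        for v in defs[name].defining_variants:
            if v in wild:
                implied[v] += count
    for v in wild:
        ev = variant_evidence.get(v)
        if ev is None:
            continue
        n_alt, n_ref, n_copies = ev
        n = n_alt + n_ref
        if not n_copies or n < 1:
            continue
        i = min(implied[v], n_copies)
        p = min(max(i / n_copies, 0.01), 0.99)
        total += float(_binom.logpmf(n_alt, n, p))
    return total


# --------------------------------------------------------------------------
# phenotype translation
# --------------------------------------------------------------------------

def translate_phenotype(call: DiplotypeCall, defs: AlleleTable) -> PhenotypeCall:
    """CPIC-style translation: sum per-copy activity scores over both
    chromosomes, then bin.  Unknown-function alleles (or a no-call)
    propagate an indeterminate phenotype."""
    if call.haplotypes is None:
        return PhenotypeCall(None, "indeterminate")
    total = 0.0
    for hap in call.haplotypes:
        if not hap:                      # *5 deletion: score 0
            continue
        for name in hap:
            score = defs[name].activity_score
            if score is None:
                return PhenotypeCall(None, "indeterminate")
            total += score
    if total == 0.0:
        return PhenotypeCall(0.0, "poor")
    if total < 1.25:
        return PhenotypeCall(total, "intermediate")
    if total <= 2.25:
        return PhenotypeCall(total, "normal")
    return PhenotypeCall(total, "ultrarapid")
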