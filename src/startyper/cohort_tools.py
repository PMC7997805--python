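"""Cohort-level utilities: trio consistency, frequency tables, concordance."""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .nomenclature import (allele_multiset, format_genotype,
                           format_haplotype, genotype_match, parse_genotype)
from .star_caller import MAX_UNITS_PER_CHROMOSOME

#: alleles whose presence marks an SV stratum
_HYBRID_ALLELES = {"*13", "*36", "*68", "*83", "*4.013"}

_TANDEMS: tuple | None = None


def _tandem_conventions() -> tuple:
    """Conventional tandem arrangements from the packaged definitions."""
    global _TANDEMS
    if _TANDEMS is None:
        from .resources import load_allele_definitions
        _TANDEMS = load_allele_definitions().tandems
    return _TANDEMS


@dataclass(frozen=True)
class TrioResult:
    status: str                       # consistent | resolvable_by_rephasing | inconsistent | not_evaluated
    proposed_rephasing: str | None = None


def _hap_counter(hap: tuple[str, ...]) -> Counter:
    """A chromosome as an allele multiset; an empty chromosome is *5."""
    return Counter(hap) if hap else Counter({"*5": 1})


def _is_submultiset(a: Counter, b: Counter) -> bool:
    return all(b.get(k, 0) >= n for k, n in a.items())


def _unit_splits(units: list[str]):
    """Unordered splits of an allele-unit multiset into two chromosomes."""
    n = len(units)
    seen = set()
    for r in range(n // 2 + 1):
        for idx in combinations(range(n), r):
            h1 = tuple(sorted(units[i] for i in idx))
            h2 = tuple(sorted(units[i] for i in range(n) if i not in idx))
            if max(len(h1), len(h2)) > MAX_UNITS_PER_CHROMOSOME:
                continue
            key = (h1, h2)
            if key not in seen:
                seen.add(key)
                yield h1, h2


def check_trio(child: str | None, mother: str | None,
               father: str | None) -> TrioResult:
    """Mendelian check of a trio of diplotype strings.

    Consistent: the child's two called haplotypes match one haplotype
    each transmissible from mother and father (tandems are atomic units of
    inheritance).  Failing that, alternative phasings of all three samples
    that preserve each sample's allele-unit multiset (hence its total CN
    evidence) are searched; success is ``resolvable_by_rephasing`` with a
    proposed child phasing.  ``inconsistent`` only when some child allele
    is absent from both parents.
    """
    if not (child and mother and father):
        return TrioResult("not_evaluated")
    ch, cm = parse_genotype(child)
    m_units = list(allele_multiset(mother).elements())
    f_units = list(allele_multiset(father).elements())
    m_ms, f_ms = Counter(m_units), Counter(f_units)

    def transmissible(hap: tuple[str, ...], parent_ms: Counter) -> bool:
        return _is_submultiset(_hap_counter(hap), parent_ms)

    if (transmissible(ch, m_ms) and transmissible(cm, f_ms)) or \
            (transmissible(cm, m_ms) and transmissible(ch, f_ms)):
        return TrioResult("consistent")

    # rephasing moves repartition the child's gene units (total CN evidence
    # preserved); an empty side becomes a *5 chromosome
    child_units = [u for u in allele_multiset(child).elements() if u != "*5"]
    for h1, h2 in _unit_splits(child_units):
        c1, c2 = _hap_counter(h1), _hap_counter(h2)
        if (_is_submultiset(c1, m_ms) and _is_submultiset(c2, f_ms)) or \
                (_is_submultiset(c2, m_ms) and _is_submultiset(c1, f_ms)):
            return TrioResult(
                "resolvable_by_rephasing",
                proposed_rephasing=format_genotype(h1, h2,
                                                   _tandem_conventions()))
    return TrioResult("inconsistent")


def aggregate_frequencies(calls: list[tuple[str, str, str | None]]
                          ) -> pd.DataFrame:
    """Per-population haplotype percent frequencies.

    ``calls`` holds (sample, population, genotype-or-None).  Each sample
    contributes two haplotypes (tandems counted as single haplotypes);
    no-calls contribute two "unknown" haplotypes, so every population
    column sums to 100%.
    """
    per_pop: dict[str, Counter] = {}
    totals: Counter = Counter()
    for _sample, pop, genotype in calls:
        per_pop.setdefault(pop, Counter())
        totals[pop] += 2
        if genotype is None:
            per_pop[pop]["unknown"] += 2
            continue
        h1, h2 = parse_genotype(genotype)
        for hap in (h1, h2):
            per_pop[pop][format_haplotype(hap, _tandem_conventions())] += 1
    pops = sorted(p for p in per_pop if totals[p] > 0)
    haps = sorted({h for c in per_pop.values() for h in c})
    data = {p: [100.0 * per_pop[p][h] / totals[p] for h in haps] for p in pops}
    return pd.DataFrame(data, index=haps)


def sv_stratum(genotype: str) -> str:
    """Stratify a truth genotype: deletion / duplication / hybrid / no_SV."""
    ms = allele_multiset(genotype)
    if ms & Counter({a: 4 for a in _HYBRID_ALLELES}):
        return "hybrid"
    if ms.get("*5", 0) > 0:
        return "deletion"
    if sum(ms.values()) - ms.get("*5", 0) > 2:
        return "duplication"
    return "no_SV"


def concordance(calls: dict[str, str | None],
                truth: dict[str, str]) -> dict:
    """Genotype concordance against a truth table, overall and by SV stratum."""
    strata: dict[str, list[int]] = {}
    matched = total = 0
    skipped = []
    for sample, truth_geno in truth.items():
        if sample not in calls:
            skipped.append(sample)
            continue
        call = calls[sample]
        ok = bool(call) and genotype_match(call, truth_geno)
        stratum = sv_stratum(truth_geno)
        strata.setdefault(stratum, [0, 0])
        strata[stratum][0] += int(ok)
        strata[stratum][1] += 1
        matched += int(ok)
        total += 1
    out = {
        "n": total,
        "n_concordant": matched,
        "overall_percent": 100.0 * matched / total if total else float("nan"),
        "by_stratum": {s: {"n": n, "n_concordant": m,
                           "percent": 100.0 * m / n}
                       for s, (m, n) in sorted(strata.items())},
        "missing_from_calls": skipped,
    }
    return out
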