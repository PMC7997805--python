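"""Star-allele genotype string handling.

Notation: ``/`` separates the two chromosomes, ``+`` joins tandem gene
copies on one chromosome, ``xN`` marks N identical copies on one chromosome
(``*1x2``), ``;`` separates alternative genotypes in reports.
"""
from __future__ import annotations

import re
from collections import Counter

_ALLELE_RE = re.compile(r"^\*(\d+)(?:\.(\w+))?$")


class GenotypeFormatError(ValueError):
    pass


def allele_sort_key(name: str):
    """Numeric-aware ordering: *4 < *10 < *68; sub-alleles after the parent."""
    m = _ALLELE_RE.match(name)
    if not m:
        raise GenotypeFormatError(f"unparseable star allele {name!r}")
    return (int(m.group(1)), m.group(2) or "")


def parse_haplotype(text: str) -> tuple[str, ...]:
    """``"*68+*4"`` -> ("*68", "*4"); ``"*1x2"`` -> ("*1", "*1")."""
    units: list[str] = []
    for tok in text.strip().split("+"):
        tok = tok.strip()
        m = re.match(r"^(\*[\w.]+?)\s*[xX×](\d+)$", tok)
        if m:
            name, n = m.group(1), int(m.group(2))
            units.extend([name] * n)
        else:
            name = tok
            units.append(name)
        allele_sort_key(units[-1])   # validate
    if not units:
        raise GenotypeFormatError(f"empty haplotype in {text!r}")
    return tuple(units)


def parse_genotype(text: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Parse ``"h1/h2"``; alternative genotypes after ``;`` are ignored."""
    primary = text.split(";")[0].strip()
    parts = primary.split("/")
    if len(parts) != 2:
        raise GenotypeFormatError(f"expected two '/'-separated haplotypes: {text!r}")
    return parse_haplotype(parts[0]), parse_haplotype(parts[1])


def allele_multiset(text: str) -> Counter:
    h1, h2 = parse_genotype(text)
    return Counter(h1) + Counter(h2)


def genotype_match(call: str, truth: str) -> bool:
    """True when both genotypes carry the same star-allele MULTISET,
    regardless of phasing or tandem grouping."""
    return allele_multiset(call) == allele_multiset(truth)


def format_haplotype(units: tuple[str, ...],
                     tandems: tuple[tuple[str, ...], ...] = ()) -> str:
    """Render one chromosome: duplications as ``xN``, known tandem
    arrangements in conventional order, anything else '+'-joined sorted."""
    if not units:
        return "*5"
    if len(units) == 1:
        return units[0]
    if len(set(units)) == 1:
        return f"{units[0]}x{len(units)}"
    for pat in tandems:
        if Counter(pat) == Counter(units):
            return "+".join(pat)
    return "+".join(sorted(units, key=allele_sort_key))


def format_genotype(h1: tuple[str, ...], h2: tuple[str, ...],
                    tandems: tuple[tuple[str, ...], ...] = ()) -> str:
    a, b = format_haplotype(h1, tandems), format_haplotype(h2, tandems)
    return "/".join(sorted((a, b), key=_hap_sort_key))


def _hap_sort_key(hap: str):
    return [allele_sort_key(u) for u in re.split(r"[+]", hap.replace("x", "+x"))
            if u and not u.startswith("x")]
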