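"""Targeted genotyping of star-allele-defining small variants.

Only catalogued protein-impacting variants are interrogated (no discovery).
For a variant inside a CYP2D6/CYP2D7 homology region, reads are pooled from
the CYP2D6 position AND its CYP2D7 mirror, because a CYP2D6 read carrying
the variant may have been placed on CYP2D7; elsewhere only CYP2D6-aligned
reads count.  The variant copy number is then the binomial maximum-likelihood
split of alt vs ref reads over the CYP2D6-derived copies present at that
position (full genes plus any hybrid whose CYP2D6 part covers it).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .paralog_cn import (CALL_POSTERIOR, MIN_DEPTH, SegmentProfile,
                         binomial_cn_posteriors)
from .resources import RegionModel, VariantKey

#: tolerance (bp) for matching a CIGAR-declared indel to its catalogued
#: position, absorbing left-alignment differences
INDEL_POS_TOL = 5


@dataclass(frozen=True)
class VariantSupport:
    key: VariantKey
    n_alt: int
    n_ref: int
    site_total_cn: int | None   # CYP2D6-derived CN at the variant's segment

    @property
    def depth(self) -> int:
        return self.n_alt + self.n_ref


@dataclass(frozen=True)
class VariantCall:
    key: VariantKey
    cn_alt: int | None        # argmax, reported only when posterior is decisive
    posterior: float
    ml_cn: int | None = None  # argmax regardless of posterior


def site_total_cn_for(key: VariantKey, segments: SegmentProfile) -> int | None:
    """CYP2D6-derived CN at the variant's position, from the segment consensus
    (hybrid copies whose CYP2D6 part covers the segment are included there)."""
    return segments.cn.get(key.segment)


# --------------------------------------------------------------------------
# read evidence (BAM path; the simulator emits VariantSupport directly)
# --------------------------------------------------------------------------

def _snv_counts(alignments, chrom: str, pos: int, ref: str, alt: str,
                min_baseq: int = 13) -> tuple[int, int]:
    n_alt = n_ref = 0
    for col in alignments.pileup(chrom, pos - 1, pos, truncate=True,
                                 min_base_quality=min_baseq,
                                 ignore_overlaps=False, max_depth=100000):
        if col.reference_pos != pos - 1:
            continue
        for pr in col.pileups:
            if pr.is_del or pr.is_refskip or pr.query_position is None:
                continue
            read = pr.alignment
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            b = read.query_sequence[pr.query_position]
            if b == alt:
                n_alt += 1
            elif b == ref:
                n_ref += 1
    return n_alt, n_ref


def _indel_counts(alignments, chrom: str, pos: int, kind: str,
                  length: int) -> tuple[int, int]:
    """Count reads declaring (alt) or not declaring (ref) the indel event
    within INDEL_POS_TOL of the catalogued position."""
    n_alt = n_ref = 0
    lo, hi = pos - INDEL_POS_TOL, pos + INDEL_POS_TOL
    for read in alignments.fetch(chrom, max(0, pos - 1 - 200), pos + 200):
        if read.is_unmapped or read.is_secondary or read.is_supplementary \
                or read.is_duplicate:
            continue
        if not (read.reference_start < pos - 1 < read.reference_end - 1):
            continue
        has_event = False
        refp = read.reference_start
        for op, ln in read.cigartuples:
            if op in (0, 7, 8):            # M/=/X
                refp += ln
            elif op == 2:                  # D
                if kind == "del" and ln == length and lo <= refp + 1 <= hi:
                    has_event = True
                refp += ln
            elif op == 1:                  # I
                if kind == "ins" and ln == length and lo <= refp <= hi:
                    has_event = True
            elif op in (3,):               # N
                refp += ln
        if has_event:
            n_alt += 1
        else:
            n_ref += 1
    return n_alt, n_ref


def collect_variant_support(alignments, key: VariantKey, model: RegionModel,
                            segments: SegmentProfile) -> VariantSupport:
    """Gather alt/ref read counts for one catalogued variant."""
    positions = [key.d6_pos]
    if key.in_homology_region and key.d7_mirror_pos is not None:
        positions.append(key.d7_mirror_pos)
    n_alt = n_ref = 0
    for pos in positions:
        if key.kind == "snv":
            a, r = _snv_counts(alignments, model.chrom, pos, key.ref, key.alt)
        else:
            ln = len(key.ref) if key.kind == "del" else len(key.alt)
            a, r = _indel_counts(alignments, model.chrom, pos, key.kind, ln)
        n_alt += a
        n_ref += r
    return VariantSupport(key=key, n_alt=n_alt, n_ref=n_ref,
                          site_total_cn=site_total_cn_for(key, segments))


# --------------------------------------------------------------------------
# variant CN call
# --------------------------------------------------------------------------

def call_variant_cn(support: VariantSupport) -> VariantCall:
    """Integer copies of the alt allele among the CYP2D6-derived copies.

    Same binomial-argmax machinery as the per-site paralog apportioning;
    posterior < CALL_POSTERIOR or pooled depth < MIN_DEPTH no-calls.
    """
    n_copies = support.site_total_cn
    if n_copies is None:
        return VariantCall(support.key, None, 0.0, None)
    if n_copies == 0:
        return VariantCall(support.key, 0, 1.0, 0)
    n = support.depth
    if n < MIN_DEPTH:
        return VariantCall(support.key, None, 0.0, None)
    post = binomial_cn_posteriors(support.n_alt, n, n_copies)
    i = int(np.argmax(post))
    p = float(post[i])
    if p < CALL_POSTERIOR:
        return VariantCall(support.key, None, p, i)
    return VariantCall(support.key, i, p, i)
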