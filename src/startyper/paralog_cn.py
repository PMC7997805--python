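"""Apportion CN(CYP2D6+CYP2D7) between the paralogs and type structural variants.

At each of the 117 differentiating sites, reads supporting the CYP2D6 base
and the CYP2D7 base are pooled across BOTH alignment loci (a misaligned
CYP2D6 read carries the CYP2D6 base wherever it lands).  Given the combined
CN, the CYP2D6 CN at a site is the binomial maximum-likelihood split of the
supporting reads.  Site calls are collapsed into exon-anchored segment
consensus values; a change of CYP2D6 CN along the gene reveals a hybrid:

* step up going 3'->5'  -> CYP2D6-CYP2D7 fusion (CYP2D6 5' part; *36/*68 class)
* step down going 3'->5' -> CYP2D7-CYP2D6 fusion (*13 class)

The spacer CN anchors the 3' identity: CN(total) - CN(spacer) equals the
number of genes with CYP2D6-derived 3' ends (full CYP2D6 + *13-class
hybrids), which must match the 3'-most segment consensus.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .resources import (SEGMENT_INDEX, SEGMENT_ORDER, DifferentiatingSite,
                        RegionModel)

#: error floor for the binomial success probability at CN boundaries
EPSILON = 0.01
#: minimum posterior to call an integer CN at a site
CALL_POSTERIOR = 0.95
#: minimum pooled read depth for a site/variant to be informative
MIN_DEPTH = 10
#: minimum base quality for pileup bases
MIN_BASEQ = 13
#: minimum informative sites for a segment consensus
MIN_SEGMENT_SITES = 3
#: minimum fraction of informative sites agreeing with the segment mode
MODE_SUPPORT = 2.0 / 3.0


@dataclass(frozen=True)
class SiteSupport:
    site_id: int
    n_d6: int
    n_d7: int
    n_other: int = 0

    @property
    def depth(self) -> int:
        return self.n_d6 + self.n_d7 + self.n_other

    @property
    def informative(self) -> bool:
        return self.depth >= MIN_DEPTH


@dataclass(frozen=True)
class SiteCN:
    site_id: int
    raw_cn: float
    called_cn: int | None     # argmax, reported only when posterior is decisive
    posterior: float
    ml_cn: int | None = None  # argmax regardless of posterior (consensus vote)


@dataclass(frozen=True)
class SegmentProfile:
    """Per-segment CYP2D6 CN consensus, ordered 3'->5' along the gene."""

    cn: dict              # segment name -> int | None
    n_sites: dict         # segment name -> informative site count
    agreement: dict       # segment name -> mode support fraction

    @property
    def fully_called(self) -> bool:
        return all(self.cn.get(seg) is not None for seg in SEGMENT_ORDER)

    def as_vector(self) -> list:
        return [self.cn.get(seg) for seg in SEGMENT_ORDER]


@dataclass(frozen=True)
class SVCall:
    """A partition of CN(CYP2D6+CYP2D7) into structural gene units."""

    cn_full_d6: int
    cn_full_d7: int
    d6_d7_hybrids: tuple[int, ...]   # through-exon of each *36/*68-class fusion
    d7_d6_hybrids: tuple[int, ...]   # from-exon of each *13-class fusion
    cn_total: int
    cn_spacer: int
    no_call: bool = False
    diagnostic: str = ""
    alternatives: tuple["SVCall", ...] = ()
    loglik: float = 0.0              # joint site-evidence log-likelihood

    @property
    def cn_d7_d6_hybrid(self) -> int:
        return len(self.d7_d6_hybrids)

    @property
    def cn_d6_3prime(self) -> int:
        """Genes CYP2D6-derived at the 3' end (= cn_total - cn_spacer)."""
        return self.cn_full_d6 + len(self.d7_d6_hybrids)

    @property
    def n_units(self) -> int:
        return (self.cn_full_d6 + self.cn_full_d7
                + len(self.d6_d7_hybrids) + len(self.d7_d6_hybrids))


# --------------------------------------------------------------------------
# site support (BAM path; the simulator emits SiteSupport directly)
# --------------------------------------------------------------------------

def _pileup_bases(alignments, chrom: str, pos: int) -> list[str]:
    """Base calls (BQ >= MIN_BASEQ) covering a 1-based position."""
    bases: list[str] = []
    for col in alignments.pileup(chrom, pos - 1, pos, truncate=True,
                                 min_base_quality=MIN_BASEQ,
                                 ignore_overlaps=False, max_depth=100000):
        if col.reference_pos != pos - 1:
            continue
        for pr in col.pileups:
            if pr.is_del or pr.is_refskip or pr.query_position is None:
                continue
            read = pr.alignment
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            bases.append(read.query_sequence[pr.query_position])
    return bases


def gather_site_support(alignments, panel: list[DifferentiatingSite],
                        model: RegionModel) -> list[SiteSupport]:
    """Pool pileup bases at the CYP2D6 and CYP2D7 positions of every site."""
    out = []
    for site in panel:
        bases = _pileup_bases(alignments, model.chrom, site.d6_pos)
        bases += _pileup_bases(alignments, model.chrom, site.d7_pos)
        n6 = sum(b == site.d6_base for b in bases)
        n7 = sum(b == site.d7_base for b in bases)
        out.append(SiteSupport(site_id=site.site_id, n_d6=n6, n_d7=n7,
                               n_other=len(bases) - n6 - n7))
    return out


# --------------------------------------------------------------------------
# binomial integer-CN apportioning
# --------------------------------------------------------------------------

def binomial_cn_posteriors(n_success: int, n_trials: int,
                           n_copies: int) -> np.ndarray:
    """Posterior over i in 0..n_copies for Binomial(n_success | n_trials, i/n_copies).

    Success probabilities are clamped into [EPSILON, 1-EPSILON] and the prior
    over i is uniform.
    """
    i = np.arange(n_copies + 1)
    p = np.clip(i / max(n_copies, 1), EPSILON, 1 - EPSILON)
    logl = binom.logpmf(n_success, n_trials, p)
    logl -= logl.max()
    like = np.exp(logl)
    return like / like.sum()


def call_site_cn(support: SiteSupport, cn_total: int) -> SiteCN:
    """CYP2D6 CN at one differentiating site given the combined CN."""
    if cn_total == 0:
        return SiteCN(support.site_id, 0.0, 0, 1.0, 0)
    n = support.n_d6 + support.n_d7
    if support.depth < MIN_DEPTH or n == 0:
        return SiteCN(support.site_id, float("nan"), None, 0.0, None)
    raw = cn_total * support.n_d6 / n
    post = binomial_cn_posteriors(support.n_d6, n, cn_total)
    i = int(np.argmax(post))
    p = float(post[i])
    if p < CALL_POSTERIOR:
        return SiteCN(support.site_id, raw, None, p, i)
    return SiteCN(support.site_id, raw, i, p, i)


def site_multiplicity(panel: list[DifferentiatingSite],
                      read_length: float) -> dict[str, float]:
    """Mean number of a segment's sites covered by one read.

    Read-level evidence (BAM pileups) counts each read once per site it
    covers, so pooled per-segment counts overstate the number of
    independent observations by roughly this factor; counts-level
    simulated evidence draws sites independently (multiplicity 1).
    """
    by_seg: dict[str, list[int]] = {}
    for s in panel:
        by_seg.setdefault(s.segment, []).append(s.d6_pos)
    out = {}
    for seg, pos in by_seg.items():
        width = max(pos) - min(pos)
        out[seg] = max(1.0, len(pos) * read_length / (width + read_length))
    return out


def consensus_segments(site_cns: list[SiteCN],
                       panel: list[DifferentiatingSite],
                       supports: list[SiteSupport] | None = None,
                       cn_total: int | None = None,
                       multiplicity: dict | float = 1.0) -> SegmentProfile:
    """Per-segment CYP2D6 CN consensus from the segment's sites.

    When per-site read counts are available (``supports`` + ``cn_total``),
    the segment CN is the binomial call on counts POOLED across the
    segment's informative sites — within a segment every site shares the
    same true CN, and pooling makes the estimate near-exact at 30x.  The
    per-site maximum-likelihood votes then act as an artifact guard: the
    segment no-calls when more than 1 - MODE_SUPPORT of them deviate from
    the pooled call by more than one copy (the signature of broken sites,
    not of sampling noise), when fewer than MIN_SEGMENT_SITES sites are
    informative, or when the pooled posterior itself is indecisive (e.g.
    sites split between two adjacent CNs).

    Without counts, the mode of the ML votes is used directly with the
    MODE_SUPPORT agreement rule.
    """
    seg_of = {s.site_id: s.segment for s in panel}
    votes: dict[str, list[int]] = {seg: [] for seg in SEGMENT_ORDER}
    pooled: dict[str, list[int]] = {seg: [0, 0] for seg in SEGMENT_ORDER}
    informative = {sc.site_id for sc in site_cns if sc.ml_cn is not None}
    for sc in site_cns:
        if sc.ml_cn is not None:
            votes[seg_of[sc.site_id]].append(sc.ml_cn)
    if supports is not None:
        for su in supports:
            if su.site_id in informative:
                acc = pooled[seg_of[su.site_id]]
                acc[0] += su.n_d6
                acc[1] += su.n_d6 + su.n_d7
    cn, n_sites, agreement = {}, {}, {}
    for seg in SEGMENT_ORDER:
        vals = votes[seg]
        n_sites[seg] = len(vals)
        if len(vals) < MIN_SEGMENT_SITES:
            cn[seg], agreement[seg] = None, 0.0
            continue
        if supports is not None and cn_total is not None:
            if cn_total == 0:
                cn[seg], agreement[seg] = 0, 1.0
                continue
            n6, n = pooled[seg]
            m = multiplicity.get(seg, 1.0) if isinstance(multiplicity, dict) \
                else float(multiplicity)
            if m > 1.0:     # effective-sample-size correction for shared reads
                n6, n = int(round(n6 / m)), int(round(n / m))
            post = binomial_cn_posteriors(n6, n, cn_total)
            k = int(np.argmax(post))
            agreement[seg] = sum(v == k for v in vals) / len(vals)
            consistent = sum(abs(v - k) <= 1 for v in vals) / len(vals)
            if post[k] < CALL_POSTERIOR or consistent < MODE_SUPPORT:
                cn[seg] = None
            else:
                cn[seg] = k
            continue
        mode, count = Counter(vals).most_common(1)[0]
        frac = count / len(vals)
        agreement[seg] = frac
        cn[seg] = mode if frac >= MODE_SUPPORT else None
    return SegmentProfile(cn=cn, n_sites=n_sites, agreement=agreement)


# --------------------------------------------------------------------------
# SV detection
# --------------------------------------------------------------------------

def enumerate_sv_partitions(profile: SegmentProfile, cn_total: int,
                            cn_spacer: int) -> list[SVCall]:
    """All structural partitions exactly consistent with the evidence.

    A partition assigns the segment CN profile to full CYP2D6 copies plus
    fusion genes: a *36/*68-class fusion contributes CYP2D6 CN from its
    through-exon to the 5' flank, a *13-class fusion from its from-exon to
    the 3' flank.  Constraints enforced exactly:

    * per-segment sums reproduce the consensus profile;
    * CN(spacer) = full CYP2D7 + *36/*68-class fusions;
    * all unit counts sum to CN(total).

    Partitions are ordered by parsimony (fewest hybrids first).
    """
    s = profile.as_vector()
    if any(v is None for v in s):
        return []
    results = []
    m = len(SEGMENT_ORDER)          # 11; index 0 = 3' flank ... 10 = 5' flank
    if s[0] != s[1] or s[m - 2] != s[m - 1]:
        return []                    # flanks must agree with terminal exons
    if s[0] != cn_total - cn_spacer:
        return []                    # 3' identity anchored by spacer arithmetic
    for full_d6 in range(0, min(s) + 1):
        r = [v - full_d6 for v in s]
        # split residual into a non-decreasing (d6-d7 fusions) and a
        # non-increasing (d7-d6 fusions) part
        for a_vec in _suffix_splits(r):
            d6d7: list[int] = []
            d7d6: list[int] = []
            for t in range(2, m - 1):
                step = a_vec[t] - a_vec[t - 1]
                d6d7.extend([10 - t] * step)          # through exon 10-t
            b_vec = [r[j] - a_vec[j] for j in range(m)]
            for t in range(1, m - 2):
                step = b_vec[t] - b_vec[t + 1]
                d7d6.extend([10 - t] * step)          # from exon 10-t
            full_d7 = cn_spacer - len(d6d7)
            if full_d7 < 0:
                continue
            if full_d6 + full_d7 + len(d6d7) + len(d7d6) != cn_total:
                continue
            results.append(SVCall(
                cn_full_d6=full_d6, cn_full_d7=full_d7,
                d6_d7_hybrids=tuple(sorted(d6d7)),
                d7_d6_hybrids=tuple(sorted(d7d6)),
                cn_total=cn_total, cn_spacer=cn_spacer))
    results.sort(key=lambda sv: (len(sv.d6_d7_hybrids) + len(sv.d7_d6_hybrids),
                                 len(sv.d7_d6_hybrids),
                                 sv.d6_d7_hybrids, sv.d7_d6_hybrids))
    return results


def _suffix_splits(r: list[int]):
    """Yield non-decreasing vectors A with A0=A1=0, increments only at
    indices 2..m-2, A[m-1]=A[m-2], and 0 <= A <= r componentwise such that
    r - A is non-increasing and ends at 0."""
    m = len(r)
    if r[0] != r[1] or r[m - 1] != r[m - 2]:
        return
    def rec(j, a_prev, b_prev, acc):
        if j == m - 1:
            # last index: no new increment allowed; b must be 0
            a = acc[-1]
            if r[j] - a == 0:
                yield acc + [a]
            return
        lo, hi = a_prev, r[j]
        for a in range(lo, hi + 1):
            b = r[j] - a
            if b > b_prev:
                continue
            yield from rec(j + 1, a, b, acc + [a])
    start_b = r[0]
    if min(r) < 0:
        return
    yield from rec(2, 0, start_b, [0, 0])


def _structure_profile(full_d6: int, d6d7: tuple[int, ...],
                       d7d6: tuple[int, ...]) -> list[int]:
    """Implied per-segment CYP2D6 CN (3'->5') of a structural partition."""
    m = len(SEGMENT_ORDER)
    s = [full_d6] * m
    for k in d6d7:                      # CYP2D6-derived from exon k to 5'
        start = SEGMENT_INDEX[f"exon{k}"]
        for j in range(start, m):
            s[j] += 1
    for k in d7d6:                      # CYP2D6-derived from exon k to 3'
        end = SEGMENT_INDEX[f"exon{k}"]
        for j in range(end + 1):
            s[j] += 1
    return s


def enumerate_structures(cn_total: int, cn_spacer: int,
                         max_hybrids: int = 3):
    """All structural partitions consistent with the two depth CNs alone.

    Yields (full_d6, full_d7, d6d7 switches, d7d6 switches); hybrid counts
    per class capped at ``max_hybrids``.
    """
    from itertools import combinations_with_replacement as cwr
    for n67 in range(0, min(max_hybrids, cn_spacer) + 1):
        full_d7 = cn_spacer - n67
        for n76 in range(0, max_hybrids + 1):
            full_d6 = cn_total - full_d7 - n67 - n76
            if full_d6 < 0:
                continue
            for d6d7 in cwr(range(1, 9), n67):
                for d7d6 in cwr(range(2, 10), n76):
                    yield full_d6, full_d7, d6d7, d7d6


def detect_sv_from_counts(seg_counts: dict, cn_total: int | None,
                          cn_spacer: int | None,
                          ll_window: float = 10.0) -> SVCall:
    """Joint maximum-likelihood SV typing from pooled per-segment counts.

    Every structural partition consistent with CN(total) and CN(spacer) is
    scored by the joint binomial log-likelihood of the pooled
    CYP2D6-supporting counts across all segments under its implied segment
    profile; the best-scoring partition is returned, with every partition
    within ``ll_window`` log-units retained as an alternative (downstream
    small-variant evidence arbitrates between them).  No-call when the
    evidence fits no partition decisively better than a saturated
    per-segment model (lack-of-fit), or when a CN input is missing.

    ``seg_counts`` maps segment -> (n_d6, n_total) effective read counts.
    """
    if cn_total is None or cn_spacer is None:
        return SVCall(0, 0, (), (), cn_total or 0, cn_spacer or 0,
                      no_call=True, diagnostic="total or spacer CN not called")
    n6 = np.array([seg_counts[seg][0] for seg in SEGMENT_ORDER], dtype=float)
    n = np.array([seg_counts[seg][1] for seg in SEGMENT_ORDER], dtype=float)
    usable = n >= MIN_DEPTH
    if usable.sum() < len(SEGMENT_ORDER) // 2:
        return SVCall(0, 0, (), (), cn_total, cn_spacer, no_call=True,
                      diagnostic="insufficient informative segments")
    cands = list(enumerate_structures(cn_total, cn_spacer))
    if not cands:
        return SVCall(0, 0, (), (), cn_total, cn_spacer, no_call=True,
                      diagnostic="no structural partition consistent with "
                                 "CN(total)/CN(spacer)")
    profiles = np.array([_structure_profile(f6, d67, d76)
                         for f6, _f7, d67, d76 in cands], dtype=float)
    denom = max(cn_total, 1)
    p = np.clip(profiles / denom, EPSILON, 1 - EPSILON)
    ll = binom.logpmf(n6[None, :], n[None, :], p)[:, usable].sum(axis=1)
    # saturated model: per-segment ML success fraction
    p_hat = np.clip(n6 / np.maximum(n, 1), EPSILON, 1 - EPSILON)
    ll_sat = float(binom.logpmf(n6, n, p_hat)[usable].sum())
    order = sorted(range(len(cands)),
                   key=lambda i: (-ll[i],
                                  len(cands[i][2]) + len(cands[i][3]),
                                  cands[i][2], cands[i][3]))
    best = order[0]
    if ll_sat - ll[best] > 30.0:
        return SVCall(0, 0, (), (), cn_total, cn_spacer, no_call=True,
                      diagnostic="segment profile fits no modelled SV "
                                 f"structure (lack of fit {ll_sat - ll[best]:.1f})")
    kept = [i for i in order if ll[i] >= ll[best] - ll_window]

    def mk(i, alts=()):
        f6, f7, d67, d76 = cands[i]
        return SVCall(f6, f7, tuple(d67), tuple(d76), cn_total, cn_spacer,
                      loglik=float(ll[i]), alternatives=tuple(alts))

    return mk(best, [mk(i) for i in kept[1:]])


def detect_sv(profile: SegmentProfile, cn_total: int | None,
              cn_spacer: int | None) -> SVCall:
    """Reconcile segment consensus, total CN and spacer CN into an SVCall.

    The primary call is the most parsimonious (fewest-hybrids) partition;
    every other exactly-consistent partition is retained in ``alternatives``
    so the diplotype resolver can fall back when small-variant evidence
    rejects the parsimonious reading.  Irreconcilable evidence no-calls.
    """
    if cn_total is None or cn_spacer is None:
        return SVCall(0, 0, (), (), cn_total or 0, cn_spacer or 0, no_call=True,
                      diagnostic="total or spacer CN not called")
    if not profile.fully_called:
        missing = [seg for seg in SEGMENT_ORDER if profile.cn.get(seg) is None]
        return SVCall(0, 0, (), (), cn_total, cn_spacer, no_call=True,
                      diagnostic=f"segments without consensus: {missing}")
    parts = enumerate_sv_partitions(profile, cn_total, cn_spacer)
    if not parts:
        return SVCall(0, 0, (), (), cn_total, cn_spacer, no_call=True,
                      diagnostic="no structural partition reconciles the "
                                 "segment profile with CN(total)/CN(spacer)")
    primary = parts[0]
    return SVCall(primary.cn_full_d6, primary.cn_full_d7,
                  primary.d6_d7_hybrids, primary.d7_d6_hybrids,
                  cn_total, cn_spacer, alternatives=tuple(parts[1:]))
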