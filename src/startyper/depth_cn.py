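"""Copy number of the combined CYP2D6+CYP2D7 region and of the spacer.

Raw evidence is a read count over a counting region.  Because the two
paralogs are near-identical, reads from every gene copy pile up onto a
single gene-length unit, so the combined region is normalized by ONE gene
length: an SV-free diploid sample (2 CYP2D6 + 2 CYP2D7) scores a normalized
depth of ~4.0 and the spacer (one copy per CYP2D7-derived 3' end) ~2.0.

The chain is: count reads (MAPQ 0 included — homology makes mapping quality
uninformative here) -> GC-correct against a panel of preselected diploid
baseline regions -> express depth in copy-number units (diploid locus = 2.0)
-> call an integer CN from a fixed Gaussian mixture with components centred
on the integers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .resources import RegionModel

#: mixture components sit at integer CN 0..MAX_CN
MAX_CN = 10
#: shared component standard deviation, CN units
GMM_SIGMA = 0.25
#: minimum posterior for an integer call; below this -> no-call
CALL_POSTERIOR = 0.95
#: GC bins of width 0.05 spanning [0.25, 0.75)
GC_BIN_WIDTH = 0.05
GC_BIN_LO, GC_BIN_HI = 0.25, 0.75
#: clamp range for the GC correction factor
GC_FACTOR_MIN, GC_FACTOR_MAX = 0.5, 2.0


class DepthError(RuntimeError):
    """Fatal problem with the depth evidence (e.g. unusable baseline)."""


@dataclass(frozen=True)
class GenomeBaseline:
    """Per-base depths and GC fractions of a panel of diploid baseline regions."""

    depths: np.ndarray
    gc: np.ndarray

    def __post_init__(self):
        if len(self.depths) != len(self.gc) or len(self.depths) == 0:
            raise DepthError("baseline panel empty or misaligned")

    @property
    def diploid_median(self) -> float:
        med = float(np.median(self.depths))
        if med <= 0:
            raise DepthError("baseline median depth is not positive")
        return med

    def gc_bin_median(self, gc: float) -> float | None:
        """Median depth of baseline regions in the same GC bin, or None if empty."""
        idx = int((gc - GC_BIN_LO) / GC_BIN_WIDTH + 1e-9)
        lo = max(GC_BIN_LO, min(GC_BIN_HI - GC_BIN_WIDTH,
                                GC_BIN_LO + GC_BIN_WIDTH * idx))
        mask = (self.gc >= lo - 1e-9) & (self.gc < lo + GC_BIN_WIDTH - 1e-9)
        if not mask.any():
            return None
        return float(np.median(self.depths[mask]))


@dataclass(frozen=True)
class NormalizedDepth:
    """Depth in copy-number units: an unduplicated diploid locus scores 2.0."""

    value: float
    qc_flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class TotalCNCall:
    cn_total: int | None
    cn_spacer: int | None
    posterior_total: float
    posterior_spacer: float
    depth_total: NormalizedDepth | None = None
    depth_spacer: NormalizedDepth | None = None
    ml_total: int | None = None    # argmax regardless of posterior
    ml_spacer: int | None = None


# --------------------------------------------------------------------------
# read counting (BAM/CRAM path)
# --------------------------------------------------------------------------

def count_region_reads(alignments, chrom: str, start: int, end: int) -> int:
    """Count primary, non-duplicate reads whose alignment start lies in
    [start, end] (1-based inclusive).  Mapping quality is NOT filtered:
    MAPQ-0 reads are deliberately included.
    """
    if end < start:
        return 0
    n = 0
    for read in alignments.fetch(chrom, start - 1, end):
        if read.is_unmapped or read.is_secondary or read.is_supplementary \
                or read.is_duplicate:
            continue
        if start - 1 <= read.reference_start < end:
            n += 1
    return n


def depth_from_count(read_count: int, read_length: float, unit_length: int) -> float:
    """Mean per-base depth implied by ``read_count`` reads over ``unit_length``."""
    if unit_length <= 0:
        raise DepthError("non-positive counting unit length")
    return read_count * read_length / unit_length


# --------------------------------------------------------------------------
# GC correction and normalization
# --------------------------------------------------------------------------

def gc_correct(raw_depth: float, gc: float | None,
               baseline: GenomeBaseline) -> tuple[float, set[str]]:
    """Scale ``raw_depth`` by the global-vs-GC-bin baseline median ratio.

    The factor is clamped to [0.5, 2.0]; an empty GC bin falls back to the
    global median (factor 1) with a qc flag.  ``gc=None`` bypasses the
    correction entirely (counts-level inputs without GC annotation).
    """
    flags: set[str] = set()
    if gc is None:
        return raw_depth, {"gc_bypassed"}
    bin_med = baseline.gc_bin_median(gc)
    if bin_med is None or bin_med <= 0:
        return raw_depth, {"gc_bin_empty"}
    factor = baseline.diploid_median / bin_med
    if factor < GC_FACTOR_MIN or factor > GC_FACTOR_MAX:
        factor = min(max(factor, GC_FACTOR_MIN), GC_FACTOR_MAX)
        flags.add("gc_factor_clamped")
    return raw_depth * factor, flags


def normalize(corrected_depth: float, baseline: GenomeBaseline,
              qc_flags: set[str] | frozenset[str] = frozenset()) -> NormalizedDepth:
    """Express a corrected per-base depth in copy-number units (diploid = 2.0)."""
    value = 2.0 * corrected_depth / baseline.diploid_median
    if value < 0:
        raise DepthError("negative normalized depth")
    return NormalizedDepth(value=value, qc_flags=frozenset(qc_flags))


# --------------------------------------------------------------------------
# Gaussian-mixture integer CN call
# --------------------------------------------------------------------------

def cn_posteriors(value: float) -> np.ndarray:
    """Posterior over integer CN 0..MAX_CN for one normalized depth value.

    Components N(k, GMM_SIGMA) with a uniform prior; returned vector sums
    to 1.
    """
    logp = norm.logpdf(value, loc=np.arange(MAX_CN + 1), scale=GMM_SIGMA)
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def call_integer_cn(depth: NormalizedDepth | float) -> tuple[int | None, float]:
    """Argmax-posterior integer CN; no-call (None) below CALL_POSTERIOR."""
    value = depth.value if isinstance(depth, NormalizedDepth) else float(depth)
    post = cn_posteriors(value)
    k = int(np.argmax(post))
    p = float(post[k])
    if p < CALL_POSTERIOR:
        return None, p
    return k, p


# --------------------------------------------------------------------------
# combined driver
# --------------------------------------------------------------------------

def _call_one(read_count: int, read_length: float, unit_length: int,
              gc: float | None, baseline: GenomeBaseline
              ) -> tuple[int | None, float, NormalizedDepth, int]:
    raw = depth_from_count(read_count, read_length, unit_length)
    corrected, flags = gc_correct(raw, gc, baseline)
    nd = normalize(corrected, baseline, flags)
    cn, post = call_integer_cn(nd)
    ml = int(np.argmax(cn_posteriors(nd.value)))
    return cn, post, nd, ml


def call_total_and_spacer_from_counts(
        d6d7_count: int, spacer_count: int, read_length: float,
        model: RegionModel, baseline: GenomeBaseline,
        gc_d6d7: float | None = None, gc_spacer: float | None = None
        ) -> TotalCNCall:
    """Counts-level entry: read counts for the combined gene region and the
    spacer (as produced by the simulator or an external counter).

    The combined CYP2D6+CYP2D7 count is normalized by a single gene length,
    the spacer count by the spacer length.
    """
    cn_t, p_t, nd_t, ml_t = _call_one(d6d7_count, read_length, model.d6_length,
                                      gc_d6d7, baseline)
    cn_s, p_s, nd_s, ml_s = _call_one(spacer_count, read_length,
                                      model.spacer_length, gc_spacer, baseline)
    return TotalCNCall(cn_total=cn_t, cn_spacer=cn_s,
                       posterior_total=p_t, posterior_spacer=p_s,
                       depth_total=nd_t, depth_spacer=nd_s,
                       ml_total=ml_t, ml_spacer=ml_s)


def call_total_and_spacer(alignments, model: RegionModel,
                          baseline: GenomeBaseline,
                          read_length: float = 150.0,
                          gc_d6d7: float | None = None,
                          gc_spacer: float | None = None) -> TotalCNCall:
    """BAM/CRAM entry: count reads over both gene spans and the spacer span,
    then run the count -> correct -> normalize -> call chain.
    """
    c6 = count_region_reads(alignments, model.chrom, *model.d6_span)
    c7 = count_region_reads(alignments, model.chrom, *model.d7_span)
    cs = count_region_reads(alignments, model.chrom, *model.spacer_span)
    if c6 + c7 + cs == 0:
        raise DepthError("no reads over the CYP2D6/CYP2D7 locus")
    return call_total_and_spacer_from_counts(
        c6 + c7, cs, read_length, model, baseline, gc_d6d7, gc_spacer)
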