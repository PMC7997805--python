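"""Synthetic evidence generator for arbitrary CYP2D6 diplotypes.

Emulates the evidence the caller consumes, at two levels:

* ``simulate_counts`` — a counts-level bundle: Poisson region read counts
  (per-copy depth x length), binomial/multinomial read splits at every
  differentiating site and catalogued variant position (with per-base error
  contamination), optional GC bias, and a diploid baseline panel;
* ``simulate_bam`` — a small sorted+indexed BAM over a miniature synthetic
  contig mirroring the chr22 locus layout (coordinate shim, not real
  sequence), with MAPQ-0 reads and cross-paralog misplacement inside the
  homology regions, so the real pysam extraction path is exercised.

Defaults model a 30x diploid WGS run: 15x per gene copy, 150 bp reads,
0.2% per-base error.  Everything is reproducible from the seed.
"""
from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .depth_cn import GenomeBaseline
from .nomenclature import parse_genotype
from .paralog_cn import SiteSupport
from .resources import (SEGMENT_ORDER, AlleleTable, DifferentiatingSite,
                        RegionModel, StructuralUnit, load_allele_definitions,
                        load_region_model, load_site_panel)

DEFAULT_PER_COPY_DEPTH = 15.0     # per-base depth per gene copy (30x diploid)
DEFAULT_READ_LENGTH = 150
DEFAULT_ERROR_RATE = 0.002
BASELINE_REGIONS = 1000
BASELINE_REGION_LENGTH = 2000
GC_D6D7 = 0.55                    # modelled GC of the gene counting region
GC_SPACER = 0.45


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationSpec:
    genotype: str
    per_copy_depth: float = DEFAULT_PER_COPY_DEPTH
    read_length: int = DEFAULT_READ_LENGTH
    error_rate: float = DEFAULT_ERROR_RATE
    seed: int = 0
    gc_bias: dict | None = None   # GC-bin lower edge -> depth multiplier
    exact: bool = False           # noise-free expectation mode

    def __post_init__(self):
        if self.per_copy_depth <= 0:
            raise SimulationError("per_copy_depth must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Deterministic structural expansion of a diplotype string."""

    genotype: str
    haplotypes: tuple[tuple[str, ...], tuple[str, ...]]
    units: tuple[tuple[str, StructuralUnit], ...]   # (allele name, structure)
    n_d7: int                                       # separate CYP2D7 copies
    cn_total: int
    cn_spacer: int
    segment_cn: dict                                # segment -> CYP2D6 CN
    variant_copies: Counter                         # g_label -> copies

    @property
    def n_full_d6(self) -> int:
        return sum(1 for _, u in self.units if u.kind == "full_d6")


def expand_genotype(genotype: str, defs: AlleleTable | None = None) -> GroundTruth:
    """Expand a diplotype string into gene units, CNs and variant copies.

    Each chromosome carries its star-allele gene units at the CYP2D6 locus
    plus one separate CYP2D7 — unless a deletion-fusion allele (*13 class)
    removed it.  The spacer count is one per CYP2D7-derived 3' end
    (separate CYP2D7 copies and *36/*68-class fusions).
    """
    defs = defs or load_allele_definitions()
    haps = parse_genotype(genotype)
    units: list[tuple[str, StructuralUnit]] = []
    n_d7 = 0
    variant_copies: Counter = Counter()
    for hap in haps:
        hap_units = []
        for name in hap:
            if name not in defs.alleles:
                raise SimulationError(f"unknown star allele {name!r}")
            a = defs[name]
            if a.is_deletion:
                if len(hap) > 1:
                    raise SimulationError("*5 cannot share a chromosome")
                continue
            hap_units.append((name, a.structure))
            variant_copies.update(a.defining_variants)
        fused = any(u.kind == "d7_d6" and u.fused for _, u in hap_units)
        n_d7 += 0 if fused else 1
        units.extend(hap_units)
    segment_cn = {seg: sum(seg in u.d6_segments() for _, u in units)
                  for seg in SEGMENT_ORDER}
    cn_spacer = n_d7 + sum(1 for _, u in units if u.has_own_spacer)
    return GroundTruth(
        genotype=genotype,
        haplotypes=tuple(tuple(h) for h in haps),
        units=tuple(units), n_d7=n_d7,
        cn_total=len(units) + n_d7, cn_spacer=cn_spacer,
        segment_cn=segment_cn, variant_copies=variant_copies)


# --------------------------------------------------------------------------
# counts-level simulation
# --------------------------------------------------------------------------

@dataclass
class CountsBundle:
    """Counts-level evidence for one sample, as consumed by the pipeline."""

    build: str
    read_length: int
    d6d7_count: int
    spacer_count: int
    gc_d6d7: float | None
    gc_spacer: float | None
    baseline: GenomeBaseline
    site_support: list[SiteSupport]
    variant_counts: dict            # g_label -> (n_alt, n_ref)
    truth: GroundTruth | None = None


def _bias_factor(gc: float, gc_bias: dict | None) -> float:
    if not gc_bias:
        return 1.0
    for lo, mult in gc_bias.items():
        if float(lo) <= gc < float(lo) + 0.05:
            return float(mult)
    return 1.0


def _poisson(rng, lam: float, exact: bool) -> int:
    return int(round(lam)) if exact else int(rng.poisson(lam))


def simulate_baseline(rng, per_copy_depth: float, read_length: int,
                      gc_bias: dict | None = None,
                      exact: bool = False,
                      n_regions: int = BASELINE_REGIONS) -> GenomeBaseline:
    """Diploid baseline panel: per-region median depths with GC fractions."""
    gc = np.round(rng.uniform(0.26, 0.74, size=n_regions), 3)
    lam = 2 * per_copy_depth * BASELINE_REGION_LENGTH / read_length
    depths = np.empty(n_regions)
    for i in range(n_regions):
        l = lam * _bias_factor(gc[i], gc_bias)
        c = _poisson(rng, l, exact)
        depths[i] = c * read_length / BASELINE_REGION_LENGTH
    return GenomeBaseline(depths=depths, gc=gc)


def _site_probs(f: float, e: float) -> tuple[float, float, float]:
    """(P[d6 base], P[d7 base], P[other]) for CYP2D6-derived fraction f."""
    p6 = f * (1 - e) + (1 - f) * (e / 3)
    p7 = (1 - f) * (1 - e) + f * (e / 3)
    return p6, p7, max(0.0, 1 - p6 - p7)


def _split(rng, n: int, probs, exact: bool) -> list[int]:
    if exact:
        out = [int(round(n * p)) for p in probs[:-1]]
        out.append(n - sum(out))
        return out
    return list(rng.multinomial(n, np.asarray(probs) / sum(probs)))


def simulate_counts(spec: SimulationSpec, build: str = "GRCh38",
                    model: RegionModel | None = None,
                    panel: list[DifferentiatingSite] | None = None,
                    defs: AlleleTable | None = None) -> CountsBundle:
    """Generate the full counts-level evidence bundle for one sample."""
    model = model or load_region_model(build)
    panel = panel or load_site_panel(build)
    defs = defs or load_allele_definitions(build, model)
    truth = expand_genotype(spec.genotype, defs)
    rng = np.random.default_rng(spec.seed)
    e = 0.0 if spec.exact else spec.error_rate
    dp, rl = spec.per_copy_depth, spec.read_length

    baseline = simulate_baseline(rng, dp, rl, spec.gc_bias, spec.exact)

    lam_gene = truth.cn_total * dp * model.d6_length / rl \
        * _bias_factor(GC_D6D7, spec.gc_bias)
    lam_spacer = truth.cn_spacer * dp * model.spacer_length / rl \
        * _bias_factor(GC_SPACER, spec.gc_bias)
    d6d7_count = _poisson(rng, lam_gene, spec.exact)
    spacer_count = _poisson(rng, lam_spacer, spec.exact)

    site_support = []
    for site in panel:
        f = (truth.segment_cn[site.segment] / truth.cn_total
             if truth.cn_total else 0.0)
        n = _poisson(rng, truth.cn_total * dp, spec.exact)
        n6, n7, no = _split(rng, n, _site_probs(f, e), spec.exact)
        site_support.append(SiteSupport(site.site_id, n6, n7, no))

    variant_counts = {}
    for g_label, key in defs.variants.items():
        n_d6_copies = truth.segment_cn[key.segment]
        alt_copies = truth.variant_copies.get(g_label, 0)
        covering = truth.cn_total if key.in_homology_region else n_d6_copies
        if covering == 0:
            variant_counts[g_label] = (0, 0)
            continue
        ref_copies = n_d6_copies - alt_copies
        p_alt = (alt_copies * (1 - e) + (covering - alt_copies) * e / 3) / covering
        p_ref = (ref_copies * (1 - e) + (covering - ref_copies) * e / 3) / covering
        n = _poisson(rng, covering * dp, spec.exact)
        n_alt, n_ref, _ = _split(
            rng, n, (p_alt, p_ref, max(0.0, 1 - p_alt - p_ref)), spec.exact)
        variant_counts[g_label] = (n_alt, n_ref)

    gc_bundle = (GC_D6D7, GC_SPACER) if spec.gc_bias else (None, None)
    return CountsBundle(
        build=build, read_length=rl,
        d6d7_count=d6d7_count, spacer_count=spacer_count,
        gc_d6d7=gc_bundle[0], gc_spacer=gc_bundle[1],
        baseline=baseline, site_support=site_support,
        variant_counts=variant_counts, truth=truth)


# --------------------------------------------------------------------------
# counts bundle TSV round-trip (CLI surface)
# --------------------------------------------------------------------------

def write_counts(bundle: CountsBundle, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "regions.tsv"), "w") as fh:
        fh.write("region\tread_count\tgc\tread_length\tbuild\n")
        for name, cnt, gc in (("d6d7", bundle.d6d7_count, bundle.gc_d6d7),
                              ("spacer", bundle.spacer_count, bundle.gc_spacer)):
            fh.write(f"{name}\t{cnt}\t{'' if gc is None else gc}"
                     f"\t{bundle.read_length}\t{bundle.build}\n")
    with open(os.path.join(directory, "baseline.tsv"), "w") as fh:
        fh.write("gc\tdepth\n")
        for g, d in zip(bundle.baseline.gc, bundle.baseline.depths):
            fh.write(f"{g:.3f}\t{d:.4f}\n")
    with open(os.path.join(directory, "sites.tsv"), "w") as fh:
        fh.write("site_id\tn_d6\tn_d7\tn_other\n")
        for s in bundle.site_support:
            fh.write(f"{s.site_id}\t{s.n_d6}\t{s.n_d7}\t{s.n_other}\n")
    with open(os.path.join(directory, "variants.tsv"), "w") as fh:
        fh.write("g_label\tn_alt\tn_ref\n")
        for g_label, (na, nr) in bundle.variant_counts.items():
            fh.write(f"{g_label}\t{na}\t{nr}\n")


def load_counts(directory: str) -> CountsBundle:
    import pandas as pd
    reg = pd.read_csv(os.path.join(directory, "regions.tsv"), sep="\t")
    reg = reg.set_index("region")
    base = pd.read_csv(os.path.join(directory, "baseline.tsv"), sep="\t")
    sites = pd.read_csv(os.path.join(directory, "sites.tsv"), sep="\t")
    var = pd.read_csv(os.path.join(directory, "variants.tsv"), sep="\t")

    def _gc(row):
        v = reg.loc[row, "gc"]
        return None if (isinstance(v, float) and np.isnan(v)) else float(v)

    return CountsBundle(
        build=str(reg.loc["d6d7", "build"]),
        read_length=int(reg.loc["d6d7", "read_length"]),
        d6d7_count=int(reg.loc["d6d7", "read_count"]),
        spacer_count=int(reg.loc["spacer", "read_count"]),
        gc_d6d7=_gc("d6d7"), gc_spacer=_gc("spacer"),
        baseline=GenomeBaseline(depths=base["depth"].to_numpy(),
                                gc=base["gc"].to_numpy()),
        site_support=[SiteSupport(int(r.site_id), int(r.n_d6), int(r.n_d7),
                                  int(r.n_other)) for r in sites.itertuples()],
        variant_counts={str(r.g_label): (int(r.n_alt), int(r.n_ref))
                        for r in var.itertuples()})


# --------------------------------------------------------------------------
# mini-reference BAM simulation
# --------------------------------------------------------------------------

MINI_SHIFT = 42120000
MINI_CONTIG = "chr22_mini"
BASELINE_CONTIG = "baseline_mini"
MINI_BASELINE_REGIONS = 100
MINI_BASELINE_REGION_LENGTH = 1000
_FLANK5_G = -350          # gene-relative extent of the simulated 5' flank
_FLANK3_G = 5162          # 3' flank end for CYP2D6-derived 3' ends
_FLANK3_D7_G = 5865       # CYP2D7-derived 3' ends run through the spacer
_REF_SEED = 20200715      # fixed: the mini reference is a constant artifact


def mini_region_model(build: str = "GRCh38") -> RegionModel:
    """The GRCh38 region model re-based onto the miniature contig."""
    m = load_region_model(build)
    sh = lambda iv: (iv[0] - MINI_SHIFT, iv[1] - MINI_SHIFT)
    return RegionModel(
        build=m.build, chrom=MINI_CONTIG,
        d6_span=sh(m.d6_span), d7_span=sh(m.d7_span),
        rep6_span=sh(m.rep6_span), rep7_span=sh(m.rep7_span),
        spacer_span=sh(m.spacer_span),
        d6_exons=tuple(sh(e) for e in m.d6_exons),
        d7_exons=tuple(sh(e) for e in m.d7_exons),
        homology_regions=tuple(sh(h) for h in m.homology_regions))


def mini_site_panel(build: str = "GRCh38") -> list[DifferentiatingSite]:
    return [DifferentiatingSite(s.site_id, s.d6_pos - MINI_SHIFT,
                                s.d7_pos - MINI_SHIFT, s.d6_base, s.d7_base,
                                s.segment)
            for s in load_site_panel(build)]


def mini_baseline_regions() -> list[tuple[str, int, int]]:
    out = []
    for i in range(MINI_BASELINE_REGIONS):
        start = 1 + i * MINI_BASELINE_REGION_LENGTH
        out.append((BASELINE_CONTIG, start,
                    start + MINI_BASELINE_REGION_LENGTH - 1))
    return out


def _mini_sequences(model: RegionModel, panel, defs: AlleleTable
                    ) -> dict[str, bytearray]:
    """Deterministic mini contig: CYP2D7 region is a copy of the CYP2D6
    region except at differentiating sites and homology-variant mirrors."""
    rng = np.random.default_rng(_REF_SEED)
    length = model.d7_span[1] + 500
    seq = bytearray(rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                               size=length).tobytes())
    lo = model.d6_span[0] - 1000
    hi = model.d6_span[1] + 1000
    off = model.d7_offset
    seq[lo + off - 1:hi + off] = seq[lo - 1:hi]        # paralog homology
    for s in panel:
        seq[s.d6_pos - 1] = ord(s.d6_base)
        seq[s.d7_pos - 1] = ord(s.d7_base)
    for key in defs.variants.values():
        if key.kind == "snv":
            seq[key.d6_pos - 1] = ord(key.ref)
            if key.d7_mirror_pos is not None:
                third = next(b for b in "ACGT" if b not in (key.ref, key.alt))
                seq[key.d7_mirror_pos - 1] = ord(third)
    base_len = MINI_BASELINE_REGIONS * MINI_BASELINE_REGION_LENGTH + 500
    baseline = bytearray(rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                                    size=base_len).tobytes())
    return {MINI_CONTIG: seq, BASELINE_CONTIG: baseline}


def write_mini_reference(path: str) -> None:
    """Write the deterministic miniature reference FASTA (+faidx)."""
    import pysam
    model = mini_region_model()
    panel = mini_site_panel()
    defs = load_allele_definitions(model=model)
    seqs = _mini_sequences(model, panel, defs)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            raw = seq.decode()
            for i in range(0, len(raw), 80):
                fh.write(raw[i:i + 80] + "\n")
    pysam.faidx(path)


def _unit_blocks(unit: StructuralUnit, model: RegionModel):
    """(g_lo, g_hi, derived) derivation blocks of one gene unit, 5'->3'."""
    gene_end = model.pos_to_g(model.d6_span[0])       # 4312
    ex = [(model.pos_to_g(hi), model.pos_to_g(lo)) for lo, hi in model.d6_exons]
    if unit.kind == "full_d6":
        return [(_FLANK5_G, _FLANK3_G, "d6")]
    if unit.kind == "d6_d7":
        k = unit.through_exon
        bound = (ex[k - 1][1] + ex[k][0]) // 2
        return [(_FLANK5_G, bound, "d6"), (bound + 1, _FLANK3_D7_G, "d7")]
    k = unit.from_exon
    bound = (ex[k - 2][1] + ex[k - 1][0]) // 2
    return [(_FLANK5_G, bound, "d7"), (bound + 1, _FLANK3_G, "d6")]


_D7_UNIT_BLOCKS = [(_FLANK5_G, _FLANK3_D7_G, "d7")]


def simulate_bam(spec: SimulationSpec, out_dir: str,
                 reference: str | None = None) -> dict:
    """Simulate an indexed mini BAM for the diplotype; returns paths and the
    shifted region model needed to genotype it."""
    import pysam
    os.makedirs(out_dir, exist_ok=True)
    model = mini_region_model()
    panel = mini_site_panel()
    defs = load_allele_definitions(model=model)
    truth = expand_genotype(spec.genotype, defs)
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length

    ref_path = reference or os.path.join(out_dir, "mini_ref.fa")
    if not os.path.exists(ref_path):
        write_mini_reference(ref_path)
    ref = pysam.FastaFile(ref_path)
    seqs = {name: ref.fetch(name) for name in ref.references}
    if MINI_CONTIG not in seqs:
        raise SimulationError("reference lacks the mini contig")
    contig_len = {name: len(s) for name, s in seqs.items()}
    off = model.d7_offset

    hom_intervals = list(model.homology_regions) + \
        [(lo + off, hi + off) for lo, hi in model.homology_regions]

    def in_homology(pos):
        return any(lo <= pos <= hi for lo, hi in hom_intervals)

    # per-unit variant edits on the CYP2D6-derived sequence
    unit_variants = []
    for name, unit in truth.units:
        keys = [defs.variants[v] for v in defs[name].defining_variants]
        unit_variants.append((unit, sorted(keys, key=lambda k: k.d6_pos)))

    reads = []  # (tid_name, pos0, mapq, cigar, seq)
    n_read = 0

    def emit_block(template_start, block_len, variants, shift_ok):
        """Place Poisson reads over one derivation block."""
        nonlocal n_read
        n = rng.poisson(spec.per_copy_depth * block_len / rl)
        starts = template_start + rng.integers(-rl + 1, block_len, size=n)
        for s0 in np.sort(starts):                      # 1-based start
            s0 = int(s0)
            if s0 < 1:
                continue
            seq, cigar, ref_span = _read_sequence(
                seqs[MINI_CONTIG], s0, rl, variants)
            if seq is None or s0 + ref_span - 1 > contig_len[MINI_CONTIG]:
                continue
            seq = _add_errors(rng, seq, spec.error_rate)
            pos = s0
            mapq = 60
            if in_homology(s0):
                mapq = 0
                if shift_ok and rng.random() < 0.5:     # cross-paralog placement
                    pos = s0 + off if s0 <= model.d6_span[1] + 1000 else s0 - off
            reads.append((MINI_CONTIG, pos - 1, mapq, cigar, seq))
            n_read += 1

    for (name, unit), (_, variants) in zip(truth.units, unit_variants):
        for g_lo, g_hi, derived in _unit_blocks(unit, model):
            # g increases 5'->3'; genomic runs opposite (minus strand)
            start = model.g_to_pos(g_hi)
            if derived == "d7":
                start += off
            blen = g_hi - g_lo + 1
            emit_block(start, blen,
                       variants if derived == "d6" else [], shift_ok=True)
    for _ in range(truth.n_d7):
        for g_lo, g_hi, derived in _D7_UNIT_BLOCKS:
            emit_block(model.g_to_pos(g_hi) + off, g_hi - g_lo + 1, [],
                       shift_ok=True)

    # diploid baseline contig
    base_template = seqs[BASELINE_CONTIG]
    total = MINI_BASELINE_REGIONS * MINI_BASELINE_REGION_LENGTH
    n = rng.poisson(2 * spec.per_copy_depth * total / rl)
    for s0 in np.sort(rng.integers(1, total - rl, size=n)):
        s0 = int(s0)
        seq = base_template[s0 - 1:s0 - 1 + rl]
        reads.append((BASELINE_CONTIG, s0 - 1, 60, [(0, rl)],
                      _add_errors(rng, seq, spec.error_rate)))

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": name, "LN": contig_len[name]}
                     for name in (MINI_CONTIG, BASELINE_CONTIG)]}
    tid = {MINI_CONTIG: 0, BASELINE_CONTIG: 1}
    reads.sort(key=lambda r: (tid[r[0]], r[1]))
    bam_path = os.path.join(out_dir, "sample.bam")
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for i, (ctg, pos0, mapq, cigar, seq) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.reference_id = tid[ctg]
            a.reference_start = pos0
            a.mapping_quality = mapq
            a.cigartuples = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.flag = 0
            reads[i] = None
            bam.write(a)
    pysam.index(bam_path)
    return {"bam": bam_path, "reference": ref_path, "model": model,
            "panel": panel, "defs": defs,
            "baseline_regions": mini_baseline_regions(), "truth": truth}


def _read_sequence(template: str, start1: int, rl: int, variants):
    """Read sequence + CIGAR from the template applying at most one indel
    (catalogued indels never co-occur within one read length)."""
    end1 = start1 + rl - 1
    for key in variants:
        p = key.d6_pos
        if key.kind == "snv":
            continue
        if key.kind == "del":
            L = len(key.ref)
            if start1 < p and p + L - 1 < end1:
                left = p - start1
                seq = template[start1 - 1:p - 1] \
                    + template[p + L - 1:p + L - 1 + (rl - left)]
                if len(seq) < rl:
                    return None, None, None
                return _apply_snvs(seq, start1, variants, del_at=(p, L)), \
                    [(0, left), (2, L), (0, rl - left)], rl + L
        if key.kind == "ins":
            L = len(key.alt)
            if start1 <= p < end1 - L:
                left = p - start1 + 1
                seq = template[start1 - 1:p] + key.alt \
                    + template[p:p + (rl - left - L)]
                if len(seq) < rl:
                    return None, None, None
                return _apply_snvs(seq, start1, variants, ins_at=(p, L)), \
                    [(0, left), (1, L), (0, rl - left - L)], rl - L
    seq = template[start1 - 1:start1 - 1 + rl]
    if len(seq) < rl:
        return None, None, None
    return _apply_snvs(seq, start1, variants), [(0, rl)], rl


def _apply_snvs(seq: str, start1: int, variants, del_at=None, ins_at=None):
    out = list(seq)
    for key in variants:
        if key.kind != "snv":
            continue
        p = key.d6_pos
        idx = p - start1
        if del_at and p >= del_at[0]:
            idx -= del_at[1] if p >= del_at[0] + del_at[1] else 0
        if ins_at and p > ins_at[0]:
            idx += ins_at[1]
        if 0 <= idx < len(out):
            out[idx] = key.alt
    return "".join(out)


def _add_errors(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n = len(seq)
    flips = rng.random(n) < error_rate
    if not flips.any():
        return seq
    out = list(seq)
    for i in np.nonzero(flips)[0]:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)
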