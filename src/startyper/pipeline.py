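"""End-to-end genotyping: depth -> paralog CN -> small variants -> diplotype."""
from __future__ import annotations

from dataclasses import dataclass

from . import depth_cn, paralog_cn, small_variants, star_caller
from .depth_cn import GenomeBaseline, TotalCNCall
from .paralog_cn import SegmentProfile, SVCall, SiteCN
from .resources import (AlleleTable, DifferentiatingSite, RegionModel,
                        load_allele_definitions, load_region_model,
                        load_site_panel)
from .small_variants import VariantCall, VariantSupport
from .star_caller import DiplotypeCall, PhenotypeCall


@dataclass
class SampleResult:
    total_cn: TotalCNCall
    site_cns: list
    segments: SegmentProfile | None
    sv: SVCall | None
    variant_calls: dict                     # g_label -> VariantCall
    diplotype: DiplotypeCall
    phenotype: PhenotypeCall

    @property
    def genotype(self) -> str | None:
        return self.diplotype.genotype

    def to_json_dict(self) -> dict:
        vc = {g: {"cn_alt": c.cn_alt, "posterior": round(c.posterior, 6)}
              for g, c in self.variant_calls.items()
              if c.cn_alt not in (0,)}
        return {
            "schema_version": "1",
            "genotype": self.genotype,
            "filter": self.diplotype.filter,
            "alternatives": list(self.diplotype.alternatives),
            "phenotype": {"activity_score": self.phenotype.activity_score_sum,
                          "category": self.phenotype.category},
            "cn_total": self.total_cn.cn_total,
            "cn_spacer": self.total_cn.cn_spacer,
            "normalized_depth_total":
                None if self.total_cn.depth_total is None
                else round(self.total_cn.depth_total.value, 4),
            "normalized_depth_spacer":
                None if self.total_cn.depth_spacer is None
                else round(self.total_cn.depth_spacer.value, 4),
            "segments": None if self.segments is None else self.segments.cn,
            "sv": None if self.sv is None else {
                "full_d6": self.sv.cn_full_d6, "full_d7": self.sv.cn_full_d7,
                "d6_d7_hybrids": list(self.sv.d6_d7_hybrids),
                "d7_d6_hybrids": list(self.sv.d7_d6_hybrids),
                "no_call": self.sv.no_call},
            "variants": vc,
            "diagnostic": self.diplotype.diagnostic,
        }


def _no_call_result(total: TotalCNCall, reason: str) -> SampleResult:
    return SampleResult(
        total_cn=total, site_cns=[], segments=None, sv=None, variant_calls={},
        diplotype=DiplotypeCall(None, None, "no_call", diagnostic=reason),
        phenotype=PhenotypeCall(None, "indeterminate"))


def _spacer_candidates(total: TotalCNCall) -> list[int]:
    """Spacer CN values to attempt.  A confidently called spacer is final;
    an indecisive one (posterior below threshold) is rescued by trying its
    maximum-likelihood neighbourhood — the segment profile's 3' anchor
    (CN(total) - CN(spacer) must equal the 3'-most segment consensus)
    almost always singles out one value, and the diplotype is accepted only
    when the surviving candidates agree."""
    if total.cn_spacer is not None:
        return [total.cn_spacer]
    ml = total.ml_spacer
    if ml is None:
        return []
    cands = [ml, ml - 1, ml + 1]
    return [c for c in cands if 0 <= c <= (total.cn_total or 0)]


def _pooled_segment_counts(site_support, site_cns, panel,
                           multiplicity: dict | float) -> dict:
    """Effective (n_d6, n_total) read counts per segment: pooled over
    depth-informative sites, deflated by the read-sharing multiplicity."""
    seg_of = {s.site_id: s.segment for s in panel}
    informative = {sc.site_id for sc in site_cns if sc.ml_cn is not None}
    pooled = {seg: [0, 0] for seg in paralog_cn.SEGMENT_ORDER}
    for su in site_support:
        if su.site_id in informative:
            acc = pooled[seg_of[su.site_id]]
            acc[0] += su.n_d6
            acc[1] += su.n_d6 + su.n_d7
    out = {}
    for seg, (n6, n) in pooled.items():
        m = multiplicity.get(seg, 1.0) if isinstance(multiplicity, dict) \
            else float(multiplicity)
        out[seg] = (int(round(n6 / m)), int(round(n / m)))
    return out


def _finish(total: TotalCNCall, site_support, variant_support_fn,
            panel, defs: AlleleTable,
            site_multiplicity: dict | float = 1.0) -> SampleResult:
    """Shared tail of both entry points once depth evidence is in hand."""
    if total.cn_total is None:
        return _no_call_result(total, "total CN no-call")
    spacer_cands = _spacer_candidates(total)
    if not spacer_cands:
        return _no_call_result(total, "spacer CN no-call")
    site_cns = [paralog_cn.call_site_cn(s, total.cn_total)
                for s in site_support]
    segments = paralog_cn.consensus_segments(site_cns, panel, site_support,
                                             total.cn_total,
                                             multiplicity=site_multiplicity)
    seg_counts = _pooled_segment_counts(site_support, site_cns, panel,
                                        site_multiplicity)
    # variant evidence does not depend on the spacer CN
    first_sv = paralog_cn.detect_sv_from_counts(seg_counts, total.cn_total,
                                                spacer_cands[0])
    var_profile = segments if first_sv.no_call else SegmentProfile(
        cn=dict(zip(paralog_cn.SEGMENT_ORDER,
                    paralog_cn._structure_profile(
                        first_sv.cn_full_d6, first_sv.d6_d7_hybrids,
                        first_sv.d7_d6_hybrids))),
        n_sites=segments.n_sites, agreement=segments.agreement)
    variant_calls: dict[str, VariantCall] = {}
    variant_evidence: dict[str, tuple] = {}
    for g_label in sorted(defs.variants):
        support = variant_support_fn(defs.variants[g_label], var_profile)
        variant_calls[g_label] = small_variants.call_variant_cn(support)
        variant_evidence[g_label] = (support.n_alt, support.n_ref,
                                     support.site_total_cn)
    variant_cns = {g: c.cn_alt for g, c in variant_calls.items()}

    resolved: list[tuple[int, "paralog_cn.SVCall", DiplotypeCall]] = []
    sv_last = first_sv
    for cand in spacer_cands:
        sv = first_sv if cand == spacer_cands[0] else \
            paralog_cn.detect_sv_from_counts(seg_counts, total.cn_total, cand)
        sv_last = sv
        diplo = star_caller.resolve_diplotype(sv, variant_cns, defs,
                                              variant_evidence)
        if diplo.genotype is not None:
            resolved.append((cand, sv, diplo))
    if not resolved:
        diplo = star_caller.resolve_diplotype(sv_last, variant_cns, defs,
                                              variant_evidence)
        pheno = star_caller.translate_phenotype(diplo, defs)
        return SampleResult(total_cn=total, site_cns=site_cns,
                            segments=segments, sv=sv_last,
                            variant_calls=variant_calls, diplotype=diplo,
                            phenotype=pheno)
    genotypes = {d.genotype for _c, _s, d in resolved}
    if len(genotypes) > 1:
        diplo = DiplotypeCall(
            None, None, "no_call",
            diagnostic="indecisive spacer CN admits conflicting genotypes: "
                       + "; ".join(sorted(genotypes)))
        pheno = star_caller.translate_phenotype(diplo, defs)
        return SampleResult(total_cn=total, site_cns=site_cns,
                            segments=segments, sv=resolved[0][1],
                            variant_calls=variant_calls, diplotype=diplo,
                            phenotype=pheno)
    cand, sv, diplo = resolved[0]
    pheno = star_caller.translate_phenotype(diplo, defs)
    return SampleResult(total_cn=total, site_cns=site_cns, segments=segments,
                        sv=diplo.sv_used or sv, variant_calls=variant_calls,
                        diplotype=diplo, phenotype=pheno)


def call_from_counts(bundle, model: RegionModel | None = None,
                     panel: list[DifferentiatingSite] | None = None,
                     defs: AlleleTable | None = None) -> SampleResult:
    """Genotype a counts-level evidence bundle (simulator or external)."""
    model = model or load_region_model(bundle.build)
    panel = panel or load_site_panel(bundle.build)
    defs = defs or load_allele_definitions(bundle.build, model)
    total = depth_cn.call_total_and_spacer_from_counts(
        bundle.d6d7_count, bundle.spacer_count, bundle.read_length,
        model, bundle.baseline, bundle.gc_d6d7, bundle.gc_spacer)

    def variant_support(key, segments):
        n_alt, n_ref = bundle.variant_counts.get(key.g_label, (0, 0))
        return VariantSupport(
            key=key, n_alt=n_alt, n_ref=n_ref,
            site_total_cn=small_variants.site_total_cn_for(key, segments))

    return _finish(total, bundle.site_support, variant_support, panel, defs)


def call_from_bam(bam_path: str, model: RegionModel,
                  baseline_regions: list[tuple[str, int, int]],
                  panel: list[DifferentiatingSite] | None = None,
                  defs: AlleleTable | None = None,
                  read_length: float = 150.0) -> SampleResult:
    """Genotype an indexed BAM/CRAM given a region model and a panel of
    diploid baseline regions (counted from the same file)."""
    import numpy as np
    import pysam

    panel = panel or load_site_panel(model.build)
    defs = defs or load_allele_definitions(model.build, model)
    with pysam.AlignmentFile(bam_path) as aln:
        depths = []
        for chrom, start, end in baseline_regions:
            c = depth_cn.count_region_reads(aln, chrom, start, end)
            depths.append(c * read_length / (end - start + 1))
        baseline = GenomeBaseline(depths=np.asarray(depths),
                                  gc=np.full(len(depths), 0.5))
        total = depth_cn.call_total_and_spacer(aln, model, baseline,
                                               read_length)
        site_support = paralog_cn.gather_site_support(aln, panel, model)

        def variant_support(key, segments):
            return small_variants.collect_variant_support(
                aln, key, model, segments)

        return _finish(total, site_support, variant_support, panel, defs,
                       paralog_cn.site_multiplicity(panel, read_length))
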