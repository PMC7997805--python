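"""Packaged, build-aware resource tables.

Everything downstream consumes the three tables loaded here:

* a :class:`RegionModel` with the chr22 coordinates of CYP2D6, CYP2D7, the
  REP6/REP7 repeats and the unique spacer, per reference build;
* the panel of 117 CYP2D6/CYP2D7 differentiating sites used to apportion
  reads between the two paralogs;
* the star-allele definition table (small variants, structural requirement,
  CPIC activity score and clinical function per allele).

All coordinates are 1-based inclusive (VCF/samtools convention).  The site
panel and allele table are versioned synthetic curated resources shipped with
the package; they follow the PharmVar-style schema but are not derived from
genome sequence at runtime.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Iterable

import pandas as pd

SUPPORTED_BUILDS = ("GRCh37", "GRCh38")

#: canonical 3'->5' segment order along CYP2D6 (exon 9 sits at the low
#: genomic coordinate end; the gene is on the minus strand)
SEGMENT_ORDER = (
    "3p_flank", "exon9", "exon8", "exon7", "exon6", "exon5",
    "exon4", "exon3", "exon2", "exon1", "5p_flank",
)
SEGMENT_INDEX = {name: i for i, name in enumerate(SEGMENT_ORDER)}


class ResourceError(ValueError):
    """A packaged resource table failed an integrity check."""


def _data_path(name: str):
    return _ilres.files("startyper.data").joinpath(name)


# --------------------------------------------------------------------------
# region model
# --------------------------------------------------------------------------

Interval = tuple[int, int]


@dataclass(frozen=True)
class RegionModel:
    """Genomic coordinates of the CYP2D6/CYP2D7 locus for one build."""

    build: str
    chrom: str
    d6_span: Interval
    d7_span: Interval
    rep6_span: Interval
    rep7_span: Interval
    spacer_span: Interval
    d6_exons: tuple[Interval, ...]   # exon 1..9, genomic intervals
    d7_exons: tuple[Interval, ...]
    homology_regions: tuple[Interval, ...]

    @property
    def d6_length(self) -> int:
        return self.d6_span[1] - self.d6_span[0] + 1

    @property
    def spacer_length(self) -> int:
        return self.spacer_span[1] - self.spacer_span[0] + 1

    @property
    def d7_offset(self) -> int:
        """Constant shift mapping a CYP2D6 position onto its CYP2D7 mirror."""
        return self.d7_span[0] - self.d6_span[0]

    def g_to_pos(self, g: int) -> int:
        """Gene-relative coordinate (g.1 = 5' end, minus strand) -> genomic."""
        return self.d6_span[1] - g + 1

    def pos_to_g(self, pos: int) -> int:
        return self.d6_span[1] - pos + 1

    def in_homology_region(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.homology_regions)

    def segment_of_g(self, g: int) -> str:
        """Assign a gene-relative position to an exon-anchored segment.

        Segment boundaries sit at intron midpoints; positions 5' of exon 1
        map to the 5' flank, positions 3' of exon 9 to the 3' flank.
        """
        exons_g = [(self.pos_to_g(hi), self.pos_to_g(lo)) for lo, hi in self.d6_exons]
        if g < exons_g[0][0]:
            return "5p_flank"
        for i in range(9):
            hi = exons_g[i][1]
            nxt = exons_g[i + 1][0] if i < 8 else None
            if nxt is None:
                gene_end = self.pos_to_g(self.d6_span[0])
                bound = (hi + gene_end) / 2
                return f"exon{i + 1}" if g <= bound else "3p_flank"
            if g <= (hi + nxt) / 2:
                return f"exon{i + 1}"
        return "3p_flank"  # pragma: no cover


def _iv(x: Iterable[int]) -> Interval:
    a, b = x
    if not (isinstance(a, int) and isinstance(b, int) and a <= b):
        raise ResourceError(f"malformed interval {x!r}")
    return (a, b)


def load_region_model(build: str = "GRCh38") -> RegionModel:
    """Load and validate the coordinate model for ``build``.

    Raises :class:`ResourceError` for an unsupported build or a model that
    fails its structural invariants.
    """
    if build not in SUPPORTED_BUILDS:
        raise ResourceError(
            f"unknown reference build {build!r}; supported: {SUPPORTED_BUILDS}")
    with _data_path("region_model.json").open() as fh:
        raw = json.load(fh)[build]
    model = RegionModel(
        build=build,
        chrom=raw["chrom"],
        d6_span=_iv(raw["d6_span"]),
        d7_span=_iv(raw["d7_span"]),
        rep6_span=_iv(raw["rep6_span"]),
        rep7_span=_iv(raw["rep7_span"]),
        spacer_span=_iv(raw["spacer_span"]),
        d6_exons=tuple(_iv(raw["d6_exons"][str(i)]) for i in range(1, 10)),
        d7_exons=tuple(_iv(raw["d7_exons"][str(i)]) for i in range(1, 10)),
        homology_regions=tuple(_iv(x) for x in raw["homology_regions"]),
    )
    _validate_region_model(model)
    return model


def _validate_region_model(m: RegionModel) -> None:
    if len(m.d6_exons) != 9 or len(m.d7_exons) != 9:
        raise ResourceError("expected exactly 9 exons per gene")
    for ex in m.d6_exons:
        if not (m.d6_span[0] <= ex[0] and ex[1] <= m.d6_span[1]):
            raise ResourceError(f"CYP2D6 exon {ex} outside gene span")
    for ex in m.d7_exons:
        if not (m.d7_span[0] <= ex[0] and ex[1] <= m.d7_span[1]):
            raise ResourceError(f"CYP2D7 exon {ex} outside gene span")
    for hr in m.homology_regions:
        if not (m.d6_span[0] <= hr[0] and hr[1] <= m.d6_span[1]):
            raise ResourceError("homology region outside CYP2D6 span")
    # spans pairwise non-overlapping; adjacent spans may share one boundary
    # base (the printed REP7 and spacer intervals abut at a common position)
    spans = [m.d6_span, m.d7_span, m.rep6_span, m.rep7_span, m.spacer_span]
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            lo = max(spans[i][0], spans[j][0])
            hi = min(spans[i][1], spans[j][1])
            if hi - lo >= 1:
                raise ResourceError(f"spans overlap: {spans[i]} vs {spans[j]}")


# --------------------------------------------------------------------------
# differentiating-site panel
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentiatingSite:
    site_id: int
    d6_pos: int
    d7_pos: int
    d6_base: str
    d7_base: str
    segment: str


def load_site_panel(build: str = "GRCh38") -> list[DifferentiatingSite]:
    """Load the 117-site CYP2D6/CYP2D7 differentiating panel for ``build``."""
    if build not in SUPPORTED_BUILDS:
        raise ResourceError(f"unknown reference build {build!r}")
    suff = build.lower().replace("grch", "grch")
    df = pd.read_csv(_data_path("differentiating_sites.tsv").open(), sep="\t")
    col6 = f"d6_pos_{build.lower()}"
    col7 = f"d7_pos_{build.lower()}"
    sites = [
        DifferentiatingSite(
            site_id=int(r.site_id), d6_pos=int(getattr(r, col6)),
            d7_pos=int(getattr(r, col7)), d6_base=str(r.d6_base),
            d7_base=str(r.d7_base), segment=str(r.segment))
        for r in df.itertuples()
    ]
    _validate_site_panel(sites)
    return sites


def _validate_site_panel(sites: list[DifferentiatingSite]) -> None:
    if len(sites) != 117:
        raise ResourceError(f"site panel has {len(sites)} sites, expected 117")
    pos = [s.d6_pos for s in sites]
    if pos != sorted(pos) or len(set(pos)) != len(pos):
        raise ResourceError("site panel not strictly increasing along CYP2D6")
    per_seg: dict[str, int] = {}
    for s in sites:
        if s.d6_base == s.d7_base:
            raise ResourceError(f"site {s.site_id}: identical base pair")
        if s.segment not in SEGMENT_INDEX:
            raise ResourceError(f"site {s.site_id}: unknown segment {s.segment!r}")
        per_seg[s.segment] = per_seg.get(s.segment, 0) + 1
    missing = [seg for seg in SEGMENT_ORDER if per_seg.get(seg, 0) < 3]
    if missing:
        raise ResourceError(f"segments with <3 sites: {missing}")


# --------------------------------------------------------------------------
# variant catalogue and star-allele definitions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantKey:
    """A star-allele-defining small variant in CYP2D6 gene numbering."""

    g_label: str               # e.g. "g.100C>T" (primary key)
    g_pos: int                 # gene-relative position of the first base
    ref: str
    alt: str
    kind: str                  # snv | ins | del
    d6_pos: int                # genomic position in the loaded build
    segment: str               # exon-anchored segment containing the variant
    in_homology_region: bool
    d7_mirror_pos: int | None  # set iff in_homology_region


@dataclass(frozen=True)
class StructuralUnit:
    """Structural identity of one gene unit at the CYP2D6 locus.

    ``kind``:
      * ``full_d6`` — an intact CYP2D6 gene;
      * ``d6_d7`` — a CYP2D6-CYP2D7 fusion, CYP2D6-derived through exon
        ``through_exon`` (5' side), CYP2D7-derived 3' of it (carries a spacer);
      * ``d7_d6`` — CYP2D7-derived 5' of exon ``from_exon``, CYP2D6-derived
        from it onward.  ``fused=True`` marks a deletion-fusion product whose
        chromosome lost the separate CYP2D7 and spacer (*13 class);
        ``fused=False`` a conversion-type allele that retains them (*4.013).
    """

    kind: str
    through_exon: int | None = None
    from_exon: int | None = None
    fused: bool = False

    def d6_segments(self) -> frozenset[str]:
        """Segments at which this unit carries CYP2D6-derived sequence."""
        if self.kind == "full_d6":
            return frozenset(SEGMENT_ORDER)
        if self.kind == "d6_d7":
            k = SEGMENT_INDEX[f"exon{self.through_exon}"]
            return frozenset(SEGMENT_ORDER[k:])
        k = SEGMENT_INDEX[f"exon{self.from_exon}"]
        return frozenset(SEGMENT_ORDER[: k + 1])

    @property
    def has_own_spacer(self) -> bool:
        """True when the unit's 3' end is CYP2D7-derived (adds a spacer copy)."""
        return self.kind == "d6_d7"


FULL_D6 = StructuralUnit("full_d6")


@dataclass(frozen=True)
class StarAlleleDefinition:
    name: str
    defining_variants: frozenset[str]     # g_labels
    sv_requirement: str                   # none | gene_deletion | d6_d7_hybrid | d7_d6_hybrid
    structure: StructuralUnit | None      # None for the *5 deletion allele
    activity_score: float | None
    function: str
    validated: bool

    @property
    def is_deletion(self) -> bool:
        return self.sv_requirement == "gene_deletion"


@dataclass(frozen=True)
class AlleleTable:
    alleles: dict[str, StarAlleleDefinition]
    variants: dict[str, VariantKey]
    tandems: tuple[tuple[str, ...], ...]   # conventional tandem arrangements

    def __getitem__(self, name: str) -> StarAlleleDefinition:
        return self.alleles[name]

    def variant_alleles(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {v: [] for v in self.variants}
        for a in self.alleles.values():
            for v in a.defining_variants:
                out[v].append(a.name)
        return out


def load_variant_catalogue(model: RegionModel) -> dict[str, VariantKey]:
    df = pd.read_csv(_data_path("variant_catalogue.tsv").open(), sep="\t")
    out: dict[str, VariantKey] = {}
    for r in df.itertuples():
        g = int(r.g_pos)
        pos = model.g_to_pos(g)
        hom = model.in_homology_region(pos)
        out[str(r.g_label)] = VariantKey(
            g_label=str(r.g_label), g_pos=g, ref=str(r.ref), alt=str(r.alt),
            kind=str(r.kind), d6_pos=pos, segment=model.segment_of_g(g),
            in_homology_region=hom,
            d7_mirror_pos=pos + model.d7_offset if hom else None)
    return out


def _structure_from_sv(sv) -> tuple[str, StructuralUnit | None]:
    if sv == "none":
        return "none", FULL_D6
    if sv == "deletion":
        return "gene_deletion", None
    if sv["type"] == "d6_d7":
        return "d6_d7_hybrid", StructuralUnit("d6_d7", through_exon=int(sv["d6_through_exon"]))
    if sv["type"] == "d7_d6":
        return "d7_d6_hybrid", StructuralUnit(
            "d7_d6", from_exon=int(sv["d6_from_exon"]), fused=bool(sv["fused"]))
    raise ResourceError(f"unknown sv requirement {sv!r}")


def load_allele_definitions(build: str = "GRCh38",
                            model: RegionModel | None = None) -> AlleleTable:
    """Load star-allele definitions plus the variant catalogue they reference."""
    model = model or load_region_model(build)
    variants = load_variant_catalogue(model)
    with _data_path("star_alleles.json").open() as fh:
        raw = json.load(fh)
    alleles: dict[str, StarAlleleDefinition] = {}
    for a in raw["alleles"]:
        name = a["name"]
        if name in alleles:
            raise ResourceError(f"duplicate allele name {name}")
        for v in a["variants"]:
            if v not in variants:
                raise ResourceError(f"{name}: dangling variant key {v}")
        sv_req, structure = _structure_from_sv(a["sv"])
        score = a["activity_score"]
        alleles[name] = StarAlleleDefinition(
            name=name, defining_variants=frozenset(a["variants"]),
            sv_requirement=sv_req, structure=structure,
            activity_score=float(score) if score is not None else None,
            function=a["function"], validated=bool(a["validated"]))
    if "*1" not in alleles or alleles["*1"].defining_variants:
        raise ResourceError("*1 must exist with an empty defining-variant set")
    return AlleleTable(alleles=alleles, variants=variants,
                       tandems=tuple(tuple(t) for t in raw["tandems"]))
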