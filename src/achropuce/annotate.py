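"""Evidence gathering: decorate a CNV with gene content, reference matches,
morbidity-map enrichment and a recurrent-CNV (PIEV) catalog match.

The annotator is pure plumbing between the reference bundle and the
criteria registry: it applies the comparability rule to every stored match
and never mutates its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Mapping, Optional, Sequence, Tuple

from .core import (
    BuildMismatchError,
    CNVRecord,
    CNVType,
    GeneAnnotation,
    GenomicInterval,
    MorbidityRegion,
    PIEVEntry,
)
from .io_formats import ReferenceBundle
from .overlap import OverlapMatch, is_comparable, mark_comparable, reciprocal_overlap

#: Default reciprocal-overlap threshold for morbidity-map and PIEV matching.
DEFAULT_MIN_OVERLAP = 0.70


class MorbidityCall(str, Enum):
    ENRICHED_IN_CASES = "ENRICHED_IN_CASES"
    NOT_ENRICHED = "NOT_ENRICHED"
    NO_DATA = "NO_DATA"


@dataclass(frozen=True)
class AnnotatedCNV:
    """A CNV plus every piece of evidence the criteria registry consumes."""

    cnv: CNVRecord
    gene_hits: tuple  # ((GeneAnnotation, impacted_exon_count), ...)
    control_matches: tuple  # comparable OverlapMatch only
    patient_matches: tuple
    syndrome_matches: tuple
    morbidity: MorbidityCall = MorbidityCall.NO_DATA
    morbidity_frequencies: Optional[Tuple[float, float]] = None  # (case, control)
    piev_match: Optional[Tuple[PIEVEntry, float]] = None
    has_gene_data: bool = True  # bundle carried gene annotation at all


def impacted_exons(cnv_iv: GenomicInterval, gene: GeneAnnotation) -> int:
    """Number of the gene's exons intersecting the CNV by at least 1 bp."""
    return sum(1 for ex in gene.exons if cnv_iv.intersection_bp(ex) >= 1)


def deletes_5prime_of_HI_gene(cnv: CNVRecord, gene: GeneAnnotation) -> bool:
    """True when a deletion removes the strand-aware 5' terminus of a
    haploinsufficient gene together with at least one coding exon."""
    if cnv.cnv_type is not CNVType.LOSS or not gene.is_haploinsufficient:
        return False
    iv = cnv.interval
    if iv.chrom != gene.interval.chrom:
        return False
    if not iv.contains_position(gene.five_prime_position):
        return False
    return impacted_exons(iv, gene) >= 1


def best_morbidity_region(
    cnv: CNVRecord,
    regions: Sequence[MorbidityRegion],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> Optional[MorbidityRegion]:
    """Best same-type morbidity region with reciprocal overlap >= threshold."""
    best: Optional[MorbidityRegion] = None
    best_ro = 0.0
    for region in regions:
        if region.cnv_type is not cnv.cnv_type:
            continue
        ro = reciprocal_overlap(cnv.interval, region.interval)
        if ro >= min_overlap and ro > best_ro:
            best, best_ro = region, ro
    return best


def morbidity_comparison(
    cnv: CNVRecord,
    regions: Sequence[MorbidityRegion],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> MorbidityCall:
    """Plain frequency comparison on the best-matching morbidity region.

    Enrichment means case frequency strictly above control frequency; a tie
    is not enrichment.  No region at the overlap threshold means no call.
    """
    region = best_morbidity_region(cnv, regions, min_overlap)
    if region is None:
        return MorbidityCall.NO_DATA
    if region.case_frequency > region.control_frequency:
        return MorbidityCall.ENRICHED_IN_CASES
    return MorbidityCall.NOT_ENRICHED


def match_piev(
    cnv: CNVRecord,
    catalog: Sequence[PIEVEntry],
    gene_by_symbol: Mapping[str, GeneAnnotation],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> Optional[Tuple[PIEVEntry, float]]:
    """Match a CNV against the recurrent-CNV catalog.

    An entry matches when its type is compatible, the reciprocal overlap
    with the tolerance-expanded region reaches the threshold, and every
    catalog candidate gene lies fully inside the CNV (vacuous for entries
    without candidate genes; a symbol absent from the gene annotation fails
    containment).  The best overlap wins, ties broken by name.
    """
    best: Optional[Tuple[PIEVEntry, float]] = None
    for entry in sorted(catalog, key=lambda e: e.name):
        if not entry.accepts_type(cnv.cnv_type):
            continue
        region = entry.region.expanded(entry.breakpoint_tolerance_bp)
        ro = reciprocal_overlap(cnv.interval, region)
        if ro < min_overlap:
            continue
        contained = True
        for symbol in entry.candidate_genes:
            gene = gene_by_symbol.get(symbol)
            if gene is None or not cnv.interval.contains(gene.interval):
                contained = False
                break
        if not contained:
            continue
        if best is None or ro > best[1]:
            best = (entry, ro)
    return best


def _comparable_matches(
    cnv: CNVRecord,
    matches: Sequence[OverlapMatch],
    bundle: ReferenceBundle,
    query_gene_symbols: frozenset,
) -> tuple:
    kept = []
    for m in matches:
        ref_genes = {g.symbol for g in bundle.genes_overlapping(m.reference.interval)}
        shared = len(ref_genes & query_gene_symbols)
        if is_comparable(cnv, m.reference, shared):
            kept.append(mark_comparable(m, True))
    return tuple(kept)


def annotate(
    cnv: CNVRecord,
    bundle: ReferenceBundle,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> AnnotatedCNV:
    """Gather all evidence for one CNV from a build-consistent bundle.

    Control/patient/syndrome matches are same-type and comparability
    filtered; the morbidity call uses the best region at ``min_overlap``;
    the PIEV match honors per-entry breakpoint tolerance.
    """
    if cnv.genome_build is not bundle.genome_build:
        raise BuildMismatchError(
            f"query build {cnv.genome_build.value} != bundle build "
            f"{bundle.genome_build.value}"
        )
    iv = cnv.interval
    gene_hits = tuple(
        (g, impacted_exons(iv, g)) for g in bundle.genes_overlapping(iv)
    )
    query_symbols = frozenset(g.symbol for g, _ in gene_hits)

    control = _comparable_matches(
        cnv, bundle.control_index.query(iv, cnv.cnv_type), bundle, query_symbols
    )
    patient = _comparable_matches(
        cnv, bundle.patient_index.query(iv, cnv.cnv_type), bundle, query_symbols
    )
    syndrome = _comparable_matches(
        cnv, bundle.syndrome_index.query(iv, cnv.cnv_type), bundle, query_symbols
    )

    region = best_morbidity_region(cnv, bundle.morbidity, min_overlap)
    call = morbidity_comparison(cnv, bundle.morbidity, min_overlap)
    freqs = None if region is None else (region.case_frequency, region.control_frequency)

    piev = match_piev(cnv, bundle.piev, bundle.gene_by_symbol, min_overlap)

    return AnnotatedCNV(
        cnv=cnv,
        gene_hits=gene_hits,
        control_matches=control,
        patient_matches=patient,
        syndrome_matches=syndrome,
        morbidity=call,
        morbidity_frequencies=freqs,
        piev_match=piev,
        has_gene_data=bundle.has_gene_data,
    )
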