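"""Reciprocal-overlap arithmetic, comparability filtering and the interval
index used for reference lookups.

The similarity measure is the reciprocal overlap

    RO(a, b) = 2 * |a ∩ b| / (len(a) + len(b))

which is symmetric, lies in [0, 1] and equals 1 exactly when the two
intervals coincide.  Variants differing by more than 30% in size *and*
sharing no gene content are considered non-comparable and excluded from
evidence gathering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

from intervaltree import IntervalTree

from .core import CNVRecord, CNVType, GenomicInterval, ReferenceVariant

#: Relative size difference above which two variants with no shared gene
#: content stop being comparable (strict inequality).
SIZE_DIFFERENCE_LIMIT = 0.30


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap fraction: twice the intersection divided by the sum
    of both lengths.  0 for different chromosomes or disjoint spans; 1 iff
    the intervals are identical."""
    inter = a.intersection_bp(b)
    if inter == 0:
        return 0.0
    return 2.0 * inter / (a.length + b.length)


def size_difference(a: GenomicInterval, b: GenomicInterval) -> float:
    """Relative length difference ``|len(a) - len(b)| / max(len(a), len(b))``.

    Symmetric, in [0, 1); 0 exactly for equal lengths.  The larger variant is
    the denominator so the measure stays bounded.
    """
    la, lb = a.length, b.length
    return abs(la - lb) / max(la, lb)


def is_comparable(
    query: CNVRecord, ref: ReferenceVariant, shared_gene_count: int
) -> bool:
    """Comparability rule: a pair is excluded exactly when the size
    difference exceeds 30% AND the two footprints share no gene.  A strict
    conjunction — either condition alone keeps the pair."""
    return not (
        size_difference(query.interval, ref.interval) > SIZE_DIFFERENCE_LIMIT
        and shared_gene_count == 0
    )


@dataclass(frozen=True)
class OverlapMatch:
    """A reference variant overlapping a query, with its similarity."""

    reference: ReferenceVariant
    overlap_fraction: float
    intersection_bp: int
    comparable: bool = True


class IntervalIndex:
    """Per-chromosome interval tree over reference variants.

    Queries return every entry intersecting the probe interval by at least
    1 bp, sorted by descending overlap fraction (ties broken by identifier).
    """

    def __init__(self, variants: Sequence[ReferenceVariant] = ()):
        self._trees: Dict[str, IntervalTree] = {}
        self._n = 0
        for v in variants:
            self.add(v)

    def add(self, variant: ReferenceVariant) -> None:
        tree = self._trees.setdefault(variant.interval.chrom, IntervalTree())
        tree.addi(variant.interval.start, variant.interval.end, variant)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(
        self, iv: GenomicInterval, type_filter: Optional[CNVType] = None
    ) -> List[OverlapMatch]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        out: List[OverlapMatch] = []
        for node in tree.overlap(iv.start, iv.end):
            ref: ReferenceVariant = node.data
            if type_filter is not None and ref.cnv_type is not type_filter:
                continue
            inter = iv.intersection_bp(ref.interval)
            if inter >= 1:
                out.append(
                    OverlapMatch(
                        reference=ref,
                        overlap_fraction=reciprocal_overlap(iv, ref.interval),
                        intersection_bp=inter,
                    )
                )
        out.sort(key=lambda m: (-m.overlap_fraction, m.reference.identifier))
        return out


def build_index(variants: Sequence[ReferenceVariant]) -> IntervalIndex:
    return IntervalIndex(variants)


def query_index(
    index: IntervalIndex, iv: GenomicInterval, type_filter: Optional[CNVType] = None
) -> List[OverlapMatch]:
    return index.query(iv, type_filter)


def mark_comparable(match: OverlapMatch, comparable: bool) -> OverlapMatch:
    return replace(match, comparable=comparable)
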