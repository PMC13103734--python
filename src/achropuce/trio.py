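"""Batch orchestration and trio-based exclusion of inherited variants."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

from .annotate import annotate
from .classifier import CriteriaConfig, DEFAULT_CONFIG, classify
from .core import (
    BuildMismatchError,
    CNVRecord,
    ClassificationResult,
    Inheritance,
    InputError,
)
from .io_formats import ReferenceBundle
from .overlap import OverlapMatch, reciprocal_overlap

logger = logging.getLogger(__name__)

DEFAULT_TRIO_OVERLAP = 0.70
DEFAULT_BATCH_LIMIT = 300


@dataclass(frozen=True)
class TrioInput:
    """Proband plus both parental CNV lists."""

    proband: Tuple[CNVRecord, ...]
    mother: Tuple[CNVRecord, ...] = ()
    father: Tuple[CNVRecord, ...] = ()
    match_overlap: float = DEFAULT_TRIO_OVERLAP

    def __post_init__(self) -> None:
        object.__setattr__(self, "proband", tuple(self.proband))
        object.__setattr__(self, "mother", tuple(self.mother))
        object.__setattr__(self, "father", tuple(self.father))
        if not (0.0 < self.match_overlap <= 1.0):
            raise InputError("match_overlap must lie in (0, 1]")
        builds = {c.genome_build for c in self.proband + self.mother + self.father}
        if len(builds) > 1:
            raise BuildMismatchError(
                f"trio mixes genome builds: {sorted(b.value for b in builds)}"
            )


@dataclass(frozen=True)
class ExcludedCNV:
    cnv: CNVRecord
    parent: str  # "mother" | "father"
    match: OverlapMatch


def exclude_inherited(
    t: TrioInput, assume_de_novo: bool = False
) -> Tuple[List[CNVRecord], List[ExcludedCNV]]:
    """Partition proband CNVs into retained and parentally-matched.

    A proband CNV is excluded when a parental CNV of the same type on the
    same chromosome reaches ``match_overlap`` reciprocal overlap.  Retained
    records keep UNKNOWN inheritance unless ``assume_de_novo`` explicitly
    promotes them (parental call sets may be incomplete, so promotion is
    opt-in).  The partition is exhaustive and disjoint.
    """
    retained: List[CNVRecord] = []
    excluded: List[ExcludedCNV] = []
    parents = [("mother", t.mother), ("father", t.father)]
    for cnv in t.proband:
        best: Optional[Tuple[str, CNVRecord, float]] = None
        for parent_name, variants in parents:
            for pv in variants:
                if pv.cnv_type is not cnv.cnv_type:
                    continue
                ro = reciprocal_overlap(cnv.interval, pv.interval)
                if ro >= t.match_overlap and (best is None or ro > best[2]):
                    best = (parent_name, pv, ro)
        if best is None:
            if assume_de_novo and cnv.inheritance is Inheritance.UNKNOWN:
                cnv = replace(cnv, inheritance=Inheritance.DE_NOVO)
            retained.append(cnv)
        else:
            parent_name, pv, ro = best
            from .core import ReferenceVariant, RefSource  # local to avoid cycle noise

            excluded.append(
                ExcludedCNV(
                    cnv=cnv,
                    parent=parent_name,
                    match=OverlapMatch(
                        reference=ReferenceVariant(
                            interval=pv.interval,
                            cnv_type=pv.cnv_type,
                            source=RefSource.CONTROL,
                            identifier=f"{parent_name}:{pv.interval}",
                            observation_count=1,
                        ),
                        overlap_fraction=ro,
                        intersection_bp=cnv.interval.intersection_bp(pv.interval),
                    ),
                )
            )
    logger.info("trio exclusion: %d retained, %d inherited", len(retained), len(excluded))
    return retained, excluded


def run_batch(
    cnvs: Sequence[CNVRecord],
    bundle: ReferenceBundle,
    cfg: CriteriaConfig = DEFAULT_CONFIG,
    limit: int = DEFAULT_BATCH_LIMIT,
) -> List[ClassificationResult]:
    """Classify a list of CNVs independently, preserving input order.

    ``limit`` is a chunk size for logging/progress, not a rejection cap;
    results are identical for any chunking.
    """
    if limit < 1:
        raise InputError("batch limit must be >= 1")
    results: List[ClassificationResult] = []
    n_chunks = (len(cnvs) + limit - 1) // limit if cnvs else 0
    for ci in range(n_chunks):
        chunk = cnvs[ci * limit:(ci + 1) * limit]
        logger.info("batch chunk %d/%d (%d CNVs)", ci + 1, n_chunks, len(chunk))
        for cnv in chunk:
            results.append(classify(annotate(cnv, bundle, cfg.piev_min_overlap), cfg))
    return results
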