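"""The weighted-criteria classifier implementing the Achro-Puce scoring
system.

Each automatable criterion carries a signed weight: direct evidence is
worth +/-1 point, a major criterion +/-0.45, a minor criterion +/-0.225,
and the inheritance pattern +/-0.45.  The global score is the plain sum of
fired criteria, and the five-tier class follows from fixed thresholds
evaluated outside-in:

    score >= +1.0  -> class 5 (pathogenic)
    score >= +0.9  -> class 4 (likely pathogenic)
    score <= -1.0  -> class 1 (benign)
    score <= -0.9  -> class 2 (likely benign)
    otherwise      -> class 3 (VUS)

Two major criteria (2 x 0.45 = 0.9), or one major plus two minors
(0.45 + 2 x 0.225 = 0.9), therefore reach a "likely" class exactly — a
designed coincidence of the default weights that the guideline's
qualitative class-4 / class-2 rules rely on.

A CNV matching the recurrent-CNV catalog (PIEV) is classified PIEV
directly, independently of the computed score; the score and criterion
trace are still reported for transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence

from .annotate import AnnotatedCNV, MorbidityCall, deletes_5prime_of_HI_gene
from .core import (
    SCORE_EPS,
    CNVType,
    ClassificationResult,
    CriterionHit,
    InputError,
    PIEV_CLASS,
    Tier,
)

logger = logging.getLogger(__name__)

ALL_CRITERIA = frozenset({
    "P_SYNDROME", "P_FULL_OVERLAP_PATHOGENIC",
    "M_GENE_MORBID", "M_HI_5PRIME_DEL", "M_HOMOZYGOUS_DEL", "M_AMPLIFICATION",
    "m_MORBIDITY_ENRICHED", "m_ABSENT_CONTROLS", "m_PARTIAL_PATHOGENIC",
    "m_SIZE_GT_1MB",
    "B_POLYMORPHISM",
    "MB_CONTROL_80", "MB_NO_GENES",
    "mb_CONTROL_50_80", "mb_MORBIDITY_NOT_ENRICHED", "mb_NO_MORBID_GENE",
    "I_DENOVO", "I_AFFECTED", "I_MOSAIC", "I_ASYMPTOMATIC",
})


@dataclass(frozen=True)
class CriteriaConfig:
    """Weights, thresholds and toggles of the scoring system.

    Defaults are the guideline values; every knob is overridable from a
    YAML/JSON config file.
    """

    weights: Mapping[str, float] = field(default_factory=lambda: {
        "DIRECT": 1.0, "MAJOR": 0.45, "MINOR": 0.225, "INHERITANCE": 0.45,
    })
    threshold_pathogenic: float = 1.0
    threshold_likely_pathogenic: float = 0.9
    threshold_likely_benign: float = -0.9
    threshold_benign: float = -1.0
    control_recurrent_min_count: int = 2
    control_major_overlap: float = 0.80
    control_minor_overlap_low: float = 0.50
    size_major_threshold_bp: int = 1_000_000
    piev_min_overlap: float = 0.70
    polymorphism_frequency: float = 0.01
    enabled_criteria: FrozenSet[str] = ALL_CRITERIA

    def __post_init__(self) -> None:
        if not (
            self.threshold_pathogenic >= self.threshold_likely_pathogenic > 0
            > self.threshold_likely_benign >= self.threshold_benign
        ):
            raise InputError("class thresholds must satisfy p >= lp > 0 > lb >= b")
        unknown = set(self.enabled_criteria) - ALL_CRITERIA
        if unknown:
            raise InputError(f"unknown criterion id(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "CriteriaConfig":
        kwargs = {}
        for key in (
            "threshold_pathogenic", "threshold_likely_pathogenic",
            "threshold_likely_benign", "threshold_benign",
            "control_recurrent_min_count", "control_major_overlap",
            "control_minor_overlap_low", "size_major_threshold_bp",
            "piev_min_overlap", "polymorphism_frequency",
        ):
            if key in data:
                kwargs[key] = data[key]
        if "weights" in data:
            merged = {"DIRECT": 1.0, "MAJOR": 0.45, "MINOR": 0.225, "INHERITANCE": 0.45}
            merged.update({k.upper(): float(v) for k, v in data["weights"].items()})
            kwargs["weights"] = merged
        if "enabled_criteria" in data:
            kwargs["enabled_criteria"] = frozenset(data["enabled_criteria"])
        return cls(**kwargs)

    def weight_for(self, tier: Tier) -> float:
        """Unsigned magnitude for a tier."""
        if tier in (Tier.DIRECT_PATHOGENIC, Tier.DIRECT_BENIGN):
            return self.weights["DIRECT"]
        if tier in (Tier.MAJOR_PATHOGENIC, Tier.MAJOR_BENIGN):
            return self.weights["MAJOR"]
        if tier in (Tier.MINOR_PATHOGENIC, Tier.MINOR_BENIGN):
            return self.weights["MINOR"]
        return self.weights["INHERITANCE"]


DEFAULT_CONFIG = CriteriaConfig()


def _hit(cfg: CriteriaConfig, cid: str, tier: Tier, evidence: str,
         negative: bool = False) -> CriterionHit:
    mag = cfg.weight_for(tier)
    return CriterionHit(cid, tier, -mag if negative else mag, evidence)


def evaluate_criteria(a: AnnotatedCNV, cfg: CriteriaConfig = DEFAULT_CONFIG) -> List[CriterionHit]:
    """Walk the criteria registry over an annotated CNV.

    Each criterion fires at most once regardless of how many reference
    matches support it.  Mutual exclusions prevent double-counting one
    piece of control evidence (B_POLYMORPHISM > MB_CONTROL_80 >
    mb_CONTROL_50_80).
    """
    hits: List[CriterionHit] = []
    enabled = cfg.enabled_criteria
    cnv = a.cnv
    iv = cnv.interval

    def on(cid: str) -> bool:
        return cid in enabled

    # ---- direct pathogenic ------------------------------------------------
    if on("P_SYNDROME"):
        strong = [m for m in a.syndrome_matches
                  if m.overlap_fraction >= cfg.control_major_overlap]
        if strong:
            best = strong[0]
            hits.append(_hit(
                cfg, "P_SYNDROME", Tier.DIRECT_PATHOGENIC,
                f"syndrome {best.reference.identifier} overlap "
                f"{best.overlap_fraction:.3f}",
            ))

    if on("P_FULL_OVERLAP_PATHOGENIC"):
        covering = [m for m in a.patient_matches
                    if m.reference.label == 5 and m.reference.interval.contains(iv)]
        if covering:
            hits.append(_hit(
                cfg, "P_FULL_OVERLAP_PATHOGENIC", Tier.DIRECT_PATHOGENIC,
                f"fully covered by pathogenic {covering[0].reference.identifier}",
            ))

    # ---- major pathogenic -------------------------------------------------
    morbid_genes = [g for g, n in a.gene_hits if g.is_morbid and n >= 1]
    if on("M_GENE_MORBID") and morbid_genes:
        hits.append(_hit(
            cfg, "M_GENE_MORBID", Tier.MAJOR_PATHOGENIC,
            "morbid gene(s): " + ",".join(g.symbol for g in morbid_genes),
        ))

    if on("M_HI_5PRIME_DEL"):
        hi = [g for g, _ in a.gene_hits if deletes_5prime_of_HI_gene(cnv, g)]
        if hi:
            hits.append(_hit(
                cfg, "M_HI_5PRIME_DEL", Tier.MAJOR_PATHOGENIC,
                "5' deletion of haploinsufficient " + ",".join(g.symbol for g in hi),
            ))

    if on("M_HOMOZYGOUS_DEL") and cnv.copy_number == 0:
        hits.append(_hit(cfg, "M_HOMOZYGOUS_DEL", Tier.MAJOR_PATHOGENIC,
                         "copy number 0"))

    if on("M_AMPLIFICATION") and cnv.copy_number is not None and cnv.copy_number > 3:
        hits.append(_hit(cfg, "M_AMPLIFICATION", Tier.MAJOR_PATHOGENIC,
                         f"copy number {cnv.copy_number} (> 3)"))

    # ---- minor pathogenic -------------------------------------------------
    if on("m_MORBIDITY_ENRICHED") and a.morbidity is MorbidityCall.ENRICHED_IN_CASES:
        freqs = a.morbidity_frequencies or (float("nan"), float("nan"))
        hits.append(_hit(
            cfg, "m_MORBIDITY_ENRICHED", Tier.MINOR_PATHOGENIC,
            f"case freq {freqs[0]:.2e} > control freq {freqs[1]:.2e}",
        ))

    control_best = max((m.overlap_fraction for m in a.control_matches), default=0.0)
    if on("m_ABSENT_CONTROLS") and control_best < cfg.control_minor_overlap_low:
        hits.append(_hit(
            cfg, "m_ABSENT_CONTROLS", Tier.MINOR_PATHOGENIC,
            "no control match at >= "
            f"{cfg.control_minor_overlap_low:.0%} reciprocal overlap",
        ))

    if on("m_PARTIAL_PATHOGENIC") and not morbid_genes:
        partial = [m for m in a.patient_matches
                   if m.reference.label == 5
                   and 0.0 < m.overlap_fraction < cfg.control_major_overlap]
        if partial:
            hits.append(_hit(
                cfg, "m_PARTIAL_PATHOGENIC", Tier.MINOR_PATHOGENIC,
                f"partial overlap {partial[0].overlap_fraction:.3f} with "
                f"pathogenic {partial[0].reference.identifier}",
            ))

    if on("m_SIZE_GT_1MB") and iv.length > cfg.size_major_threshold_bp:
        hits.append(_hit(cfg, "m_SIZE_GT_1MB", Tier.MINOR_PATHOGENIC,
                         f"size {iv.length} bp > {cfg.size_major_threshold_bp} bp"))

    # ---- benign side ------------------------------------------------------
    polymorphism = False
    if on("B_POLYMORPHISM") and a.control_matches:
        best = a.control_matches[0]
        freq_ok = (best.reference.population_frequency is not None
                   and best.reference.population_frequency >= cfg.polymorphism_frequency)
        recurrent_ok = (
            best.overlap_fraction >= cfg.control_major_overlap
            and best.reference.observation_count >= cfg.control_recurrent_min_count
        )
        if freq_ok or recurrent_ok:
            polymorphism = True
            hits.append(_hit(
                cfg, "B_POLYMORPHISM", Tier.DIRECT_BENIGN,
                f"control {best.reference.identifier}: count "
                f"{best.reference.observation_count}, freq "
                f"{best.reference.population_frequency}",
                negative=True,
            ))

    control_80 = False
    if on("MB_CONTROL_80") and not polymorphism:
        strong = [m for m in a.control_matches
                  if m.overlap_fraction > cfg.control_major_overlap]
        if strong:
            control_80 = True
            hits.append(_hit(
                cfg, "MB_CONTROL_80", Tier.MAJOR_BENIGN,
                f"control {strong[0].reference.identifier} overlap "
                f"{strong[0].overlap_fraction:.3f}",
                negative=True,
            ))

    # MB_NO_GENES asserts absence of (real) gene content, which is only
    # meaningful when the bundle carries gene annotation at all.
    if on("MB_NO_GENES") and a.has_gene_data:
        if not a.gene_hits or all(
            g.is_pseudogene_or_uncharacterized for g, _ in a.gene_hits
        ):
            hits.append(_hit(
                cfg, "MB_NO_GENES", Tier.MAJOR_BENIGN,
                "no genes, or pseudogenes/uncharacterized only", negative=True,
            ))

    if (on("mb_CONTROL_50_80") and not polymorphism and not control_80
            and cfg.control_minor_overlap_low <= control_best <= cfg.control_major_overlap):
        hits.append(_hit(
            cfg, "mb_CONTROL_50_80", Tier.MINOR_BENIGN,
            f"best control overlap {control_best:.3f} in "
            f"[{cfg.control_minor_overlap_low:.0%}, {cfg.control_major_overlap:.0%}]",
            negative=True,
        ))

    if on("mb_MORBIDITY_NOT_ENRICHED") and a.morbidity is MorbidityCall.NOT_ENRICHED:
        hits.append(_hit(
            cfg, "mb_MORBIDITY_NOT_ENRICHED", Tier.MINOR_BENIGN,
            "case frequency not above control frequency", negative=True,
        ))

    if (on("mb_NO_MORBID_GENE") and a.gene_hits and not morbid_genes
            and not all(g.is_pseudogene_or_uncharacterized for g, _ in a.gene_hits)):
        hits.append(_hit(
            cfg, "mb_NO_MORBID_GENE", Tier.MINOR_BENIGN,
            "no morbid gene among " + ",".join(g.symbol for g, _ in a.gene_hits),
            negative=True,
        ))

    # ---- inheritance ------------------------------------------------------
    inh = cnv.inheritance.value
    inheritance_map = {
        "DE_NOVO": ("I_DENOVO", False),
        "INHERITED_AFFECTED_PARENT": ("I_AFFECTED", False),
        "INHERITED_MOSAIC_PARENT": ("I_MOSAIC", False),
        "INHERITED_ASYMPTOMATIC_PARENT": ("I_ASYMPTOMATIC", True),
    }
    if inh in inheritance_map:
        cid, negative = inheritance_map[inh]
        if on(cid):
            hits.append(_hit(cfg, cid, Tier.INHERITANCE,
                             f"inheritance {inh}", negative=negative))

    for h in hits:
        logger.debug("criterion %s fired (%+.3f): %s", h.criterion_id, h.weight,
                     h.evidence)
    return hits


def compute_score(hits: Sequence[CriterionHit]) -> float:
    """Exact additive score; the empty evidence set scores 0."""
    return sum(h.weight for h in hits)


def classify_score(score: float, cfg: CriteriaConfig = DEFAULT_CONFIG) -> int:
    """Map a score to the five-tier class, thresholds evaluated outside-in
    (pathogenic before likely pathogenic, benign before likely benign)."""
    if score >= cfg.threshold_pathogenic - SCORE_EPS:
        return 5
    if score >= cfg.threshold_likely_pathogenic - SCORE_EPS:
        return 4
    if score <= cfg.threshold_benign + SCORE_EPS:
        return 1
    if score <= cfg.threshold_likely_benign + SCORE_EPS:
        return 2
    return 3


def classify(a: AnnotatedCNV, cfg: CriteriaConfig = DEFAULT_CONFIG) -> ClassificationResult:
    """Full classification of one annotated CNV.

    A PIEV catalog match takes precedence over the numeric score; the score
    and fired criteria are still computed and reported.
    """
    hits = evaluate_criteria(a, cfg)
    score = compute_score(hits)
    if a.piev_match is not None:
        entry, ro = a.piev_match
        final: object = PIEV_CLASS
        piev_entry, piev_ro = entry, ro
    else:
        final = classify_score(score, cfg)
        piev_entry, piev_ro = None, None
    result = ClassificationResult(
        cnv=a.cnv,
        final_class=final,  # type: ignore[arg-type]
        score=score,
        hits=tuple(hits),
        piev_match=piev_entry,
        piev_overlap=piev_ro,
        gene_hits=a.gene_hits,
    )
    logger.info(
        "%s %s -> class %s (score %+.3f, %d criteria)",
        a.cnv.cnv_type.value, a.cnv.interval, result.final_class, score, len(hits),
    )
    return result
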