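"""The weighted scoring system: registry walk-throughs, threshold
semantics, mutual exclusions, monotonicity and the PIEV override."""

import pytest

from achropuce.annotate import AnnotatedCNV, MorbidityCall, annotate
from achropuce.classifier import (
    ALL_CRITERIA,
    CriteriaConfig,
    classify,
    classify_score,
    compute_score,
    evaluate_criteria,
)
from achropuce.core import (
    CNVRecord,
    CNVType,
    CriterionHit,
    GeneAnnotation,
    GenomicInterval,
    Inheritance,
    InputError,
    PIEVEntry,
    PIEV_CLASS,
    ReferenceVariant,
    RefSource,
    Tier,
)
from achropuce.io_formats import ReferenceBundle
from achropuce.overlap import OverlapMatch, reciprocal_overlap

CFG = CriteriaConfig()


def _annotated(cnv, **kwargs):
    defaults = dict(gene_hits=(), control_matches=(), patient_matches=(),
                    syndrome_matches=(), morbidity=MorbidityCall.NO_DATA,
                    has_gene_data=True)
    defaults.update(kwargs)
    return AnnotatedCNV(cnv=cnv, **defaults)


def _match(ref, query_iv):
    return OverlapMatch(
        reference=ref,
        overlap_fraction=reciprocal_overlap(query_iv, ref.interval),
        intersection_bp=query_iv.intersection_bp(ref.interval),
    )


# ---------------------------------------------------------------------------
# thresholds and weight sums

@pytest.mark.parametrize(
    "score, expected",
    [(-1.5, 1), (-1.0, 1), (-0.9, 2), (-0.89, 3), (0.0, 3),
     (0.89, 3), (0.9, 4), (1.0, 5), (1.5, 5)],
)
def test_threshold_semantics(score, expected):
    assert classify_score(score, CFG) == expected


def test_two_majors_reach_likely_pathogenic_exactly():
    hits = [CriterionHit("a", Tier.MAJOR_PATHOGENIC, 0.45),
            CriterionHit("b", Tier.MAJOR_PATHOGENIC, 0.45)]
    assert compute_score(hits) == pytest.approx(0.9)
    assert classify_score(compute_score(hits), CFG) == 4


def test_one_major_two_minors_reach_likely_pathogenic_exactly():
    hits = [CriterionHit("a", Tier.MAJOR_PATHOGENIC, 0.45),
            CriterionHit("b", Tier.MINOR_PATHOGENIC, 0.225),
            CriterionHit("c", Tier.MINOR_PATHOGENIC, 0.225)]
    assert classify_score(compute_score(hits), CFG) == 4


def test_benign_mirror_reaches_likely_benign():
    two_major = [CriterionHit("a", Tier.MAJOR_BENIGN, -0.45),
                 CriterionHit("b", Tier.MAJOR_BENIGN, -0.45)]
    assert classify_score(compute_score(two_major), CFG) == 2
    mixed = [CriterionHit("a", Tier.MAJOR_BENIGN, -0.45),
             CriterionHit("b", Tier.MINOR_BENIGN, -0.225),
             CriterionHit("c", Tier.MINOR_BENIGN, -0.225)]
    assert classify_score(compute_score(mixed), CFG) == 2


def test_empty_evidence_scores_zero():
    assert compute_score([]) == 0.0
    assert classify_score(0.0, CFG) == 3


def test_threshold_config_invariant_enforced():
    with pytest.raises(InputError):
        CriteriaConfig(threshold_likely_pathogenic=1.5, threshold_pathogenic=1.0)


# ---------------------------------------------------------------------------
# registry walk-throughs

def test_cnv_with_no_evidence_and_no_gene_data_scores_absent_controls_only():
    """An empty bundle asserts nothing about gene content, so only the
    control-absence criterion fires."""
    cnv = CNVRecord(GenomicInterval("1", 0, 500_000), CNVType.LOSS)
    a = _annotated(cnv, has_gene_data=False)
    hits = evaluate_criteria(a, CFG)
    assert {h.criterion_id for h in hits} == {"m_ABSENT_CONTROLS"}
    result = classify(a, CFG)
    assert result.score == pytest.approx(0.225)
    assert result.final_class == 3


def test_one_non_morbid_gene_no_controls_is_a_balanced_vus():
    gene = GeneAnnotation("G", GenomicInterval("1", 100_000, 150_000), "+",
                          (GenomicInterval("1", 100_000, 101_000),))
    cnv = CNVRecord(GenomicInterval("1", 0, 500_000), CNVType.LOSS)
    a = _annotated(cnv, gene_hits=((gene, 1),))
    hits = evaluate_criteria(a, CFG)
    assert {h.criterion_id for h in hits} == {"m_ABSENT_CONTROLS",
                                              "mb_NO_MORBID_GENE"}
    assert compute_score(hits) == pytest.approx(0.0)


def test_polymorphism_suppresses_control_80():
    iv = GenomicInterval("1", 0, 100_000)
    ref = ReferenceVariant(GenomicInterval("1", 0, 110_000), CNVType.LOSS,
                           RefSource.CONTROL, "c", observation_count=5)
    cnv = CNVRecord(iv, CNVType.LOSS)
    a = _annotated(cnv, control_matches=(_match(ref, iv),), has_gene_data=False)
    ids = {h.criterion_id for h in evaluate_criteria(a, CFG)}
    assert "B_POLYMORPHISM" in ids
    assert "MB_CONTROL_80" not in ids
    assert "mb_CONTROL_50_80" not in ids


def test_single_observation_control_fires_major_benign_not_polymorphism():
    iv = GenomicInterval("1", 0, 100_000)
    ref = ReferenceVariant(GenomicInterval("1", 0, 110_000), CNVType.LOSS,
                           RefSource.CONTROL, "c", observation_count=1)
    cnv = CNVRecord(iv, CNVType.LOSS)
    gene_elsewhere = True  # bundle has gene data, CNV covers no gene
    a = _annotated(cnv, control_matches=(_match(ref, iv),),
                   has_gene_data=gene_elsewhere)
    hits = evaluate_criteria(a, CFG)
    ids = {h.criterion_id for h in hits}
    assert ids == {"MB_CONTROL_80", "MB_NO_GENES"}
    assert classify_score(compute_score(hits), CFG) == 2


def test_mid_overlap_control_fires_minor_benign_only():
    iv = GenomicInterval("1", 0, 100_000)
    # RO = 2*60k/(100k+60k) = 0.75 in [0.5, 0.8]
    ref = ReferenceVariant(GenomicInterval("1", 0, 60_000), CNVType.LOSS,
                           RefSource.CONTROL, "c", observation_count=1)
    cnv = CNVRecord(iv, CNVType.LOSS)
    a = _annotated(cnv, control_matches=(_match(ref, iv),), has_gene_data=False)
    ids = {h.criterion_id for h in evaluate_criteria(a, CFG)}
    assert "mb_CONTROL_50_80" in ids
    assert "MB_CONTROL_80" not in ids
    assert "m_ABSENT_CONTROLS" not in ids


def test_de_novo_syndrome_match_is_pathogenic():
    iv = GenomicInterval("1", 0, 500_000)
    ref = ReferenceVariant(iv, CNVType.LOSS, RefSource.SYNDROME, "syn", label=5)
    cnv = CNVRecord(iv, CNVType.LOSS, inheritance=Inheritance.DE_NOVO)
    a = _annotated(cnv, syndrome_matches=(_match(ref, iv),), has_gene_data=False)
    hits = evaluate_criteria(a, CFG)
    ids = {h.criterion_id for h in hits}
    assert {"P_SYNDROME", "I_DENOVO"} <= ids
    assert compute_score(hits) >= 1.45 - 1e-9
    assert classify(a, CFG).final_class == 5


@pytest.mark.parametrize(
    "inheritance, cid, sign",
    [
        (Inheritance.DE_NOVO, "I_DENOVO", +1),
        (Inheritance.INHERITED_AFFECTED_PARENT, "I_AFFECTED", +1),
        (Inheritance.INHERITED_MOSAIC_PARENT, "I_MOSAIC", +1),
        (Inheritance.INHERITED_ASYMPTOMATIC_PARENT, "I_ASYMPTOMATIC", -1),
    ],
)
def test_inheritance_evidence(inheritance, cid, sign):
    cnv = CNVRecord(GenomicInterval("1", 0, 100_000), CNVType.LOSS,
                    inheritance=inheritance)
    hits = evaluate_criteria(_annotated(cnv, has_gene_data=False), CFG)
    by_id = {h.criterion_id: h for h in hits}
    assert cid in by_id
    assert by_id[cid].weight == pytest.approx(sign * 0.45)


def test_unknown_inheritance_contributes_nothing():
    cnv = CNVRecord(GenomicInterval("1", 0, 100_000), CNVType.LOSS)
    ids = {h.criterion_id for h in evaluate_criteria(_annotated(cnv, has_gene_data=False), CFG)}
    assert not any(i.startswith("I_") for i in ids)


def test_disabled_criteria_do_not_fire():
    cnv = CNVRecord(GenomicInterval("1", 0, 2_000_000), CNVType.LOSS,
                    inheritance=Inheritance.DE_NOVO)
    cfg = CriteriaConfig(enabled_criteria=frozenset({"m_SIZE_GT_1MB"}))
    ids = {h.criterion_id for h in evaluate_criteria(_annotated(cnv), cfg)}
    assert ids == {"m_SIZE_GT_1MB"}
    with pytest.raises(InputError):
        CriteriaConfig(enabled_criteria=frozenset({"NOT_A_CRITERION"}))


# ---------------------------------------------------------------------------
# structural properties

def test_piev_override_beats_any_score():
    iv = GenomicInterval("1", 0, 500_000)
    entry = PIEVEntry("p", iv, "LOSS")
    ref = ReferenceVariant(iv, CNVType.LOSS, RefSource.PATIENT, "pat", label=5)
    cnv = CNVRecord(iv, CNVType.LOSS, inheritance=Inheritance.DE_NOVO)
    a = _annotated(cnv, patient_matches=(_match(ref, iv),),
                   piev_match=(entry, 1.0), has_gene_data=False)
    result = classify(a, CFG)
    assert result.final_class == PIEV_CLASS
    assert result.piev_match is entry
    assert result.score > 0  # score still computed and reported


def test_adding_pathogenic_evidence_never_lowers_the_class():
    for base in (-1.2, -0.9, -0.3, 0.0, 0.5, 0.9, 1.3):
        for w in (0.225, 0.45, 1.0):
            assert classify_score(base + w, CFG) >= classify_score(base, CFG)
            assert classify_score(base - w, CFG) <= classify_score(base, CFG)


def test_score_additivity_on_all_planted_results(bundle, planted):
    for p in planted:
        r = classify(annotate(p.record, bundle), CFG)
        assert r.score == pytest.approx(sum(h.weight for h in r.hits))
        assert len({h.criterion_id for h in r.hits}) == len(r.hits)
        assert {h.criterion_id for h in r.hits} <= ALL_CRITERIA
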