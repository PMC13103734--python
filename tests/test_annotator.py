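"""Evidence gathering: exon impact, 5'-HI deletions, morbidity enrichment,
recurrent-CNV (PIEV) matching and the full annotate() composition."""

import pytest

from achropuce.annotate import (
    AnnotatedCNV,
    MorbidityCall,
    annotate,
    deletes_5prime_of_HI_gene,
    impacted_exons,
    match_piev,
    morbidity_comparison,
)
from achropuce.core import (
    BuildMismatchError,
    CNVRecord,
    CNVType,
    GeneAnnotation,
    GenomeBuild,
    GenomicInterval,
    Inheritance,
    MorbidityRegion,
    PIEVEntry,
)
from achropuce.io_formats import ReferenceBundle


def _ten_exon_gene(strand="+", hi=False):
    # exons of 50 bp every 100 bp starting at 1000
    exons = tuple(GenomicInterval("1", 1000 + i * 100, 1050 + i * 100)
                  for i in range(10))
    return GeneAnnotation("TEN", GenomicInterval("1", 1000, 2000), strand, exons,
                          is_haploinsufficient=hi)


def test_impacted_exons_counts_intersecting_exons():
    g = _ten_exon_gene()
    assert impacted_exons(GenomicInterval("1", 0, 5000), g) == 10
    assert impacted_exons(GenomicInterval("1", 3000, 4000), g) == 0
    # covers exons 3-5 (0-based exons 2,3,4): span 1200..1500
    assert impacted_exons(GenomicInterval("1", 1200, 1460), g) == 3


def test_deletes_5prime_of_HI_gene_strand_aware():
    g = _ten_exon_gene(hi=True)
    full = CNVRecord(GenomicInterval("1", 900, 2100), CNVType.LOSS)
    assert deletes_5prime_of_HI_gene(full, g)
    left = CNVRecord(GenomicInterval("1", 900, 1300), CNVType.LOSS)
    assert deletes_5prime_of_HI_gene(left, g)  # covers + strand 5' end
    right = CNVRecord(GenomicInterval("1", 1500, 2100), CNVType.LOSS)
    assert not deletes_5prime_of_HI_gene(right, g)  # only 3' half
    gain = CNVRecord(GenomicInterval("1", 900, 2100), CNVType.GAIN)
    assert not deletes_5prime_of_HI_gene(gain, g)  # not a deletion
    not_hi = _ten_exon_gene(hi=False)
    assert not deletes_5prime_of_HI_gene(full, not_hi)

    minus = _ten_exon_gene(strand="-", hi=True)
    assert deletes_5prime_of_HI_gene(right, minus)       # covers end - 1
    assert not deletes_5prime_of_HI_gene(left, minus)


def _morb(case, control, t=CNVType.LOSS):
    return MorbidityRegion(GenomicInterval("1", 0, 1000), t,
                           case_count=case, case_total=1000,
                           control_count=control, control_total=1000)


def test_morbidity_comparison():
    cnv = CNVRecord(GenomicInterval("1", 0, 1000), CNVType.LOSS)
    assert morbidity_comparison(cnv, [_morb(10, 1)]) is MorbidityCall.ENRICHED_IN_CASES
    # a tie is not enrichment
    assert morbidity_comparison(cnv, [_morb(1, 1)]) is MorbidityCall.NOT_ENRICHED
    assert morbidity_comparison(cnv, []) is MorbidityCall.NO_DATA
    # wrong type gives no data
    assert morbidity_comparison(cnv, [_morb(10, 1, CNVType.GAIN)]) is MorbidityCall.NO_DATA
    # below the overlap threshold gives no data
    far = CNVRecord(GenomicInterval("1", 900, 1900), CNVType.LOSS)
    assert morbidity_comparison(far, [_morb(10, 1)]) is MorbidityCall.NO_DATA


def _gene(symbol, start, end):
    return GeneAnnotation(symbol, GenomicInterval("1", start, end), "+",
                          (GenomicInterval("1", start, min(start + 50, end)),))


def test_match_piev_rules():
    ga, gb = _gene("A", 2000, 2500), _gene("B", 5000, 5500)
    genes = {"A": ga, "B": gb}
    entry = PIEVEntry("16p-like", GenomicInterval("1", 1000, 9000), "LOSS",
                      candidate_genes=("A", "B"), breakpoint_tolerance_bp=0)

    exact = CNVRecord(GenomicInterval("1", 1000, 9000), CNVType.LOSS)
    m = match_piev(exact, [entry], genes)
    assert m is not None and m[1] == 1.0

    # type incompatibility
    assert match_piev(
        CNVRecord(GenomicInterval("1", 1000, 9000), CNVType.GAIN), [entry], genes
    ) is None

    # 0.75 overlap (threshold 0.70), genes contained -> match
    shrunk = CNVRecord(GenomicInterval("1", 1000, 5800), CNVType.LOSS)
    assert 2 * 4800 / (4800 + 8000) == 0.75
    m = match_piev(shrunk, [entry], genes)
    assert m is not None and m[1] == 0.75

    # high overlap but candidate gene B no longer contained -> no match
    missing_b = CNVRecord(GenomicInterval("1", 1000, 5400), CNVType.LOSS)
    assert match_piev(missing_b, [entry], genes) is None

    # unknown candidate symbol fails containment
    ghost = PIEVEntry("ghost", GenomicInterval("1", 1000, 9000), "LOSS",
                      candidate_genes=("NOPE",))
    assert match_piev(exact, [ghost], genes) is None

    # breakpoint tolerance rescues a shifted CNV
    tol = PIEVEntry("tol", GenomicInterval("1", 1000, 9000), "BOTH",
                    candidate_genes=(), breakpoint_tolerance_bp=2000)
    shifted = CNVRecord(GenomicInterval("1", 0, 8000), CNVType.GAIN)
    assert match_piev(shifted, [tol], {}) is not None


def test_match_piev_best_overlap_wins_ties_by_name():
    e1 = PIEVEntry("b_entry", GenomicInterval("1", 1000, 9000), "LOSS")
    e2 = PIEVEntry("a_entry", GenomicInterval("1", 1000, 9000), "LOSS")
    cnv = CNVRecord(GenomicInterval("1", 1000, 9000), CNVType.LOSS)
    m = match_piev(cnv, [e1, e2], {})
    assert m is not None and m[0].name == "a_entry"


def test_annotate_empty_bundle():
    empty = ReferenceBundle()
    cnv = CNVRecord(GenomicInterval("1", 0, 500_000), CNVType.LOSS)
    a = annotate(cnv, empty)
    assert a.gene_hits == () and a.control_matches == ()
    assert a.patient_matches == () and a.syndrome_matches == ()
    assert a.morbidity is MorbidityCall.NO_DATA
    assert a.piev_match is None
    assert a.has_gene_data is False


def test_annotate_build_mismatch_is_fatal(bundle):
    cnv = CNVRecord(GenomicInterval("1", 0, 500_000), CNVType.LOSS,
                    genome_build=GenomeBuild.GRCH38)
    with pytest.raises(BuildMismatchError):
        annotate(cnv, bundle)


def test_annotate_is_deterministic_and_pure(bundle, planted):
    rec = planted[0].record
    a1 = annotate(rec, bundle)
    a2 = annotate(rec, bundle)
    assert a1 == a2
    # every stored match is comparable with real intersection
    for a in (a1,):
        for m in a.control_matches + a.patient_matches + a.syndrome_matches:
            assert m.comparable and m.intersection_bp >= 1


def test_annotate_exact_control_match(bundle, spec):
    ctrl = bundle.controls[0]
    cnv = CNVRecord(ctrl.interval, ctrl.cnv_type)
    a = annotate(cnv, bundle)
    assert len(a.control_matches) == 1
    assert a.control_matches[0].overlap_fraction == 1.0
    assert a.control_matches[0].reference.observation_count == 5


def test_impacted_exon_count_never_exceeds_total(bundle, planted):
    for p in planted[:50]:
        a = annotate(p.record, bundle)
        for gene, n in a.gene_hits:
            assert 0 <= n <= len(gene.exons)
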