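"""Reciprocal-overlap arithmetic, the comparability rule and the interval
index (checked against a brute-force all-pairs scan)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from achropuce.core import (
    CNVRecord,
    CNVType,
    GenomicInterval,
    ReferenceVariant,
    RefSource,
)
from achropuce.overlap import (
    IntervalIndex,
    build_index,
    is_comparable,
    query_index,
    reciprocal_overlap,
    size_difference,
)


@st.composite
def intervals(draw, chroms=("1", "2")):
    chrom = draw(st.sampled_from(chroms))
    start = draw(st.integers(0, 10_000))
    length = draw(st.integers(1, 5_000))
    return GenomicInterval(chrom, start, start + length)


def test_reciprocal_overlap_examples():
    a = GenomicInterval("1", 0, 100)
    assert reciprocal_overlap(a, a) == 1.0
    assert reciprocal_overlap(a, GenomicInterval("1", 200, 300)) == 0.0
    assert reciprocal_overlap(a, GenomicInterval("2", 0, 100)) == 0.0
    # 2 * 50 / (100 + 100)
    assert reciprocal_overlap(a, GenomicInterval("1", 50, 150)) == pytest.approx(0.5)


@settings(derandomize=True, max_examples=300)
@given(intervals(), intervals(), st.integers(0, 100_000))
def test_reciprocal_overlap_properties(a, b, offset):
    ro = reciprocal_overlap(a, b)
    assert 0.0 <= ro <= 1.0
    assert ro == reciprocal_overlap(b, a)
    assert (ro == 1.0) == (a == b)
    shifted_a = GenomicInterval(a.chrom, a.start + offset, a.end + offset)
    shifted_b = GenomicInterval(b.chrom, b.start + offset, b.end + offset)
    assert reciprocal_overlap(shifted_a, shifted_b) == pytest.approx(ro)


@pytest.mark.parametrize(
    "la, lb, expected",
    [(100, 100, 0.0), (100, 70, 0.30), (100, 50, 0.50), (70, 100, 0.30)],
)
def test_size_difference(la, lb, expected):
    a = GenomicInterval("1", 0, la)
    b = GenomicInterval("1", 0, lb)
    assert size_difference(a, b) == pytest.approx(expected)


@pytest.mark.parametrize(
    "len_ref, shared, expected",
    [
        (50, 0, False),   # >30% difference and no shared genes: excluded
        (50, 1, True),    # shared gene rescues the pair
        (90, 0, True),    # small size difference alone is fine
        (70, 0, True),    # exactly 30% is NOT excluded (strict rule)
    ],
)
def test_comparability_rule_is_a_strict_conjunction(len_ref, shared, expected):
    q = CNVRecord(GenomicInterval("1", 0, 100), CNVType.LOSS)
    ref = ReferenceVariant(GenomicInterval("1", 0, len_ref), CNVType.LOSS,
                           RefSource.CONTROL, "c", observation_count=1)
    assert is_comparable(q, ref, shared) is expected


def _random_refs(rng, n):
    refs = []
    for i in range(n):
        chrom = str(rng.integers(1, 4))
        start = int(rng.integers(0, 100_000))
        length = int(rng.integers(1, 20_000))
        t = CNVType.LOSS if rng.random() < 0.5 else CNVType.GAIN
        refs.append(ReferenceVariant(
            GenomicInterval(chrom, start, start + length), t,
            RefSource.CONTROL, f"R{i:04d}", observation_count=1))
    return refs


def _brute_force(refs, iv, type_filter=None):
    out = []
    for r in refs:
        if type_filter is not None and r.cnv_type is not type_filter:
            continue
        inter = iv.intersection_bp(r.interval)
        if inter >= 1:
            out.append((r.identifier, reciprocal_overlap(iv, r.interval), inter))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def test_index_matches_brute_force_scan():
    rng = np.random.default_rng(42)
    refs = _random_refs(rng, 300)
    index = build_index(refs)
    assert len(index) == 300
    for _ in range(60):
        chrom = str(rng.integers(1, 4))
        start = int(rng.integers(0, 100_000))
        iv = GenomicInterval(chrom, start, start + int(rng.integers(1, 30_000)))
        for tf in (None, CNVType.LOSS):
            got = [(m.reference.identifier, m.overlap_fraction, m.intersection_bp)
                   for m in query_index(index, iv, tf)]
            assert got == _brute_force(refs, iv, tf)


def test_index_trivial_queries():
    ref = ReferenceVariant(GenomicInterval("1", 100, 200), CNVType.LOSS,
                           RefSource.CONTROL, "only", observation_count=1)
    index = IntervalIndex([ref])
    assert index.query(GenomicInterval("1", 500, 600)) == []
    assert index.query(GenomicInterval("2", 100, 200)) == []
    hit = index.query(GenomicInterval("1", 100, 200))
    assert len(hit) == 1 and hit[0].overlap_fraction == 1.0


@settings(derandomize=True, max_examples=100)
@given(intervals(chroms=("1",)), intervals(chroms=("1",)), st.integers(1, 3_000))
def test_growing_query_never_loses_intersection(q, ref, grow):
    bigger = GenomicInterval(q.chrom, q.start, q.end + grow)
    assert bigger.intersection_bp(ref) >= q.intersection_bp(ref)
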