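"""Deterministic synthetic reference bundles and labeled CNV sets.

The generator lays a toy genome out in disjoint 2 Mb *slots*, each owned by
exactly one evidence source (a syndrome region, one control variant, one
morbidity region, ...).  Slots are separated by 100 kb margins, so a CNV
planted inside one slot can only ever match that slot's evidence — which
makes the criterion trace of every planted CNV exactly predictable and lets
tests assert fired criteria verbatim.

Planted CNVs come from a fixed set of recipes that emulate the two truth
strata of a balanced validation set (pathogenic evidence vs benign
evidence), plus a separate recurrent-CNV (PIEV) set with jittered
breakpoints for override tests.  Everything is reproducible: the same spec
yields byte-identical bundle files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    CNVRecord,
    CNVType,
    GeneAnnotation,
    GenomeBuild,
    GenomicInterval,
    Inheritance,
    InputError,
    MorbidityRegion,
    PIEVEntry,
    ReferenceVariant,
    RefSource,
)
from .io_formats import ReferenceBundle
from .metrics import Truth
from .trio import TrioInput

SLOT_WIDTH = 2_000_000
SLOT_MARGIN = 100_000


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic bundle + planted CNV set."""

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length_bp: int = 100_000_000
    n_genes: int = 80
    morbid_fraction: float = 0.25
    hi_fraction: float = 0.15
    pseudogene_fraction: float = 0.10
    n_control: int = 40
    n_patient: int = 30
    n_syndrome: int = 12
    n_morbidity: int = 20
    n_piev: int = 8
    n_pathogenic_cnvs: int = 200
    n_benign_cnvs: int = 200
    size_range_bp: Tuple[int, int] = (50_000, 2_000_000)
    genome_build: GenomeBuild = GenomeBuild.GRCH37

    def __post_init__(self) -> None:
        for name in ("morbid_fraction", "hi_fraction", "pseudogene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InputError(f"{name} must lie in [0,1], got {v}")
        for name in ("n_control", "n_patient", "n_syndrome", "n_morbidity",
                     "n_piev", "n_pathogenic_cnvs", "n_benign_cnvs", "n_genes"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PlantedCNV:
    """A generated CNV with its truth label and the criteria it was built
    to fire (for exact-trace assertions)."""

    record: CNVRecord
    truth: Truth
    intended_criteria: frozenset
    expected_class: Union[int, str]
    recipe: str


# ---------------------------------------------------------------------------
# layout

@dataclass
class _Layout:
    """Deterministic slot assignment derived from a spec (no randomness)."""

    spec: FixtureSpec
    controls: List[ReferenceVariant] = field(default_factory=list)
    patients: List[ReferenceVariant] = field(default_factory=list)
    syndromes: List[ReferenceVariant] = field(default_factory=list)
    morbidity: List[MorbidityRegion] = field(default_factory=list)
    genes: List[GeneAnnotation] = field(default_factory=list)
    piev: List[PIEVEntry] = field(default_factory=list)
    # usable slot starts per evidence source, for CNV planting
    syndrome_slots: List[GenomicInterval] = field(default_factory=list)
    patient_slots: List[GenomicInterval] = field(default_factory=list)
    control_slots: List[GenomicInterval] = field(default_factory=list)
    morbidity_slots: List[GenomicInterval] = field(default_factory=list)
    piev_slots: List[GenomicInterval] = field(default_factory=list)
    hi_slots: List[Tuple[GenomicInterval, GeneAnnotation]] = field(default_factory=list)


def _make_gene(symbol: str, chrom: str, start: int, length: int, n_exons: int,
               strand: str, **flags) -> GeneAnnotation:
    exon_len = max(1, length // (2 * n_exons))
    exons = tuple(
        GenomicInterval(chrom, start + 2 * k * exon_len,
                        start + 2 * k * exon_len + exon_len)
        for k in range(n_exons)
    )
    scores = None
    if flags.get("is_haploinsufficient"):
        scores = {"pLI": 0.99, "pHaplo": 0.92}
    return GeneAnnotation(
        symbol=symbol,
        interval=GenomicInterval(chrom, start, start + length),
        strand=strand,
        exons=exons,
        display_scores=scores,
        **flags,
    )


def _build_layout(spec: FixtureSpec) -> _Layout:
    n_morbid = round(spec.n_genes * spec.morbid_fraction)
    n_hi = round(spec.n_genes * spec.hi_fraction)
    n_pseudo = round(spec.n_genes * spec.pseudogene_fraction)
    if n_morbid < spec.n_syndrome:
        raise InputError(
            f"need >= {spec.n_syndrome} morbid genes for the syndrome slots, "
            f"spec yields {n_morbid}"
        )
    n_hi_slots = min(n_hi, n_morbid - spec.n_syndrome)
    n_plain_hi = n_hi - n_hi_slots
    n_plain_morbid = n_morbid - spec.n_syndrome - n_hi_slots
    n_normal = spec.n_genes - n_morbid - n_plain_hi - n_pseudo
    needed_normal = spec.n_patient + 2 * spec.n_piev
    if n_normal < needed_normal:
        raise InputError(
            f"need >= {needed_normal} non-morbid genes for patient/PIEV slots, "
            f"spec yields {n_normal}"
        )
    n_plain_normal = n_normal - needed_normal
    n_desert = 20

    total_slots = (
        spec.n_syndrome + spec.n_patient + spec.n_control + spec.n_morbidity
        + spec.n_piev + n_hi_slots + n_pseudo + n_plain_hi + n_plain_morbid
        + n_plain_normal + n_desert
    )
    slots_per_chrom = spec.chrom_length_bp // SLOT_WIDTH
    if total_slots > spec.n_chromosomes * slots_per_chrom:
        raise InputError(
            f"layout needs {total_slots} slots but the genome only has "
            f"{spec.n_chromosomes * slots_per_chrom}"
        )

    def slot(k: int) -> Tuple[str, int]:
        chrom = str(k // slots_per_chrom + 1)
        u = (k % slots_per_chrom) * SLOT_WIDTH + SLOT_MARGIN
        return chrom, u

    lay = _Layout(spec=spec)
    k = 0

    for i in range(spec.n_syndrome):
        chrom, u = slot(k); k += 1
        t = CNVType.LOSS if i % 2 == 0 else CNVType.GAIN
        region = GenomicInterval(chrom, u + 50_000, u + 1_250_000)
        lay.syndromes.append(ReferenceVariant(
            interval=region, cnv_type=t, source=RefSource.SYNDROME,
            identifier=f"SYN{i:03d}", label=5,
        ))
        lay.genes.append(_make_gene(f"MORB{i:03d}", chrom, u + 200_000, 100_000,
                                    5, "+", is_morbid=True))
        lay.syndrome_slots.append(region)

    for i in range(spec.n_patient):
        chrom, u = slot(k); k += 1
        t = CNVType.LOSS if i % 2 == 0 else CNVType.GAIN
        region = GenomicInterval(chrom, u + 50_000, u + 1_250_000)
        lay.patients.append(ReferenceVariant(
            interval=region, cnv_type=t, source=RefSource.PATIENT,
            identifier=f"PAT{i:03d}", label=5,
        ))
        lay.genes.append(_make_gene(f"PGEN{i:03d}", chrom, u + 100_000, 80_000,
                                    4, "+"))
        lay.patient_slots.append(region)

    for i in range(spec.n_control):
        chrom, u = slot(k); k += 1
        t = CNVType.LOSS if i % 2 == 0 else CNVType.GAIN
        iv = GenomicInterval(chrom, u + 100_000, u + 500_000)
        recurrent = i % 2 == 0
        lay.controls.append(ReferenceVariant(
            interval=iv, cnv_type=t, source=RefSource.CONTROL,
            identifier=f"CTRL{i:03d}",
            observation_count=5 if recurrent else 1,
            population_frequency=0.02 if recurrent else None,
        ))
        lay.control_slots.append(iv)

    for i in range(spec.n_morbidity):
        chrom, u = slot(k); k += 1
        t = CNVType.GAIN if i % 2 == 0 else CNVType.LOSS
        region = GenomicInterval(chrom, u + 100_000, u + 700_000)
        enriched = i % 4 < 2
        lay.morbidity.append(MorbidityRegion(
            interval=region, cnv_type=t,
            case_count=30 if enriched else 1, case_total=1000,
            control_count=2 if enriched else 5, control_total=1000,
        ))
        lay.morbidity_slots.append(region)

    for i in range(spec.n_piev):
        chrom, u = slot(k); k += 1
        region = GenomicInterval(chrom, u + 100_000, u + 900_000)
        t = ("BOTH", "LOSS", "GAIN")[i % 3]
        ga = _make_gene(f"PVG{i:02d}A", chrom, u + 200_000, 60_000, 3, "+")
        gb = _make_gene(f"PVG{i:02d}B", chrom, u + 400_000, 60_000, 3, "+")
        lay.genes.extend([ga, gb])
        lay.piev.append(PIEVEntry(
            name=f"PIEV_{i:02d}", region=region, cnv_type=t,
            candidate_genes=(ga.symbol, gb.symbol),
            breakpoint_tolerance_bp=100_000,
        ))
        lay.piev_slots.append(region)

    for i in range(n_hi_slots):
        chrom, u = slot(k); k += 1
        strand = "+" if i % 2 == 0 else "-"
        g = _make_gene(f"HIGN{i:03d}", chrom, u + 500_000, 80_000, 10, strand,
                       is_morbid=True, is_haploinsufficient=True)
        lay.genes.append(g)
        lay.hi_slots.append((GenomicInterval(chrom, u, u + SLOT_WIDTH - 2 * SLOT_MARGIN), g))

    for i in range(n_pseudo):
        chrom, u = slot(k); k += 1
        lay.genes.append(_make_gene(f"PSG{i:03d}", chrom, u + 200_000, 30_000,
                                    2, "+", is_pseudogene_or_uncharacterized=True))

    for i in range(n_plain_hi):
        chrom, u = slot(k); k += 1
        lay.genes.append(_make_gene(f"HIPL{i:03d}", chrom, u + 300_000, 60_000,
                                    5, "+", is_haploinsufficient=True))

    for i in range(n_plain_morbid):
        chrom, u = slot(k); k += 1
        lay.genes.append(_make_gene(f"MBPL{i:03d}", chrom, u + 300_000, 60_000,
                                    5, "+", is_morbid=True))

    for i in range(n_plain_normal):
        chrom, u = slot(k); k += 1
        lay.genes.append(_make_gene(f"NRM{i:03d}", chrom, u + 300_000, 60_000,
                                    5, "+"))

    return lay


def build_bundle(spec: FixtureSpec) -> ReferenceBundle:
    """In-memory bundle for the spec (same content the files would carry)."""
    lay = _build_layout(spec)
    return ReferenceBundle(
        controls=lay.controls, patients=lay.patients, syndromes=lay.syndromes,
        morbidity=lay.morbidity, genes=lay.genes, piev=lay.piev,
        genome_build=spec.genome_build,
    )


# ---------------------------------------------------------------------------
# writing bundle files

def generate_bundle(spec: FixtureSpec, outdir: Union[str, Path]) -> Path:
    """Write the bundle to disk in the formats the readers consume.

    Deterministic: the same spec produces byte-identical files.
    """
    lay = _build_layout(spec)
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)

    with open(d / "meta.json", "w") as fh:
        json.dump({"genome_build": spec.genome_build.value}, fh, indent=0)
        fh.write("\n")

    with open(d / "controls.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tobservation_count\tpopulation_frequency\tid\n")
        for v in lay.controls:
            freq = "" if v.population_frequency is None else f"{v.population_frequency:g}"
            fh.write(f"{v.interval.chrom}\t{v.interval.start}\t{v.interval.end}\t"
                     f"{v.cnv_type.value}\t{v.observation_count}\t{freq}\t{v.identifier}\n")

    for fname, variants in (("patients.tsv", lay.patients),
                            ("syndromes.tsv", lay.syndromes)):
        with open(d / fname, "w") as fh:
            fh.write("chrom\tstart\tend\ttype\tlabel\tid\n")
            for v in variants:
                fh.write(f"{v.interval.chrom}\t{v.interval.start}\t{v.interval.end}\t"
                         f"{v.cnv_type.value}\t{v.label}\t{v.identifier}\n")

    with open(d / "morbidity.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tcase_count\tcase_total\t"
                 "control_count\tcontrol_total\n")
        for m in lay.morbidity:
            fh.write(f"{m.interval.chrom}\t{m.interval.start}\t{m.interval.end}\t"
                     f"{m.cnv_type.value}\t{m.case_count}\t{m.case_total}\t"
                     f"{m.control_count}\t{m.control_total}\n")

    with open(d / "genes.bed", "w") as fh:
        for g in lay.genes:
            iv = g.interval
            sizes = ",".join(str(e.length) for e in g.exons) + ","
            starts = ",".join(str(e.start - iv.start) for e in g.exons) + ","
            scores = ("." if not g.display_scores else
                      ";".join(f"{k}={v:g}" for k, v in sorted(g.display_scores.items())))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.symbol}\t0\t{g.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\t"
                f"{1 if g.is_morbid else 0}\t{1 if g.is_haploinsufficient else 0}\t"
                f"{1 if g.is_pseudogene_or_uncharacterized else 0}\t{scores}\n"
            )

    with open(d / "piev.tsv", "w") as fh:
        fh.write("name\tchrom\tstart\tend\ttype\tcandidate_genes\ttolerance_bp\n")
        for e in lay.piev:
            genes = ";".join(e.candidate_genes) or "."
            fh.write(f"{e.name}\t{e.region.chrom}\t{e.region.start}\t{e.region.end}\t"
                     f"{e.cnv_type}\t{genes}\t{e.breakpoint_tolerance_bp}\n")

    return d


# ---------------------------------------------------------------------------
# planted CNVs

def generate_labeled_cnvs(spec: FixtureSpec) -> List[PlantedCNV]:
    """Plant a balanced labeled CNV set over the bundle's evidence slots.

    Pathogenic recipes overlap syndrome / pathogenic-patient / morbid-gene
    evidence; benign recipes sit on recurrent control regions, not-enriched
    morbidity regions or gene deserts.  Each record carries the exact set
    of criteria it was designed to fire and its expected class.
    """
    lay = _build_layout(spec)
    build = spec.genome_build
    out: List[PlantedCNV] = []

    path_recipes = ["syndrome", "patient_full", "hi_deletion", "patient_partial",
                    "amplification"]
    loss_patient = [iv for i, iv in enumerate(lay.patient_slots) if i % 2 == 0]
    gain_enriched_morb = [iv for i, iv in enumerate(lay.morbidity_slots) if i % 4 == 0]

    for i in range(spec.n_pathogenic_cnvs):
        recipe = path_recipes[i % len(path_recipes)]
        j = i // len(path_recipes)
        sid = f"P{i:04d}"
        if recipe == "syndrome":
            region = lay.syndrome_slots[j % len(lay.syndrome_slots)]
            idx = j % len(lay.syndrome_slots)
            t = lay.syndromes[idx].cnv_type
            rec = CNVRecord(region, t, copy_number=1 if t is CNVType.LOSS else 3,
                            inheritance=Inheritance.DE_NOVO, sample_id=sid,
                            genome_build=build)
            intended = {"P_SYNDROME", "M_GENE_MORBID", "m_ABSENT_CONTROLS",
                        "m_SIZE_GT_1MB", "I_DENOVO"}
            expected: Union[int, str] = 5
        elif recipe == "patient_full":
            idx = j % len(lay.patient_slots)
            region = lay.patient_slots[idx]
            t = lay.patients[idx].cnv_type
            rec = CNVRecord(region, t, inheritance=Inheritance.UNKNOWN,
                            sample_id=sid, genome_build=build)
            intended = {"P_FULL_OVERLAP_PATHOGENIC", "m_ABSENT_CONTROLS",
                        "m_SIZE_GT_1MB", "mb_NO_MORBID_GENE"}
            expected = 5
        elif recipe == "hi_deletion":
            slot_iv, gene = lay.hi_slots[j % len(lay.hi_slots)]
            iv = GenomicInterval(gene.interval.chrom, gene.interval.start - 20_000,
                                 gene.interval.end + 20_000)
            rec = CNVRecord(iv, CNVType.LOSS, copy_number=1,
                            inheritance=Inheritance.DE_NOVO, sample_id=sid,
                            genome_build=build)
            intended = {"M_HI_5PRIME_DEL", "M_GENE_MORBID", "m_ABSENT_CONTROLS",
                        "I_DENOVO"}
            expected = 5
        elif recipe == "patient_partial":
            region = loss_patient[j % len(loss_patient)]
            iv = GenomicInterval(region.chrom, region.start + 500_000,
                                 region.start + 1_500_000)
            rec = CNVRecord(iv, CNVType.LOSS, copy_number=0,
                            inheritance=Inheritance.DE_NOVO, sample_id=sid,
                            genome_build=build)
            intended = {"m_PARTIAL_PATHOGENIC", "M_HOMOZYGOUS_DEL",
                        "m_ABSENT_CONTROLS", "MB_NO_GENES", "I_DENOVO"}
            expected = 4
        else:  # amplification over an enriched GAIN morbidity region
            region = gain_enriched_morb[j % len(gain_enriched_morb)]
            rec = CNVRecord(region, CNVType.GAIN, copy_number=4,
                            inheritance=Inheritance.INHERITED_AFFECTED_PARENT,
                            sample_id=sid, genome_build=build)
            intended = {"M_AMPLIFICATION", "m_MORBIDITY_ENRICHED",
                        "m_ABSENT_CONTROLS", "MB_NO_GENES", "I_AFFECTED"}
            expected = 4
        out.append(PlantedCNV(rec, Truth.PATHOGENIC, frozenset(intended),
                              expected, recipe))

    benign_recipes = ["polymorphism", "control_once", "not_enriched",
                      "control_near"]
    recurrent_controls = [(i, iv) for i, iv in enumerate(lay.control_slots) if i % 2 == 0]
    singleton_controls = [(i, iv) for i, iv in enumerate(lay.control_slots) if i % 2 == 1]
    not_enriched_morb = [(i, iv) for i, iv in enumerate(lay.morbidity_slots) if i % 4 >= 2]

    for i in range(spec.n_benign_cnvs):
        recipe = benign_recipes[i % len(benign_recipes)]
        j = i // len(benign_recipes)
        sid = f"B{i:04d}"
        if recipe == "polymorphism":
            idx, iv = recurrent_controls[j % len(recurrent_controls)]
            t = lay.controls[idx].cnv_type
            rec = CNVRecord(iv, t, inheritance=Inheritance.UNKNOWN,
                            sample_id=sid, genome_build=build)
            intended = {"B_POLYMORPHISM", "MB_NO_GENES"}
            expected = 1
        elif recipe == "control_once":
            idx, iv = singleton_controls[j % len(singleton_controls)]
            t = lay.controls[idx].cnv_type
            rec = CNVRecord(iv, t, inheritance=Inheritance.UNKNOWN,
                            sample_id=sid, genome_build=build)
            intended = {"MB_CONTROL_80", "MB_NO_GENES"}
            expected = 2
        elif recipe == "not_enriched":
            idx, iv = not_enriched_morb[j % len(not_enriched_morb)]
            t = lay.morbidity[idx].cnv_type
            rec = CNVRecord(
                iv, t, inheritance=Inheritance.INHERITED_ASYMPTOMATIC_PARENT,
                sample_id=sid, genome_build=build)
            intended = {"mb_MORBIDITY_NOT_ENRICHED", "m_ABSENT_CONTROLS",
                        "MB_NO_GENES", "I_ASYMPTOMATIC"}
            expected = 2
        else:  # high-overlap (not exact) singleton control match
            idx, iv = singleton_controls[j % len(singleton_controls)]
            t = lay.controls[idx].cnv_type
            wide = GenomicInterval(iv.chrom, iv.start, iv.end + 40_000)
            rec = CNVRecord(
                wide, t, inheritance=Inheritance.INHERITED_ASYMPTOMATIC_PARENT,
                sample_id=sid, genome_build=build)
            intended = {"MB_CONTROL_80", "MB_NO_GENES", "I_ASYMPTOMATIC"}
            expected = 1
        out.append(PlantedCNV(rec, Truth.BENIGN, frozenset(intended),
                              expected, recipe))

    return out


def generate_piev_cnvs(spec: FixtureSpec, n: int = 60) -> List[PlantedCNV]:
    """Plant CNVs matching the recurrent-CNV catalog, with breakpoints
    jittered within each entry's tolerance.  All must classify as PIEV."""
    lay = _build_layout(spec)
    if not lay.piev:
        return []
    rng = np.random.default_rng(spec.seed + 7)
    out: List[PlantedCNV] = []
    for i in range(n):
        entry = lay.piev[i % len(lay.piev)]
        if entry.cnv_type == "BOTH":
            t = CNVType.LOSS if i % 2 == 0 else CNVType.GAIN
        else:
            t = CNVType[entry.cnv_type]
        j1 = int(rng.integers(-50_000, 50_001))
        j2 = int(rng.integers(-50_000, 50_001))
        iv = GenomicInterval(entry.region.chrom, entry.region.start + j1,
                             entry.region.end + j2)
        rec = CNVRecord(iv, t, inheritance=Inheritance.DE_NOVO,
                        sample_id=f"V{i:04d}", genome_build=spec.genome_build)
        out.append(PlantedCNV(rec, Truth.PATHOGENIC, frozenset(), "PIEV",
                              f"piev:{entry.name}"))
    return out


# ---------------------------------------------------------------------------
# trios

def generate_trio(rng: np.random.Generator, n_proband: int = 8,
                  match_overlap: float = 0.70) -> TrioInput:
    """One random trio: a share of proband CNVs copied (exactly or jittered)
    into a parent, the rest unique; parents also carry private CNVs."""
    def random_cnv(sample: str) -> CNVRecord:
        chrom = str(int(rng.integers(1, 5)))
        start = int(rng.integers(0, 50_000_000))
        length = int(rng.integers(20_000, 2_000_000))
        t = CNVType.LOSS if rng.random() < 0.5 else CNVType.GAIN
        return CNVRecord(GenomicInterval(chrom, start, start + length), t,
                         sample_id=sample)

    proband = [random_cnv("proband") for _ in range(n_proband)]
    mother: List[CNVRecord] = []
    father: List[CNVRecord] = []
    for cnv in proband:
        u = rng.random()
        if u < 0.35:  # exact parental copy
            target = mother if rng.random() < 0.5 else father
            target.append(CNVRecord(cnv.interval, cnv.cnv_type, sample_id="parent"))
        elif u < 0.55:  # jittered copy, may or may not clear the threshold
            iv = cnv.interval
            shift = int(rng.integers(0, max(2, iv.length)))
            jit = GenomicInterval(iv.chrom, iv.start + shift, iv.end + shift)
            target = mother if rng.random() < 0.5 else father
            target.append(CNVRecord(jit, cnv.cnv_type, sample_id="parent"))
    for _ in range(int(rng.integers(0, 4))):
        mother.append(random_cnv("mother"))
    for _ in range(int(rng.integers(0, 4))):
        father.append(random_cnv("father"))
    return TrioInput(proband=tuple(proband), mother=tuple(mother),
                     father=tuple(father), match_overlap=match_overlap)
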