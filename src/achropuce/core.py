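"""Domain types and coordinate conventions shared by every other module.

All coordinates are 0-based half-open internally (BED convention), so
``length = end - start`` and interval intersection is plain integer
arithmetic.  Chromosome names are stored without a ``chr`` prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Union

SCORE_EPS = 1e-9
"""Tolerance for comparing sums of criterion weights against thresholds.

Scores are sums of 0.45 / 0.225 multiples; binary floats representing those
sums must still compare equal to the 0.9 / 1.0 class thresholds, hence every
threshold comparison in the package allows this slack.
"""


class InputError(ValueError):
    """A user-supplied value violates a domain invariant."""


class ParseError(InputError):
    """A string or file token could not be interpreted."""


class SchemaError(InputError):
    """A reference file is missing a mandatory column or breaks an invariant."""


class BuildMismatchError(InputError):
    """Query and reference bundle disagree on genome build."""


class CNVType(str, Enum):
    LOSS = "LOSS"
    GAIN = "GAIN"


class RefSource(str, Enum):
    CONTROL = "CONTROL"
    PATIENT = "PATIENT"
    SYNDROME = "SYNDROME"


class Inheritance(str, Enum):
    DE_NOVO = "DE_NOVO"
    INHERITED_AFFECTED_PARENT = "INHERITED_AFFECTED_PARENT"
    INHERITED_MOSAIC_PARENT = "INHERITED_MOSAIC_PARENT"
    INHERITED_ASYMPTOMATIC_PARENT = "INHERITED_ASYMPTOMATIC_PARENT"
    UNKNOWN = "UNKNOWN"


class GenomeBuild(str, Enum):
    GRCH37 = "GRCh37"
    GRCH38 = "GRCh38"


class Tier(str, Enum):
    DIRECT_PATHOGENIC = "DIRECT_PATHOGENIC"
    MAJOR_PATHOGENIC = "MAJOR_PATHOGENIC"
    MINOR_PATHOGENIC = "MINOR_PATHOGENIC"
    DIRECT_BENIGN = "DIRECT_BENIGN"
    MAJOR_BENIGN = "MAJOR_BENIGN"
    MINOR_BENIGN = "MINOR_BENIGN"
    INHERITANCE = "INHERITANCE"


PATHOGENIC_TIERS = frozenset(
    {Tier.DIRECT_PATHOGENIC, Tier.MAJOR_PATHOGENIC, Tier.MINOR_PATHOGENIC}
)
BENIGN_TIERS = frozenset({Tier.DIRECT_BENIGN, Tier.MAJOR_BENIGN, Tier.MINOR_BENIGN})

#: The sixth class: recurrent NDD CNVs with incomplete penetrance and variable
#: expressivity.  Catalog-driven, overrides the numeric score.
PIEV_CLASS = "PIEV"

FinalClass = Union[int, str]  # 1..5 or PIEV_CLASS


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: strip ``chr`` prefix, map 23/24 to X/Y,
    uppercase the sex/mito chromosomes.

    >>> normalize_chrom("chr1")
    '1'
    >>> normalize_chrom("x")
    'X'
    """
    if not isinstance(name, str) or not name.strip():
        raise InputError("chromosome name must be a non-empty string")
    name = name.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if not name:
        raise InputError("chromosome name is empty after stripping 'chr'")
    if name == "23":
        return "X"
    if name == "24":
        return "Y"
    if name.upper() in ("X", "Y", "MT", "M"):
        return "MT" if name.upper() in ("MT", "M") else name.upper()
    return name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise InputError(f"coordinates must be integers: {self.start}-{self.end}")
        if self.start < 0:
            raise InputError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise InputError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def intersection_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """True when ``other`` lies fully inside this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def expanded(self, pad_bp: int) -> "GenomicInterval":
        """Symmetrically widen by ``pad_bp`` on each side (clamped at 0)."""
        return GenomicInterval(self.chrom, max(0, self.start - pad_bp), self.end + pad_bp)

    def __str__(self) -> str:  # 1-based inclusive display, UCSC style
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a half-open interval (``end - start``)."""
    return iv.length


@dataclass(frozen=True)
class CNVRecord:
    """A query copy-number variant.

    ``copy_number`` must agree with ``cnv_type`` when present (a loss has
    fewer than two copies, a gain more); disagreements are input errors,
    never silently fixed.
    """

    interval: GenomicInterval
    cnv_type: CNVType
    copy_number: Optional[int] = None
    inheritance: Inheritance = Inheritance.UNKNOWN
    sample_id: Optional[str] = None
    genome_build: GenomeBuild = GenomeBuild.GRCH37

    def __post_init__(self) -> None:
        cn = self.copy_number
        if cn is not None:
            if not isinstance(cn, int) or cn < 0:
                raise InputError(f"copy_number must be a non-negative integer, got {cn}")
            if self.cnv_type is CNVType.LOSS and cn >= 2:
                raise InputError(f"LOSS with copy_number {cn} (must be < 2)")
            if self.cnv_type is CNVType.GAIN and cn <= 2:
                raise InputError(f"GAIN with copy_number {cn} (must be > 2)")


@dataclass(frozen=True)
class ReferenceVariant:
    """A variant from a control, patient or syndrome reference set."""

    interval: GenomicInterval
    cnv_type: CNVType
    source: RefSource
    identifier: str
    label: Optional[int] = None  # 5-tier class for PATIENT/SYNDROME entries
    observation_count: int = 0
    population_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source is RefSource.CONTROL and self.observation_count < 1:
            raise InputError(
                f"control variant {self.identifier} needs observation_count >= 1"
            )
        if self.source is RefSource.SYNDROME and self.label not in (4, 5):
            raise InputError(
                f"syndrome region {self.identifier} must carry label 4 or 5"
            )
        if self.label is not None and self.label not in (1, 2, 3, 4, 5):
            raise InputError(f"label must be a 5-tier class, got {self.label}")
        pf = self.population_frequency
        if pf is not None and not (0.0 <= pf <= 1.0):
            raise InputError(f"population_frequency must lie in [0,1], got {pf}")


@dataclass(frozen=True)
class MorbidityRegion:
    """A case–control CNV frequency region (developmental-delay morbidity map)."""

    interval: GenomicInterval
    cnv_type: CNVType
    case_count: int
    case_total: int
    control_count: int
    control_total: int

    def __post_init__(self) -> None:
        if self.case_total <= 0 or self.control_total <= 0:
            raise InputError("case_total and control_total must be positive")
        if not (0 <= self.case_count <= self.case_total):
            raise InputError("case_count must lie in [0, case_total]")
        if not (0 <= self.control_count <= self.control_total):
            raise InputError("control_count must lie in [0, control_total]")

    @property
    def case_frequency(self) -> float:
        return self.case_count / self.case_total

    @property
    def control_frequency(self) -> float:
        return self.control_count / self.control_total


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with exon structure and the flags the criteria consume.

    Dosage-sensitivity display scores (pHaplo, pTriplo, pLI, LOEUF) are
    carried as pass-through annotation only; no criterion reads them.
    """

    symbol: str
    interval: GenomicInterval
    strand: str
    exons: tuple  # tuple[GenomicInterval, ...]
    is_morbid: bool = False
    is_haploinsufficient: bool = False
    is_pseudogene_or_uncharacterized: bool = False
    display_scores: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or not self.interval.contains(ex):
                raise SchemaError(f"gene {self.symbol}: exon {ex} outside gene span")
            if prev_end is not None and ex.start < prev_end:
                raise SchemaError(
                    f"gene {self.symbol}: exons overlap or are unsorted at {ex}"
                )
            prev_end = ex.end

    @property
    def five_prime_position(self) -> int:
        """Strand-aware 5' terminal base (0-based)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass(frozen=True)
class PIEVEntry:
    """One recurrent-CNV catalog entry (incomplete penetrance / variable
    expressivity)."""

    name: str
    region: GenomicInterval
    cnv_type: str  # "LOSS", "GAIN" or "BOTH"
    candidate_genes: tuple = ()
    breakpoint_tolerance_bp: int = 0

    def __post_init__(self) -> None:
        if self.cnv_type not in ("LOSS", "GAIN", "BOTH"):
            raise InputError(f"PIEV type must be LOSS/GAIN/BOTH, got {self.cnv_type}")
        if self.breakpoint_tolerance_bp < 0:
            raise InputError("breakpoint_tolerance_bp must be >= 0")
        object.__setattr__(self, "candidate_genes", tuple(self.candidate_genes))

    def accepts_type(self, t: CNVType) -> bool:
        return self.cnv_type == "BOTH" or self.cnv_type == t.value


@dataclass(frozen=True)
class CriterionHit:
    """One fired classification criterion, with its signed weight and a
    human-readable evidence trace."""

    criterion_id: str
    tier: Tier
    weight: float
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.tier in PATHOGENIC_TIERS and self.weight <= 0:
            raise InputError(
                f"{self.criterion_id}: pathogenic tier requires positive weight"
            )
        if self.tier in BENIGN_TIERS and self.weight >= 0:
            raise InputError(
                f"{self.criterion_id}: benign tier requires negative weight"
            )
        if self.tier is Tier.INHERITANCE and self.weight == 0:
            raise InputError(f"{self.criterion_id}: inheritance weight must be nonzero")


@dataclass(frozen=True)
class ClassificationResult:
    """Final verdict for one CNV: class, additive score, fired criteria."""

    cnv: CNVRecord
    final_class: FinalClass
    score: float
    hits: tuple  # tuple[CriterionHit, ...]
    piev_match: Optional[PIEVEntry] = None
    piev_overlap: Optional[float] = None
    gene_hits: tuple = ()  # tuple[(GeneAnnotation, impacted_exon_count), ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "hits", tuple(self.hits))
        object.__setattr__(self, "gene_hits", tuple(self.gene_hits))
        total = sum(h.weight for h in self.hits)
        if abs(total - self.score) > SCORE_EPS:
            raise InputError(
                f"score {self.score} does not equal sum of hit weights {total}"
            )
        if (self.final_class == PIEV_CLASS) != (self.piev_match is not None):
            raise InputError("final_class is PIEV exactly when a PIEV match exists")
        if self.final_class != PIEV_CLASS and self.final_class not in (1, 2, 3, 4, 5):
            raise InputError(f"final_class must be 1..5 or PIEV, got {self.final_class}")


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion tallies with VUS kept in separate per-truth strata."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    vus_pathogenic: int = 0
    vus_benign: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "vus_pathogenic", "vus_benign"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    @property
    def total_pathogenic(self) -> int:
        return self.tp + self.fn + self.vus_pathogenic

    @property
    def total_benign(self) -> int:
        return self.tn + self.fp + self.vus_benign
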