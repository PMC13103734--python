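"""Readers and writers: CNV call tables, reference bundles, PIEV catalogs,
cytoband maps, config files and result exports.

Conventions
-----------
* Internal coordinates are always 0-based half-open.
* ``chr:start-end`` region strings and 1-based TSV dialects are converted on
  read; BED files are taken as-is (they already use the native convention).
* Reference bundle tables (controls / patients / syndromes / morbidity /
  PIEV) are headered TSVs in 0-based half-open coordinates; genes are BED12
  plus four extra columns (morbid flag, haploinsufficiency flag, pseudogene
  flag, semicolon-joined ``name=value`` display scores).
* Malformed rows are collected with their line numbers and skipped, never
  silently dropped and never fatal to a batch.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, IO, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml
from intervaltree import IntervalTree

from .core import (
    CNVRecord,
    CNVType,
    ClassificationResult,
    CriterionHit,
    GeneAnnotation,
    GenomeBuild,
    GenomicInterval,
    Inheritance,
    InputError,
    MorbidityRegion,
    PIEVEntry,
    PIEV_CLASS,
    ParseError,
    ReferenceVariant,
    RefSource,
    SchemaError,
    Tier,
    normalize_chrom,
)
from .overlap import IntervalIndex

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# dialects and vocabulary

DEFAULT_TYPE_VOCABULARY: Dict[str, CNVType] = {
    "del": CNVType.LOSS,
    "deletion": CNVType.LOSS,
    "loss": CNVType.LOSS,
    "dup": CNVType.GAIN,
    "duplication": CNVType.GAIN,
    "gain": CNVType.GAIN,
}

INHERITANCE_VOCABULARY: Dict[str, Inheritance] = {
    "de novo": Inheritance.DE_NOVO,
    "de_novo": Inheritance.DE_NOVO,
    "denovo": Inheritance.DE_NOVO,
    "affected": Inheritance.INHERITED_AFFECTED_PARENT,
    "inherited_affected_parent": Inheritance.INHERITED_AFFECTED_PARENT,
    "mosaic": Inheritance.INHERITED_MOSAIC_PARENT,
    "inherited_mosaic_parent": Inheritance.INHERITED_MOSAIC_PARENT,
    "asymptomatic": Inheritance.INHERITED_ASYMPTOMATIC_PARENT,
    "healthy": Inheritance.INHERITED_ASYMPTOMATIC_PARENT,
    "inherited_asymptomatic_parent": Inheritance.INHERITED_ASYMPTOMATIC_PARENT,
    "unknown": Inheritance.UNKNOWN,
    "": Inheritance.UNKNOWN,
    ".": Inheritance.UNKNOWN,
}

BASE_0_HALF_OPEN = "0-half-open"
BASE_1_INCLUSIVE = "1-inclusive"


@dataclass(frozen=True)
class CNVTableDialect:
    """How to interpret a delimited CNV table.

    ``column_map`` maps the logical fields chrom/start/end/type (mandatory)
    and copy_number/inheritance/sample_id (optional) to header names, or to
    integer column indices for headerless files.
    """

    coordinate_base: str = BASE_1_INCLUSIVE
    column_map: Mapping[str, Union[str, int]] = field(
        default_factory=lambda: {
            "chrom": "chrom",
            "start": "start",
            "end": "end",
            "type": "type",
            "copy_number": "copy_number",
            "inheritance": "inheritance",
            "sample_id": "sample_id",
        }
    )
    type_vocabulary: Mapping[str, CNVType] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_VOCABULARY)
    )
    delimiter: str = "\t"
    has_header: bool = True

    def __post_init__(self) -> None:
        for f in ("chrom", "start", "end", "type"):
            if f not in self.column_map:
                raise SchemaError(f"dialect column_map is missing mandatory field {f!r}")
        if self.coordinate_base not in (BASE_0_HALF_OPEN, BASE_1_INCLUSIVE):
            raise SchemaError(f"unknown coordinate base {self.coordinate_base!r}")


DEFAULT_TSV_DIALECT = CNVTableDialect()

#: headerless BED: chrom / start / end / type [/ copy_number ...], native coords
BED_DIALECT = CNVTableDialect(
    coordinate_base=BASE_0_HALF_OPEN,
    column_map={"chrom": 0, "start": 1, "end": 2, "type": 3, "copy_number": 4,
                "inheritance": 5, "sample_id": 6},
    has_header=False,
)


def dialect_for_path(path: Union[str, Path]) -> CNVTableDialect:
    """Pick the conventional dialect for a file name (.bed -> BED, else
    headered 1-based TSV)."""
    if str(path).lower().endswith(".bed"):
        return BED_DIALECT
    return DEFAULT_TSV_DIALECT


# ---------------------------------------------------------------------------
# region strings

_REGION_RE = re.compile(r"^\s*(?P<chrom>[^:\s]+)\s*:\s*(?P<start>[\d,_ ]+)\s*-\s*(?P<end>[\d,_ ]+)\s*$")


def parse_region_string(
    s: str, base_convention: str = BASE_1_INCLUSIVE
) -> GenomicInterval:
    """Parse a UCSC-style ``chr:start-end`` region string.

    Thousands separators (commas, underscores, spaces) are tolerated.  With
    the default 1-based inclusive convention the start is shifted down by
    one to the internal half-open representation.
    """
    m = _REGION_RE.match(s or "")
    if not m:
        raise ParseError(f"malformed region string: {s!r}")
    chrom = normalize_chrom(m.group("chrom"))
    start = int(re.sub(r"[,_ ]", "", m.group("start")))
    end = int(re.sub(r"[,_ ]", "", m.group("end")))
    if base_convention == BASE_1_INCLUSIVE:
        start -= 1
    elif base_convention != BASE_0_HALF_OPEN:
        raise ParseError(f"unknown coordinate convention {base_convention!r}")
    if start < 0:
        raise ParseError(f"region start out of range in {s!r}")
    if end <= start:
        raise ParseError(f"region end {end} does not exceed start in {s!r}")
    return GenomicInterval(chrom, start, end)


def format_region(iv: GenomicInterval, base_convention: str = BASE_1_INCLUSIVE) -> str:
    if base_convention == BASE_1_INCLUSIVE:
        return f"{iv.chrom}:{iv.start + 1}-{iv.end}"
    return f"{iv.chrom}:{iv.start}-{iv.end}"


# ---------------------------------------------------------------------------
# CNV tables

@dataclass(frozen=True)
class RowError:
    line_number: int
    message: str
    raw: str = ""


def _cell(row: Sequence[str], header: Optional[Mapping[str, int]],
          column_map: Mapping[str, Union[str, int]], fieldname: str) -> Optional[str]:
    key = column_map.get(fieldname)
    if key is None:
        return None
    if isinstance(key, int):
        idx = key
    else:
        if header is None or key not in header:
            return None
        idx = header[key]
    if idx >= len(row):
        return None
    val = row[idx].strip()
    return val if val not in ("", ".") else None


def read_cnv_table(
    source: Union[str, Path, IO[str]],
    dialect: Optional[CNVTableDialect] = None,
    genome_build: GenomeBuild = GenomeBuild.GRCH37,
) -> Tuple[List[CNVRecord], List[RowError]]:
    """Read a delimited CNV table into records plus per-row errors.

    Valid rows become :class:`CNVRecord` in input order; invalid rows are
    collected with their 1-based line numbers.  ``records + errors`` always
    accounts for every data row.
    """
    if dialect is None:
        dialect = dialect_for_path(source) if isinstance(source, (str, Path)) else DEFAULT_TSV_DIALECT
    close = False
    if isinstance(source, (str, Path)):
        stream: IO[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        stream = source
    try:
        reader = csv.reader(stream, delimiter=dialect.delimiter)
        rows = list(reader)
    finally:
        if close:
            stream.close()

    header: Optional[Dict[str, int]] = None
    start_line = 1
    if dialect.has_header:
        if not rows:
            return [], []
        header = {name.strip(): i for i, name in enumerate(rows[0])}
        rows = rows[1:]
        start_line = 2

    vocab = {k.lower(): v for k, v in dialect.type_vocabulary.items()}
    # canonical enum names always accepted
    vocab.setdefault("loss", CNVType.LOSS)
    vocab.setdefault("gain", CNVType.GAIN)

    records: List[CNVRecord] = []
    errors: List[RowError] = []
    for offset, row in enumerate(rows):
        line_no = start_line + offset
        raw = dialect.delimiter.join(row)
        if not row or all(not c.strip() for c in row):
            continue
        try:
            chrom = _cell(row, header, dialect.column_map, "chrom")
            start_s = _cell(row, header, dialect.column_map, "start")
            end_s = _cell(row, header, dialect.column_map, "end")
            type_s = _cell(row, header, dialect.column_map, "type")
            if chrom is None or start_s is None or end_s is None or type_s is None:
                raise ParseError("missing chrom/start/end/type value")
            start, end = int(start_s), int(end_s)
            if dialect.coordinate_base == BASE_1_INCLUSIVE:
                start -= 1
            cnv_type = vocab.get(type_s.lower())
            if cnv_type is None:
                raise ParseError(f"unknown CNV type token {type_s!r}")
            cn_s = _cell(row, header, dialect.column_map, "copy_number")
            inh_s = _cell(row, header, dialect.column_map, "inheritance")
            inheritance = Inheritance.UNKNOWN
            if inh_s is not None:
                if inh_s.lower() not in INHERITANCE_VOCABULARY:
                    raise ParseError(f"unknown inheritance token {inh_s!r}")
                inheritance = INHERITANCE_VOCABULARY[inh_s.lower()]
            records.append(
                CNVRecord(
                    interval=GenomicInterval(chrom, start, end),
                    cnv_type=cnv_type,
                    copy_number=int(cn_s) if cn_s is not None else None,
                    inheritance=inheritance,
                    sample_id=_cell(row, header, dialect.column_map, "sample_id"),
                    genome_build=genome_build,
                )
            )
        except (InputError, ValueError) as exc:
            errors.append(RowError(line_number=line_no, message=str(exc), raw=raw))
    return records, errors


# ---------------------------------------------------------------------------
# reference bundle

BUNDLE_FILES = {
    "controls": "controls.tsv",
    "patients": "patients.tsv",
    "syndromes": "syndromes.tsv",
    "morbidity": "morbidity.tsv",
    "genes": "genes.bed",
    "piev": "piev.tsv",
    "meta": "meta.json",
}


class ReferenceBundle:
    """All reference sets plus the interval indexes built over them."""

    def __init__(
        self,
        controls: Sequence[ReferenceVariant] = (),
        patients: Sequence[ReferenceVariant] = (),
        syndromes: Sequence[ReferenceVariant] = (),
        morbidity: Sequence[MorbidityRegion] = (),
        genes: Sequence[GeneAnnotation] = (),
        piev: Sequence[PIEVEntry] = (),
        genome_build: GenomeBuild = GenomeBuild.GRCH37,
    ):
        self.controls = list(controls)
        self.patients = list(patients)
        self.syndromes = list(syndromes)
        self.morbidity = list(morbidity)
        self.genes = list(genes)
        self.piev = list(piev)
        self.genome_build = genome_build

        self.control_index = IntervalIndex(self.controls)
        self.patient_index = IntervalIndex(self.patients)
        self.syndrome_index = IntervalIndex(self.syndromes)
        self._gene_trees: Dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._gene_trees.setdefault(g.interval.chrom, IntervalTree())
            tree.addi(g.interval.start, g.interval.end, g)
        self.gene_by_symbol: Dict[str, GeneAnnotation] = {g.symbol: g for g in self.genes}

    @property
    def has_gene_data(self) -> bool:
        return bool(self.genes)

    def genes_overlapping(self, iv: GenomicInterval) -> List[GeneAnnotation]:
        tree = self._gene_trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(iv.start, iv.end)]
        hits.sort(key=lambda g: (g.interval.start, g.symbol))
        return hits

    def source_counts(self) -> Dict[str, int]:
        return {
            "controls": len(self.controls),
            "patients": len(self.patients),
            "syndromes": len(self.syndromes),
            "morbidity": len(self.morbidity),
            "genes": len(self.genes),
            "piev": len(self.piev),
        }


def _require_columns(df: pd.DataFrame, cols: Iterable[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing mandatory column(s) {', '.join(missing)}")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_type(token: str, where: str) -> CNVType:
    t = DEFAULT_TYPE_VOCABULARY.get(token.strip().lower())
    if t is None:
        if token.strip().upper() in ("LOSS", "GAIN"):
            return CNVType[token.strip().upper()]
        raise SchemaError(f"{where}: unknown CNV type {token!r}")
    return t


def read_reference_bundle(directory: Union[str, Path]) -> ReferenceBundle:
    """Load a reference bundle from a directory of TSV/BED files.

    Missing optional sources (any file except ``meta.json``) yield empty
    sets rather than errors; counts per source are logged.
    """
    d = Path(directory)
    if not d.is_dir():
        raise InputError(f"bundle directory not found: {d}")

    build = GenomeBuild.GRCH37
    meta_path = d / BUNDLE_FILES["meta"]
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        build = GenomeBuild(meta.get("genome_build", "GRCh37"))

    controls: List[ReferenceVariant] = []
    p = d / BUNDLE_FILES["controls"]
    if p.exists():
        df = _read_tsv(p)
        _require_columns(df, ["chrom", "start", "end", "type", "observation_count", "id"], p.name)
        for row in df.itertuples(index=False):
            freq = getattr(row, "population_frequency", "")
            controls.append(
                ReferenceVariant(
                    interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                    cnv_type=_parse_type(row.type, p.name),
                    source=RefSource.CONTROL,
                    identifier=str(row.id),
                    observation_count=int(row.observation_count),
                    population_frequency=float(freq) if freq not in ("", ".") else None,
                )
            )

    def _read_variants(fname: str, source: RefSource) -> List[ReferenceVariant]:
        path = d / fname
        if not path.exists():
            return []
        df = _read_tsv(path)
        _require_columns(df, ["chrom", "start", "end", "type", "label", "id"], path.name)
        out = []
        for row in df.itertuples(index=False):
            out.append(
                ReferenceVariant(
                    interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                    cnv_type=_parse_type(row.type, path.name),
                    source=source,
                    identifier=str(row.id),
                    label=int(row.label) if row.label not in ("", ".") else None,
                )
            )
        return out

    patients = _read_variants(BUNDLE_FILES["patients"], RefSource.PATIENT)
    syndromes = _read_variants(BUNDLE_FILES["syndromes"], RefSource.SYNDROME)

    morbidity: List[MorbidityRegion] = []
    p = d / BUNDLE_FILES["morbidity"]
    if p.exists():
        df = _read_tsv(p)
        _require_columns(
            df,
            ["chrom", "start", "end", "type", "case_count", "case_total",
             "control_count", "control_total"],
            p.name,
        )
        for row in df.itertuples(index=False):
            morbidity.append(
                MorbidityRegion(
                    interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                    cnv_type=_parse_type(row.type, p.name),
                    case_count=int(row.case_count),
                    case_total=int(row.case_total),
                    control_count=int(row.control_count),
                    control_total=int(row.control_total),
                )
            )

    genes = _read_gene_bed(d / BUNDLE_FILES["genes"]) if (d / BUNDLE_FILES["genes"]).exists() else []
    piev = read_piev_catalog(d / BUNDLE_FILES["piev"]) if (d / BUNDLE_FILES["piev"]).exists() else []

    bundle = ReferenceBundle(
        controls=controls, patients=patients, syndromes=syndromes,
        morbidity=morbidity, genes=genes, piev=piev, genome_build=build,
    )
    logger.info("loaded reference bundle from %s: %s", d, bundle.source_counts())
    return bundle


def _read_gene_bed(path: Path) -> List[GeneAnnotation]:
    """BED12 + 4 extra columns: is_morbid, is_haploinsufficient,
    is_pseudogene, display scores (``name=value;...`` or ``.``)."""
    genes: List[GeneAnnotation] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise SchemaError(f"{path.name}:{line_no}: expected >= 12 BED columns, got {len(f)}")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in f[11].rstrip(",").split(",") if x]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise SchemaError(f"{path.name}:{line_no}: block count mismatch for {name}")
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size)
                for off, size in zip(starts, sizes)
            )
            is_morbid = len(f) > 12 and f[12] == "1"
            is_hi = len(f) > 13 and f[13] == "1"
            is_pseudo = len(f) > 14 and f[14] == "1"
            scores = None
            if len(f) > 15 and f[15] not in ("", "."):
                scores = {}
                for item in f[15].split(";"):
                    if item:
                        k, v = item.split("=")
                        scores[k] = float(v)
            try:
                genes.append(
                    GeneAnnotation(
                        symbol=name,
                        interval=GenomicInterval(chrom, start, end),
                        strand=strand,
                        exons=exons,
                        is_morbid=is_morbid,
                        is_haploinsufficient=is_hi,
                        is_pseudogene_or_uncharacterized=is_pseudo,
                        display_scores=scores,
                    )
                )
            except SchemaError as exc:
                raise SchemaError(f"{path.name}:{line_no}: {exc}") from exc
    return genes


def read_piev_catalog(path: Union[str, Path]) -> List[PIEVEntry]:
    """Editable recurrent-CNV catalog TSV: name, chrom, start, end, type,
    candidate_genes (semicolon list), tolerance_bp."""
    df = _read_tsv(Path(path))
    _require_columns(
        df, ["name", "chrom", "start", "end", "type", "candidate_genes", "tolerance_bp"],
        Path(path).name,
    )
    out: List[PIEVEntry] = []
    for row in df.itertuples(index=False):
        t = row.type.strip().upper()
        if t not in ("BOTH",):
            t = _parse_type(row.type, Path(path).name).value
        genes = tuple(g for g in str(row.candidate_genes).split(";") if g and g != ".")
        out.append(
            PIEVEntry(
                name=str(row.name),
                region=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                cnv_type=t,
                candidate_genes=genes,
                breakpoint_tolerance_bp=int(row.tolerance_bp),
            )
        )
    return out


# ---------------------------------------------------------------------------
# cytobands

class CytobandLookupError(LookupError):
    pass


def read_cytoband_map(source: Union[str, Path, IO[str]]) -> Dict[str, List[Tuple[int, int, str]]]:
    """Read a UCSC ``cytoBand.txt`` file (chrom, start, end, band, stain)."""
    close = False
    if isinstance(source, (str, Path)):
        stream: IO[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        stream = source
    lookup: Dict[str, List[Tuple[int, int, str]]] = {}
    try:
        for line in stream:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"malformed cytoband line: {line!r}")
            chrom = normalize_chrom(f[0])
            lookup.setdefault(chrom, []).append((int(f[1]), int(f[2]), f[3]))
    finally:
        if close:
            stream.close()
    for bands in lookup.values():
        bands.sort()
    return lookup


def cytoband_of(lookup: Mapping[str, List[Tuple[int, int, str]]], iv: GenomicInterval) -> str:
    """Band span label for an interval: ``22q11.2`` inside one band, or
    ``22q11.1q11.2`` when it straddles several."""
    bands = lookup.get(iv.chrom)
    if not bands:
        raise CytobandLookupError(f"no cytobands for chromosome {iv.chrom}")
    touched = [name for (s, e, name) in bands if min(e, iv.end) > max(s, iv.start)]
    if not touched:
        raise CytobandLookupError(f"interval {iv} outside the cytoband map")
    if touched[0] == touched[-1]:
        return f"{iv.chrom}{touched[0]}"
    return f"{iv.chrom}{touched[0]}{touched[-1]}"


# ---------------------------------------------------------------------------
# config files

def load_config_file(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON weights/thresholds config into a plain dict."""
    text = Path(path).read_text()
    if str(path).lower().endswith(".json"):
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    return data


# ---------------------------------------------------------------------------
# result export

RESULT_CSV_COLUMNS = [
    "sample_id", "chrom", "start", "end", "type", "final_class", "score",
    "criteria", "piev_name", "genes",
]


def _interval_to_dict(iv: GenomicInterval) -> dict:
    return {"chrom": iv.chrom, "start": iv.start, "end": iv.end}


def _interval_from_dict(d: dict) -> GenomicInterval:
    return GenomicInterval(d["chrom"], d["start"], d["end"])


def _gene_to_dict(g: GeneAnnotation) -> dict:
    return {
        "symbol": g.symbol,
        "interval": _interval_to_dict(g.interval),
        "strand": g.strand,
        "exons": [_interval_to_dict(e) for e in g.exons],
        "is_morbid": g.is_morbid,
        "is_haploinsufficient": g.is_haploinsufficient,
        "is_pseudogene_or_uncharacterized": g.is_pseudogene_or_uncharacterized,
        "display_scores": dict(g.display_scores) if g.display_scores else None,
    }


def _gene_from_dict(d: dict) -> GeneAnnotation:
    return GeneAnnotation(
        symbol=d["symbol"],
        interval=_interval_from_dict(d["interval"]),
        strand=d["strand"],
        exons=tuple(_interval_from_dict(e) for e in d["exons"]),
        is_morbid=d["is_morbid"],
        is_haploinsufficient=d["is_haploinsufficient"],
        is_pseudogene_or_uncharacterized=d["is_pseudogene_or_uncharacterized"],
        display_scores=d.get("display_scores") or None,
    )


def result_to_dict(r: ClassificationResult) -> dict:
    return {
        "cnv": {
            "interval": _interval_to_dict(r.cnv.interval),
            "cnv_type": r.cnv.cnv_type.value,
            "copy_number": r.cnv.copy_number,
            "inheritance": r.cnv.inheritance.value,
            "sample_id": r.cnv.sample_id,
            "genome_build": r.cnv.genome_build.value,
        },
        "final_class": r.final_class,
        "score": r.score,
        "hits": [
            {"criterion_id": h.criterion_id, "tier": h.tier.value,
             "weight": h.weight, "evidence": h.evidence}
            for h in r.hits
        ],
        "piev_match": None if r.piev_match is None else {
            "name": r.piev_match.name,
            "region": _interval_to_dict(r.piev_match.region),
            "cnv_type": r.piev_match.cnv_type,
            "candidate_genes": list(r.piev_match.candidate_genes),
            "breakpoint_tolerance_bp": r.piev_match.breakpoint_tolerance_bp,
        },
        "piev_overlap": r.piev_overlap,
        "gene_hits": [
            {"gene": _gene_to_dict(g), "impacted_exons": n} for g, n in r.gene_hits
        ],
    }


def result_from_dict(d: dict) -> ClassificationResult:
    cnv = d["cnv"]
    piev = d.get("piev_match")
    return ClassificationResult(
        cnv=CNVRecord(
            interval=_interval_from_dict(cnv["interval"]),
            cnv_type=CNVType(cnv["cnv_type"]),
            copy_number=cnv.get("copy_number"),
            inheritance=Inheritance(cnv["inheritance"]),
            sample_id=cnv.get("sample_id"),
            genome_build=GenomeBuild(cnv["genome_build"]),
        ),
        final_class=d["final_class"],
        score=d["score"],
        hits=tuple(
            CriterionHit(h["criterion_id"], Tier(h["tier"]), h["weight"], h["evidence"])
            for h in d["hits"]
        ),
        piev_match=None if piev is None else PIEVEntry(
            name=piev["name"],
            region=_interval_from_dict(piev["region"]),
            cnv_type=piev["cnv_type"],
            candidate_genes=tuple(piev["candidate_genes"]),
            breakpoint_tolerance_bp=piev["breakpoint_tolerance_bp"],
        ),
        piev_overlap=d.get("piev_overlap"),
        gene_hits=tuple(
            (_gene_from_dict(g["gene"]), g["impacted_exons"]) for g in d["gene_hits"]
        ),
    )


def write_results(
    results: Sequence[ClassificationResult],
    stream: IO[str],
    fmt: str = "csv",
) -> None:
    """Export results as CSV (summary columns) or JSON (lossless)."""
    if fmt == "csv":
        writer = csv.writer(stream)
        writer.writerow(RESULT_CSV_COLUMNS)
        for r in results:
            iv = r.cnv.interval
            writer.writerow([
                r.cnv.sample_id or "",
                iv.chrom, iv.start, iv.end,
                r.cnv.cnv_type.value,
                r.final_class,
                f"{r.score:g}",
                ";".join(h.criterion_id for h in r.hits),
                r.piev_match.name if r.piev_match else "",
                ";".join(g.symbol for g, _ in r.gene_hits),
            ])
    elif fmt == "json":
        json.dump([result_to_dict(r) for r in results], stream, indent=2)
    else:
        raise InputError(f"unknown export format {fmt!r}")


def read_results_json(stream: IO[str]) -> List[ClassificationResult]:
    return [result_from_dict(d) for d in json.load(stream)]
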