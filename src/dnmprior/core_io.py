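"""Data model, TSV/GMT readers and writers, and variant-level rules.

The trio studies this package targets report de novo mutations (DNMs) as
flat per-variant tables: one row per variant call in one child, already
annotated with a gene symbol, a functional class, the number of in-silico
damaging predictions (out of 14 tools) for missense calls, and the maximum
minor-allele frequency observed across population databases. This module
owns that record type, the rare-coding filter (drop non-exonic calls and
anything with MAF >= 1e-3), and the "extreme mutation" classification:
loss-of-function (frameshift/non-frameshift indels, stop-gain, stop-loss,
splicing SNVs) and damaging missense (>= 8 of 14 predictors).
"""

from __future__ import annotations

import enum
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

MISSING = "."

#: default threshold: variants at or above this MAF are considered common
DEFAULT_MAF_THRESHOLD = 0.001
#: default minimum number of damaging predictor votes (of 14) for D-Mis
DEFAULT_MIN_VOTES = 8
N_PREDICTORS = 14


class VariantClass(str, enum.Enum):
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    SPLICING_SNV = "splicing_snv"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


class ExtremeClass(str, enum.Enum):
    LOF = "LoF"
    DMIS = "DMis"
    OTHER = "other"


#: variant classes that count as loss-of-function. Non-frameshift indels are
#: included by default (see ``lof_includes_nonframeshift_indels``).
LOF_CLASSES = frozenset(
    {
        VariantClass.FRAMESHIFT_INDEL,
        VariantClass.NONFRAMESHIFT_INDEL,
        VariantClass.STOPGAIN,
        VariantClass.STOPLOSS,
        VariantClass.SPLICING_SNV,
    }
)


class Cohort(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class DnmRecord:
    """One de novo variant call in one trio child."""

    sample_id: str
    cohort: Cohort
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: VariantClass
    damaging_votes: int | None = None  # meaningful only for missense
    max_maf: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.damaging_votes is not None and not (
            0 <= self.damaging_votes <= N_PREDICTORS
        ):
            raise ValueError(
                f"damaging_votes must be in [0, {N_PREDICTORS}], "
                f"got {self.damaging_votes}"
            )
        if not (0.0 <= self.max_maf <= 1.0):
            raise ValueError(f"max_maf must be in [0, 1], got {self.max_maf}")


@dataclass(frozen=True)
class CohortSpec:
    """A sequenced cohort of parent-offspring trios."""

    label: Cohort
    n_trios: int

    def __post_init__(self) -> None:
        if self.n_trios <= 0:
            raise ValueError(f"n_trios must be positive, got {self.n_trios}")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. FMRP targets, CHD8 targets, PSD, known-ID).

    If a ``universe`` is given, enrichment computations restrict every set
    to it.
    """

    sets: "OrderedDict[str, frozenset[str]]"
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        fixed: "OrderedDict[str, frozenset[str]]" = OrderedDict()
        for name, genes in self.sets.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            fixed[name] = genes
        self.sets = fixed
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def restricted(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied sets."""
        uni = frozenset(universe)
        kept = OrderedDict(
            (name, genes & uni) for name, genes in self.sets.items() if genes & uni
        )
        return GeneSetCollection(sets=kept, universe=uni)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GeneCounts:
    """Per-gene extreme-mutation tallies."""

    n_lof: int = 0
    n_dmis: int = 0
    n_total_dnms: int = 0
    samples_lof: set[str] = field(default_factory=set)
    samples_dmis: set[str] = field(default_factory=set)

    @property
    def n_extreme(self) -> int:
        return self.n_lof + self.n_dmis


class ExtremeCountTable(dict):
    """gene -> :class:`GeneCounts`; only genes with >= 1 coding DNM appear."""

    def counts_for(self, gene: str) -> GeneCounts:
        return self.get(gene, GeneCounts())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

DNM_COLUMNS = (
    "sample_id",
    "cohort",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "damaging_votes",
    "max_maf",
)


class TableFormatError(ValueError):
    """A file-level problem: missing column, bad header."""


class RowParseError(ValueError):
    """A row-level problem, carrying the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def read_dnm_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[DnmRecord]:
    """Read a tab-separated DNM table into records, preserving row order.

    ``dialect`` maps canonical column names (:data:`DNM_COLUMNS`) to the
    names used in the file; unmapped columns keep their canonical name.
    """
    dialect = dict(dialect or {})
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise TableFormatError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\n").split("\t")
        col_index: dict[str, int] = {}
        for canonical in DNM_COLUMNS:
            actual = dialect.get(canonical, canonical)
            if actual not in header:
                raise TableFormatError(
                    f"{path}: required column {actual!r} (for {canonical!r}) "
                    f"not found in header"
                )
            col_index[canonical] = header.index(actual)

        records: list[DnmRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")

            def cell(name: str) -> str:
                try:
                    return fields[col_index[name]]
                except IndexError:
                    raise RowParseError(
                        lineno, f"row has too few columns for {name!r}"
                    ) from None

            vclass_raw = cell("variant_class").strip()
            try:
                vclass = VariantClass(vclass_raw)
            except ValueError:
                raise RowParseError(
                    lineno, f"unknown variant class {vclass_raw!r}"
                ) from None
            try:
                pos = int(cell("pos"))
            except ValueError:
                raise RowParseError(
                    lineno, f"unparsable pos {cell('pos')!r}"
                ) from None
            maf_raw = cell("max_maf")
            try:
                maf = 0.0 if maf_raw == MISSING else float(maf_raw)
            except ValueError:
                raise RowParseError(lineno, f"unparsable max_maf {maf_raw!r}") from None

            votes_raw = cell("damaging_votes")
            votes: int | None
            if votes_raw == MISSING or votes_raw == "":
                votes = None
            else:
                try:
                    votes = int(votes_raw)
                except ValueError:
                    raise RowParseError(
                        lineno, f"unparsable damaging_votes {votes_raw!r}"
                    ) from None
            if vclass is VariantClass.MISSENSE and votes is None:
                # missing votes on a missense row are treated as 0, not an error
                logger.warning(
                    "%s line %d: missense row without damaging_votes; using 0",
                    path,
                    lineno,
                )
                votes = 0

            records.append(
                DnmRecord(
                    sample_id=cell("sample_id").strip(),
                    cohort=Cohort(cell("cohort").strip()),
                    gene=cell("gene").strip(),
                    chrom=cell("chrom").strip(),
                    pos=pos,
                    ref=cell("ref").strip(),
                    alt=cell("alt").strip(),
                    variant_class=vclass,
                    damaging_votes=votes,
                    max_maf=maf,
                )
            )
    return records


def write_dnm_table(records: Iterable[DnmRecord], path: str | Path) -> None:
    """Write records as TSV with a header; missing values as ``.``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(DNM_COLUMNS) + "\n")
        for rec in records:
            votes = MISSING if rec.damaging_votes is None else str(rec.damaging_votes)
            fh.write(
                "\t".join(
                    [
                        rec.sample_id,
                        rec.cohort.value,
                        rec.gene,
                        rec.chrom,
                        str(rec.pos),
                        rec.ref,
                        rec.alt,
                        rec.variant_class.value,
                        votes,
                        format(rec.max_maf, "g"),
                    ]
                )
                + "\n"
            )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB gene...``."""
    sets: "OrderedDict[str, frozenset[str]]" = OrderedDict()
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RowParseError(
                    lineno, "GMT line needs name, description and >= 1 gene"
                )
            name = fields[0]
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise RowParseError(lineno, f"gene set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, MISSING] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Filtering and classification
# ---------------------------------------------------------------------------


def filter_coding_rare(
    records: Sequence[DnmRecord],
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> list[DnmRecord]:
    """Keep coding variants with MAF strictly below ``maf_threshold``.

    Non-coding calls and common variants (max_maf >= threshold) are dropped;
    synonymous variants are coding and pass through. Order is preserved.
    """
    return [
        rec
        for rec in records
        if rec.variant_class is not VariantClass.NONCODING
        and rec.max_maf < maf_threshold
    ]


def drop_exact_duplicates(records: Sequence[DnmRecord]) -> list[DnmRecord]:
    """Optionally remove exact duplicate calls.

    Overlapping source cohorts can report the same call twice; a duplicate is
    an identical (sample, chrom, pos, ref, alt) tuple. First occurrence wins.
    """
    seen: set[tuple] = set()
    kept = []
    for rec in records:
        key = (rec.sample_id, rec.chrom, rec.pos, rec.ref, rec.alt)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept


def classify_extreme(
    record: DnmRecord,
    min_votes: int = DEFAULT_MIN_VOTES,
    lof_includes_nonframeshift_indels: bool = True,
) -> ExtremeClass:
    """Classify a coding variant as LoF, damaging missense, or other.

    LoF covers frameshift and (by default) non-frameshift indels, stop-gain,
    stop-loss and splicing SNVs. A missense call is D-Mis when at least
    ``min_votes`` of the 14 predictors call it damaging. Everything else
    (sub-threshold missense, synonymous) is ``other``.
    """
    vclass = record.variant_class
    if vclass is VariantClass.NONCODING:
        raise ValueError("classify_extreme requires coding input; got noncoding")
    lof_classes = LOF_CLASSES
    if not lof_includes_nonframeshift_indels:
        lof_classes = LOF_CLASSES - {VariantClass.NONFRAMESHIFT_INDEL}
    if vclass in lof_classes:
        return ExtremeClass.LOF
    if vclass is VariantClass.MISSENSE:
        votes = record.damaging_votes if record.damaging_votes is not None else 0
        if votes >= min_votes:
            return ExtremeClass.DMIS
    return ExtremeClass.OTHER


def count_extreme_by_gene(
    records: Sequence[DnmRecord],
    min_votes: int = DEFAULT_MIN_VOTES,
    lof_includes_nonframeshift_indels: bool = True,
) -> ExtremeCountTable:
    """Aggregate filtered records into per-gene extreme-mutation counts."""
    table = ExtremeCountTable()
    for rec in records:
        counts = table.setdefault(rec.gene, GeneCounts())
        counts.n_total_dnms += 1
        cls = classify_extreme(
            rec,
            min_votes=min_votes,
            lof_includes_nonframeshift_indels=lof_includes_nonframeshift_indels,
        )
        if cls is ExtremeClass.LOF:
            counts.n_lof += 1
            counts.samples_lof.add(rec.sample_id)
        elif cls is ExtremeClass.DMIS:
            counts.n_dmis += 1
            counts.samples_dmis.add(rec.sample_id)
    return table


def write_count_table(table: ExtremeCountTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\tn_lof\tn_dmis\tn_total_dnms\tn_samples_lof\tn_samples_dmis\n")
        for gene in sorted(table):
            c = table[gene]
            fh.write(
                f"{gene}\t{c.n_lof}\t{c.n_dmis}\t{c.n_total_dnms}"
                f"\t{len(c.samples_lof)}\t{len(c.samples_dmis)}\n"
            )
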