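"""Gene-set burden, intolerance classification, and module mutation burden.

Every test here is a two-sided Fisher's exact test on a 2x2 table with a
cross-product (sample) odds ratio, Haldane-corrected (0.5 added to every
cell) only when a cell is zero. Gene-set enrichment contrasts a query gene
set against the rest of a stated background universe; intolerance burden
uses derived flags — intolerant (RVIS percentile <= 25), extremely
intolerant (pLI > 0.9), and their intersection, the "hot zone" — as the
gene sets. Module mutation burden contrasts the loss-of-function vs
damaging-missense composition of two co-expression modules at three
levels: DNM count, genes carrying such DNMs, and distinct samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExtremeCountTable, GeneSetCollection
from .modules import ModuleAssignment

logger = logging.getLogger(__name__)

RVIS_INTOLERANT_PERCENTILE = 25.0
PLI_EXTREME = 0.9


@dataclass(frozen=True)
class IntoleranceAnnotation:
    """Per-gene intolerance scores and derived flags."""

    gene: str
    rvis_percentile: float
    pli: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rvis_percentile <= 100.0):
            raise ValueError(f"rvis_percentile out of [0,100]: {self.rvis_percentile}")
        if not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pli out of [0,1]: {self.pli}")

    @property
    def intolerant(self) -> bool:
        """RVIS in the top 25% most intolerant (percentile <= 25)."""
        return self.rvis_percentile <= RVIS_INTOLERANT_PERCENTILE

    @property
    def extreme_pli(self) -> bool:
        """pLI strictly greater than 0.9."""
        return self.pli > PLI_EXTREME

    @property
    def hot_zone(self) -> bool:
        return self.intolerant and self.extreme_pli


@dataclass
class EnrichmentResult:
    set_name: str
    a: int  # query & set
    b: int  # query, not set
    c: int  # background & set
    d: int  # background, not set
    odds_ratio: float
    p_value: float
    p_corrected: float | None = None

    @property
    def n_overlap(self) -> int:
        return self.a


@dataclass
class ModuleBurdenResult:
    level: str  # dnm | gene | sample
    mutation_class: str  # LoF | DMis
    m1_class: int
    m1_other: int
    m2_class: int
    m2_other: int
    odds_ratio: float
    p_value: float
    haldane_corrected: bool = False


# ---------------------------------------------------------------------------


def _fisher(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Two-sided Fisher p and cross-product OR (Haldane 0.5 on zero cells)."""
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be nonnegative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = 0 in (a, b, c, d)
    if haldane:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    return (aa * dd) / (bb * cc), float(p), haldane


def fisher_gene_set_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    correction: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Test the query set for over-representation in each collection set.

    Genes outside the universe are dropped from the query with a warning;
    every set is intersected with the universe. ``correction`` is any
    statsmodels multipletests method name ("fdr_bh" default, "bonferroni"
    available); it is applied across the whole collection.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = frozenset(query)
    outside = query - universe
    if outside:
        logger.warning(
            "%d query genes outside universe dropped: %s%s",
            len(outside),
            sorted(outside)[:5],
            "..." if len(outside) > 5 else "",
        )
    query &= universe
    if not query:
        raise ValueError("query is empty after restricting to the universe")

    results = []
    for name in collection:
        gene_set = collection[name] & universe
        a = len(query & gene_set)
        b = len(query) - a
        c = len(gene_set) - a
        d = len(universe) - len(query) - c
        odds, p, _ = _fisher(a, b, c, d)
        results.append(
            EnrichmentResult(set_name=name, a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=p)
        )
    if results:
        _, p_corr, _, _ = multipletests([r.p_value for r in results], method=correction)
        for r, pc in zip(results, p_corr):
            r.p_corrected = float(pc)
    return results


def intolerance_burden(
    query: Iterable[str],
    annotations: Mapping[str, IntoleranceAnnotation],
    universe: Iterable[str],
    correction: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Burden of intolerant / extreme-pLI / hot-zone flags in the query.

    Unannotated genes are excluded from both query and background (logged);
    the three derived flags act as the gene sets.
    """
    universe = frozenset(universe)
    annotated = frozenset(g for g in universe if g in annotations)
    dropped = universe - annotated
    if dropped:
        logger.warning("%d universe genes lack intolerance annotations", len(dropped))
    results = []
    query_in = frozenset(query) & annotated
    if not query_in:
        raise ValueError("no annotated query genes")
    for flag in ("intolerant", "extreme_pli", "hot_zone"):
        flagged = frozenset(g for g in annotated if getattr(annotations[g], flag))
        a = len(query_in & flagged)
        b = len(query_in) - a
        c = len(flagged) - a
        d = len(annotated) - len(query_in) - c
        odds, p, _ = _fisher(a, b, c, d)
        results.append(
            EnrichmentResult(set_name=flag, a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=p)
        )
    _, p_corr, _, _ = multipletests([r.p_value for r in results], method=correction)
    for r, pc in zip(results, p_corr):
        r.p_corrected = float(pc)
    return results


def module_mutation_burden(
    counts: ExtremeCountTable,
    assignment: ModuleAssignment,
    m1: int = 1,
    m2: int = 2,
) -> list[ModuleBurdenResult]:
    """LoF vs D-Mis burden between two modules at three counting levels.

    Levels: "dnm" counts mutations, "gene" counts genes with >= 1 mutation
    of the class, "sample" counts distinct carriers. The 2x2 per class is
    [[class in M1, other class in M1], [class in M2, other class in M2]]
    with the odds ratio oriented M1/M2. Returns 2 classes x 3 levels rows.
    """
    g1 = assignment.module_genes(m1)
    g2 = assignment.module_genes(m2)
    if not g1 or not g2:
        raise ValueError("both modules must be nonempty")

    def tallies(genes: list[str]) -> dict[str, dict[str, int]]:
        lof_dnm = sum(counts.counts_for(g).n_lof for g in genes)
        dmis_dnm = sum(counts.counts_for(g).n_dmis for g in genes)
        lof_genes = sum(1 for g in genes if counts.counts_for(g).n_lof > 0)
        dmis_genes = sum(1 for g in genes if counts.counts_for(g).n_dmis > 0)
        lof_samples = len(set().union(*(counts.counts_for(g).samples_lof for g in genes)))
        dmis_samples = len(set().union(*(counts.counts_for(g).samples_dmis for g in genes)))
        return {
            "dnm": {"LoF": lof_dnm, "DMis": dmis_dnm},
            "gene": {"LoF": lof_genes, "DMis": dmis_genes},
            "sample": {"LoF": lof_samples, "DMis": dmis_samples},
        }

    t1, t2 = tallies(g1), tallies(g2)
    results = []
    for level in ("dnm", "gene", "sample"):
        for cls, other in (("LoF", "DMis"), ("DMis", "LoF")):
            a, b = t1[level][cls], t1[level][other]
            c, d = t2[level][cls], t2[level][other]
            odds, p, haldane = _fisher(a, b, c, d)
            if haldane:
                logger.warning(
                    "module burden %s/%s: zero margin, Haldane-corrected OR", level, cls
                )
            results.append(
                ModuleBurdenResult(
                    level=level,
                    mutation_class=cls,
                    m1_class=a,
                    m1_other=b,
                    m2_class=c,
                    m2_other=d,
                    odds_ratio=odds,
                    p_value=p,
                    haldane_corrected=haldane,
                )
            )
    return results


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_intolerance(path: str | Path) -> dict[str, IntoleranceAnnotation]:
    """Read a TSV with columns gene, rvis_percentile, pli."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "rvis_percentile", "pli"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return {
        str(row.gene): IntoleranceAnnotation(
            gene=str(row.gene),
            rvis_percentile=float(row.rvis_percentile),
            pli=float(row.pli),
        )
        for row in df.itertuples(index=False)
    }


def write_intolerance(
    annotations: Mapping[str, IntoleranceAnnotation], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\trvis_percentile\tpli\n")
        for gene in sorted(annotations):
            ann = annotations[gene]
            fh.write(f"{gene}\t{ann.rvis_percentile:.6g}\t{ann.pli:.6g}\n")


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("set\ta\tb\tc\td\todds_ratio\tp_value\tp_corrected\n")
        for r in results:
            pc = "." if r.p_corrected is None else format(r.p_corrected, ".6g")
            fh.write(
                f"{r.set_name}\t{r.a}\t{r.b}\t{r.c}\t{r.d}"
                f"\t{r.odds_ratio:.6g}\t{r.p_value:.6g}\t{pc}\n"
            )


def write_module_burden(results: Sequence[ModuleBurdenResult], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            "level\tmutation_class\tm1_class\tm1_other\tm2_class\tm2_other"
            "\todds_ratio\tp_value\thaldane\n"
        )
        for r in results:
            fh.write(
                f"{r.level}\t{r.mutation_class}\t{r.m1_class}\t{r.m1_other}"
                f"\t{r.m2_class}\t{r.m2_other}\t{r.odds_ratio:.6g}"
                f"\t{r.p_value:.6g}\t{str(r.haldane_corrected).lower()}\n"
            )
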