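"""Seeded generators for every input the pipeline consumes.

Each generator plants a known ground truth (risk genes with elevated
relative risk, temporally patterned co-expression modules, extra
query-partner connectivity, enriched gene-set overlap) and returns it in
a :class:`SimTruth`, so calibration and recovery can be tested end to end.

Default scale mirrors a combined intellectual-disability trio cohort:
1,027 case trios (951 controls), 63 planted risk genes, co-expression
modules of 39 and 18 genes. Background per-gene, per-class mutation rates
are lognormal with median 1e-5 per haploid genome per generation
(sigma 1); the four rate-model tables are noisy copies of the truth
(multiplicative lognormal noise, sigma 0.2) so the three-of-four
consensus rule is exercised on marginal genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import (
    Cohort,
    CohortSpec,
    DnmRecord,
    GeneSetCollection,
    VariantClass,
    write_dnm_table,
    write_gmt,
)
from .enrichment import IntoleranceAnnotation, write_intolerance
from .modules import PERIODS, ExpressionMatrix, write_expression
from .network import Network, write_edge_list
from .tada import GeneRates, GeneRateTable, RateSource, write_rate_table

DEFAULT_N_GENES = 5000
DEFAULT_N_TRIOS = 1027
DEFAULT_N_CONTROL_TRIOS = 951
DEFAULT_N_RISK_GENES = 63
DEFAULT_MODULE_SIZES = (39, 18)
DEFAULT_REGIONS = ("NCX", "HIP", "AMY", "STR", "MD", "CBC")

MU_MEDIAN = 1e-5
MU_SIGMA = 1.0
RATE_TABLE_NOISE_SIGMA = 0.2

_LOF_CLASSES = (
    VariantClass.FRAMESHIFT_INDEL,
    VariantClass.NONFRAMESHIFT_INDEL,
    VariantClass.STOPGAIN,
    VariantClass.STOPLOSS,
    VariantClass.SPLICING_SNV,
)

# representative numeric age per developmental period (years; fetal negative)
_PERIOD_AGES = (
    -0.65, -0.60, -0.55, -0.50, -0.45, -0.40, -0.30,
    0.25, 0.75, 3.5, 9.0, 16.0, 30.0, 50.0, 70.0,
)


@dataclass
class SimTruth:
    """Planted ground truth for one simulated dataset."""

    seed: int
    risk_genes: dict[str, tuple[float, float]] = field(default_factory=dict)
    module_labels: dict[str, int] = field(default_factory=dict)
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    enriched_sets: dict[str, float] = field(default_factory=dict)
    planted_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    true_rates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "risk_genes": {g: list(v) for g, v in self.risk_genes.items()},
            "module_labels": self.module_labels,
            "planted_edges": sorted(map(list, self.planted_edges)),
            "enriched_sets": self.enriched_sets,
            "planted_counts": {g: list(v) for g, v in self.planted_counts.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# (a) + (b): trio DNM tables and rate tables
# ---------------------------------------------------------------------------


def simulate_trio_dnms(
    n_genes: int = DEFAULT_N_GENES,
    n_trios: int = DEFAULT_N_TRIOS,
    n_risk_genes: int = DEFAULT_N_RISK_GENES,
    gamma_lof: float = 20.0,
    gamma_dmis: float = 4.7,
    cohort: Cohort = Cohort.CASE,
    decoy_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[list[DnmRecord], dict[RateSource, GeneRateTable], CohortSpec, SimTruth]:
    """Simulate one cohort's DNM table plus the four rate-model tables.

    Per gene and mutation class, counts are Poisson(2 N mu gamma) with
    gamma = 1 for non-risk genes. Counts are expanded to one record per
    mutation with distinct carriers per gene/class; decoy rows (synonymous,
    non-coding, and common variants with MAF >= 1e-3) are sprinkled in at
    roughly ``decoy_fraction`` of the extreme-row count to exercise the
    upstream filters. The four rate tables are lognormal-noised copies of
    the true rates, one per source.
    """
    if n_risk_genes > n_genes:
        raise ValueError("n_risk_genes cannot exceed n_genes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD17A]))
    genes = _gene_names(n_genes)
    mu = np.exp(
        rng.normal(np.log(MU_MEDIAN), MU_SIGMA, size=(n_genes, 2))
    )  # columns: LoF, D-Mis
    risk_idx = rng.choice(n_genes, size=n_risk_genes, replace=False)
    gamma = np.ones((n_genes, 2))
    gamma[risk_idx, 0] = gamma_lof
    gamma[risk_idx, 1] = gamma_dmis

    lam = 2.0 * n_trios * mu * gamma
    counts = rng.poisson(lam)

    truth = SimTruth(
        seed=seed,
        risk_genes={genes[i]: (gamma_lof, gamma_dmis) for i in sorted(risk_idx)},
        true_rates={g: (float(mu[i, 0]), float(mu[i, 1])) for i, g in enumerate(genes)},
    )

    records: list[DnmRecord] = []
    bases = np.array(list("ACGT"))

    def make_record(gene_i: int, vclass: VariantClass, sample: int,
                    votes: int | None, maf: float) -> DnmRecord:
        ref, alt = rng.choice(4, size=2, replace=False)
        return DnmRecord(
            sample_id=f"{cohort.value}_{sample + 1:05d}",
            cohort=cohort,
            gene=genes[gene_i],
            chrom=f"chr{int(rng.integers(1, 23))}",
            pos=int(rng.integers(1, 2_000_000)),
            ref=str(bases[ref]),
            alt=str(bases[alt]),
            variant_class=vclass,
            damaging_votes=votes,
            max_maf=maf,
        )

    n_extreme_rows = 0
    for i in range(n_genes):
        n_lof, n_dmis = int(counts[i, 0]), int(counts[i, 1])
        if n_lof + n_dmis == 0:
            continue
        truth.planted_counts[genes[i]] = (n_lof, n_dmis)
        carriers = rng.choice(n_trios, size=min(n_lof + n_dmis, n_trios), replace=False)
        it = iter(carriers)
        for _ in range(n_lof):
            vclass = _LOF_CLASSES[int(rng.integers(len(_LOF_CLASSES)))]
            records.append(make_record(i, vclass, int(next(it)), None, 0.0))
            n_extreme_rows += 1
        for _ in range(n_dmis):
            votes = int(rng.integers(8, 15))
            records.append(make_record(i, VariantClass.MISSENSE, int(next(it)), votes, 0.0))
            n_extreme_rows += 1

    # decoys: retained-but-non-extreme rows (synonymous, weak missense) and
    # rows the rare-coding filter must remove (noncoding, common variants)
    n_decoys = int(round(decoy_fraction * max(n_extreme_rows, 10)))
    for _ in range(n_decoys):
        i = int(rng.integers(n_genes))
        sample = int(rng.integers(n_trios))
        kind = rng.random()
        if kind < 0.4:
            records.append(make_record(i, VariantClass.SYNONYMOUS, sample, None, 0.0))
        elif kind < 0.6:
            votes = int(rng.integers(0, 8))
            records.append(make_record(i, VariantClass.MISSENSE, sample, votes, 0.0))
        elif kind < 0.8:
            records.append(make_record(i, VariantClass.NONCODING, sample, None, 0.0))
        else:
            maf = float(rng.uniform(0.001, 0.05))
            records.append(make_record(i, VariantClass.MISSENSE, sample, 14, maf))

    rate_tables: dict[RateSource, GeneRateTable] = {}
    for source in RateSource:
        noise = np.exp(rng.normal(0.0, RATE_TABLE_NOISE_SIGMA, size=(n_genes, 2)))
        noisy = mu * noise
        rate_tables[source] = GeneRateTable(
            source=source,
            rates={
                g: GeneRates(mu_lof=float(noisy[i, 0]), mu_dmis=float(noisy[i, 1]))
                for i, g in enumerate(genes)
            },
        )
    spec = CohortSpec(label=cohort, n_trios=n_trios)
    return records, rate_tables, spec, truth


# ---------------------------------------------------------------------------
# (e): spatiotemporal expression
# ---------------------------------------------------------------------------

# developmental trajectory templates over the 15 ordered periods (z-scale):
# module 1 rises from the embryonic period to a peak at 16-19 PCW, then
# declines to its lowest level in childhood; module 2 falls through the
# fetal and infancy periods to a minimum in infancy, recovers through
# adolescence and plateaus in adulthood
_M1_TEMPLATE = np.array(
    [-1.5, -0.9, -0.3, 0.4, 1.2, 1.0, 0.6, 0.0, -0.6, -1.2, -1.4, -1.2, -1.0, -0.9, -0.9]
)
_M2_TEMPLATE = np.array(
    [1.3, 1.1, 0.8, 0.5, 0.2, -0.2, -0.6, -1.1, -1.3, -0.8, -0.2, 0.4, 0.7, 0.7, 0.7]
)
M1_PEAK_PERIOD = PERIODS[int(np.argmax(_M1_TEMPLATE))]  # "16-19 PCW"


def simulate_expression(
    module_sizes: Sequence[int] = DEFAULT_MODULE_SIZES,
    n_background: int = 6,
    genes: Sequence[str] | None = None,
    regions: Sequence[str] = DEFAULT_REGIONS,
    samples_per_period_region: int = 1,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate an HBT-like matrix with two planted temporal modules.

    Module genes follow their module's trajectory template plus Gaussian
    noise; background genes are pure noise. ``genes`` optionally names the
    rows (first ``module_sizes[0]`` genes become module 1, the next block
    module 2, the rest background); by default synthetic names are used.
    """
    if any(s < 2 for s in module_sizes):
        raise ValueError("module sizes must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE49]))
    n_genes = sum(module_sizes) + n_background
    if genes is None:
        genes = _gene_names(n_genes)
    genes = list(genes)
    if len(genes) != n_genes:
        raise ValueError(f"need {n_genes} gene names, got {len(genes)}")

    sample_ids, sample_region, sample_period, sample_age = [], [], [], []
    for p_idx, period in enumerate(PERIODS):
        for region in regions:
            for rep in range(samples_per_period_region):
                sample_ids.append(f"s_{period.replace(' ', '')}_{region}_{rep + 1}")
                sample_region.append(region)
                sample_period.append(period)
                sample_age.append(_PERIOD_AGES[p_idx])
    n_samples = len(sample_ids)
    period_idx = np.array([PERIODS.index(p) for p in sample_period])

    templates = [_M1_TEMPLATE, _M2_TEMPLATE]
    if len(module_sizes) > len(templates):
        raise ValueError("at most two planted modules are supported")
    values = np.empty((n_genes, n_samples))
    truth = SimTruth(seed=seed)
    row = 0
    for m, size in enumerate(module_sizes):
        base = templates[m][period_idx]
        for _ in range(size):
            values[row] = base + rng.normal(0.0, noise_sd, size=n_samples)
            truth.module_labels[genes[row]] = m + 1
            row += 1
    for _ in range(n_background):
        values[row] = rng.normal(0.0, 1.0, size=n_samples)
        truth.module_labels[genes[row]] = 0
        row += 1

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        samples=pd.DataFrame(
            {"region": sample_region, "period": sample_period, "age": sample_age},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    return expr, truth


# ---------------------------------------------------------------------------
# (f): interaction network
# ---------------------------------------------------------------------------


def simulate_network(
    universe: Sequence[str],
    background_edge_prob: float = 0.01,
    query_set: Sequence[str] = (),
    partner_set: Sequence[str] = (),
    planted_extra_prob: float = 0.0,
    seed: int = 0,
) -> tuple[Network, SimTruth]:
    """Erdos-Renyi background plus planted query-partner edges.

    With ``planted_extra_prob`` = 0 the graph is exchangeable across gene
    labels, which is the null the permutation test should be calibrated
    against. Edge weights are STRING-style combined scores in [400, 999].
    """
    universe = list(dict.fromkeys(universe))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x2E7]))
    n = len(universe)
    graph = nx.Graph()
    idx_u, idx_v = np.triu_indices(n, k=1)
    draws = rng.random(idx_u.size)
    truth = SimTruth(seed=seed)
    for u, v in zip(idx_u[draws < background_edge_prob], idx_v[draws < background_edge_prob]):
        graph.add_edge(universe[u], universe[v], weight=float(rng.uniform(400, 999)))
    if planted_extra_prob > 0:
        qs = [g for g in dict.fromkeys(query_set) if g in set(universe)]
        ps = [g for g in dict.fromkeys(partner_set) if g in set(universe)]
        for q in qs:
            for p in ps:
                if q == p:
                    continue
                if rng.random() < planted_extra_prob and not graph.has_edge(q, p):
                    graph.add_edge(q, p, weight=float(rng.uniform(400, 999)))
                    truth.planted_edges.add(tuple(sorted((q, p))))
    net = Network(graph=graph, universe=frozenset(universe))
    return net, truth


# ---------------------------------------------------------------------------
# (c): gene-set collections
# ---------------------------------------------------------------------------


def simulate_gene_sets(
    universe: Sequence[str],
    query_set: Sequence[str],
    planted_overlap_fractions: Mapping[str, float],
    set_size: int = 200,
    seed: int = 0,
) -> tuple[GeneSetCollection, SimTruth]:
    """Gene sets drawing a planted fraction of their members from the query.

    Each named set takes ``round(fraction * set_size)`` genes from the
    query set (without replacement) and fills the remainder uniformly from
    the rest of the universe.
    """
    universe = list(dict.fromkeys(universe))
    query = [g for g in dict.fromkeys(query_set) if g in set(universe)]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E7]))
    truth = SimTruth(seed=seed, enriched_sets=dict(planted_overlap_fractions))
    non_query = [g for g in universe if g not in set(query)]
    sets = {}
    for name, frac in planted_overlap_fractions.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"overlap fraction for {name!r} must be in [0,1]")
        n_from_query = min(int(round(frac * set_size)), len(query))
        chosen = list(rng.choice(query, size=n_from_query, replace=False)) if n_from_query else []
        n_fill = set_size - len(chosen)
        chosen += list(rng.choice(non_query, size=min(n_fill, len(non_query)), replace=False))
        sets[name] = frozenset(chosen)
    return GeneSetCollection(sets=sets, universe=frozenset(universe)), truth


# ---------------------------------------------------------------------------
# (d): intolerance annotations
# ---------------------------------------------------------------------------


def simulate_intolerance(
    universe: Sequence[str],
    query_set: Sequence[str] = (),
    hot_zone_rate_query: float = 0.6,
    hot_zone_rate_background: float = 0.1,
    seed: int = 0,
) -> dict[str, IntoleranceAnnotation]:
    """Per-gene RVIS percentile / pLI with hot-zone enrichment in the query.

    A hot-zone gene gets RVIS percentile <= 25 and pLI > 0.9; other genes
    draw uniform RVIS and a low-skewed pLI.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x407]))
    query = set(query_set)
    out = {}
    for gene in dict.fromkeys(universe):
        rate = hot_zone_rate_query if gene in query else hot_zone_rate_background
        if rng.random() < rate:
            rvis = float(rng.uniform(0, 25))
            pli = float(rng.uniform(0.901, 1.0))
        else:
            rvis = float(rng.uniform(0, 100))
            pli = float(rng.beta(0.5, 2.0))
            if rvis <= 25 and pli > 0.9:
                pli = 0.85  # keep the planted hot-zone membership exact
        out[gene] = IntoleranceAnnotation(gene=gene, rvis_percentile=rvis, pli=pli)
    return out


# ---------------------------------------------------------------------------
# demo workspace
# ---------------------------------------------------------------------------


def write_workspace(outdir: str | Path, seed: int = 0, n_genes: int = DEFAULT_N_GENES,
                    n_trios: int = DEFAULT_N_TRIOS,
                    n_control_trios: int = DEFAULT_N_CONTROL_TRIOS) -> dict[str, Path]:
    """Write a complete demo workspace of synthetic inputs; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    records, rate_tables, cohort, truth = simulate_trio_dnms(
        n_genes=n_genes, n_trios=n_trios, seed=seed
    )
    control_records, _, control_cohort, _ = simulate_trio_dnms(
        n_genes=n_genes, n_trios=n_control_trios, n_risk_genes=0,
        cohort=Cohort.CONTROL, seed=seed + 1,
    )
    paths["dnms_case"] = outdir / "dnms_case.tsv"
    write_dnm_table(records, paths["dnms_case"])
    paths["dnms_control"] = outdir / "dnms_control.tsv"
    write_dnm_table(control_records, paths["dnms_control"])
    for source, table in rate_tables.items():
        key = f"rates_{source.value}"
        paths[key] = outdir / f"rates_{source.value}.tsv"
        write_rate_table(table, paths[key])

    risk_genes = sorted(truth.risk_genes)
    n_m1, n_m2 = DEFAULT_MODULE_SIZES
    expr_genes = risk_genes[: n_m1 + n_m2 + 6]
    expr, expr_truth = simulate_expression(genes=expr_genes, seed=seed)
    paths["expression"] = outdir / "expression.tsv"
    paths["expression_samples"] = outdir / "expression_samples.tsv"
    write_expression(expr, paths["expression"], paths["expression_samples"])
    truth.module_labels = expr_truth.module_labels

    all_genes = sorted(truth.true_rates)
    net, net_truth = simulate_network(
        universe=all_genes[:1500] + risk_genes,
        background_edge_prob=0.005,
        query_set=risk_genes[:12],
        partner_set=risk_genes[12:],
        planted_extra_prob=0.25,
        seed=seed,
    )
    paths["ppi"] = outdir / "ppi_edges.tsv"
    write_edge_list(net, paths["ppi"])
    truth.planted_edges = net_truth.planted_edges

    collection, set_truth = simulate_gene_sets(
        universe=all_genes,
        query_set=risk_genes,
        planted_overlap_fractions={
            "FMRP_targets": 0.15,
            "CHD8_targets": 0.12,
            "PSD": 0.08,
            "haploinsufficient": 0.05,
            "constrained": 0.2,
            "known_ID": 0.3,
            "random_control": 0.0,
        },
        seed=seed,
    )
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    write_gmt(collection, paths["gene_sets"])
    truth.enriched_sets = set_truth.enriched_sets

    annotations = simulate_intolerance(all_genes, query_set=risk_genes, seed=seed)
    paths["intolerance"] = outdir / "intolerance.tsv"
    write_intolerance(annotations, paths["intolerance"])

    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
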