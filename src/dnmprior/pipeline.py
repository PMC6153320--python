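"""Pipeline orchestration: YAML config, staged execution, JSON summary.

Stages run in the order of the analysis — filter, per-source TADA,
consensus, then optionally the network, module and burden analyses — and
communicate through TSV intermediates in the output directory, so each
stage can be re-run on its own from the cached files of the previous one.
Every analysis constant is a named config key whose default is the value
used throughout this package (MAF 0.001, >= 8 of 14 damaging votes,
q < 0.1 under >= 3 of 4 rate models with >= 2 DNMs, |r| > 0.6, soft
power 6, 100,000 permutation iterations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from . import core_io, enrichment, modules, network, tada

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs
    dnm_table: str
    rate_tables: dict[str, str]  # source name -> path
    outdir: str
    n_trios: int = 1027
    cohort: str = "case"
    gene_sets: str | None = None
    intolerance: str | None = None
    expression: str | None = None
    expression_samples: str | None = None
    ppi_edges: str | None = None
    # thresholds (analysis constants)
    maf_threshold: float = 0.001
    min_votes: int = 8
    q_threshold: float = 0.1
    relaxed_threshold: float = 0.3
    min_sources: int = 3
    min_dnms: int = 2
    r_threshold: float = 0.6
    power: float = 6.0
    n_iter: int = 100_000
    ppi_score_cutoff: float = 400.0
    n_modules: int = 2
    min_module_size: int = 5
    # model parameters
    pi: float = 0.05
    gamma_bar_lof: float = 20.0
    beta_lof: float = 1.0
    gamma_bar_dmis: float = 4.7
    beta_dmis: float = 1.0
    n_null_samples: int = 1000
    q_method: str = "bh"
    drop_duplicates: bool = False
    # misc
    seed: int = 0
    partners_set: str = "known_ID"  # gene-set name used as network partners

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise tada.ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        missing = [
            p
            for p in [self.dnm_table, *self.rate_tables.values(), self.gene_sets,
                      self.intolerance, self.expression, self.expression_samples,
                      self.ppi_edges]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise tada.ConfigurationError(f"input files not found: {missing}")
        if self.min_sources > len(self.rate_tables):
            raise tada.ConfigurationError(
                f"min_sources={self.min_sources} exceeds the "
                f"{len(self.rate_tables)} rate tables configured"
            )
        if not (0.0 < self.maf_threshold <= 1.0):
            raise tada.ConfigurationError("maf_threshold must be in (0, 1]")
        if not (0 <= self.min_votes <= core_io.N_PREDICTORS):
            raise tada.ConfigurationError("min_votes must be in [0, 14]")
        if not (0.0 < self.q_threshold < 1.0 and 0.0 < self.relaxed_threshold < 1.0):
            raise tada.ConfigurationError("q thresholds must be in (0, 1)")
        if not (0.0 <= self.r_threshold < 1.0):
            raise tada.ConfigurationError("r_threshold must be in [0, 1)")
        if (self.expression is None) != (self.expression_samples is None):
            raise tada.ConfigurationError(
                "expression and expression_samples must be given together"
            )

    def tada_params(self) -> tada.TadaParams:
        return tada.TadaParams(
            pi=self.pi,
            gamma_bar_lof=self.gamma_bar_lof,
            beta_lof=self.beta_lof,
            gamma_bar_dmis=self.gamma_bar_dmis,
            beta_dmis=self.beta_dmis,
            n_null_samples=self.n_null_samples,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = out / "config_hash.txt"
    stamp.write_text(config.config_hash() + "\n")
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_filter(config: PipelineConfig) -> Path:
    """Read, optionally deduplicate, and rare-coding-filter the DNM table."""
    out = _outdir(config)
    records = core_io.read_dnm_table(config.dnm_table)
    n_in = len(records)
    if config.drop_duplicates:
        records = core_io.drop_exact_duplicates(records)
    filtered = core_io.filter_coding_rare(records, maf_threshold=config.maf_threshold)
    path = out / "filtered_dnms.tsv"
    core_io.write_dnm_table(filtered, path)
    counts = core_io.count_extreme_by_gene(filtered, min_votes=config.min_votes)
    core_io.write_count_table(counts, out / "extreme_counts.tsv")
    logger.info("filter: %d records in, %d retained", n_in, len(filtered))
    return path


def _load_counts(config: PipelineConfig) -> core_io.ExtremeCountTable:
    path = Path(config.outdir) / "filtered_dnms.tsv"
    if not path.exists():
        raise StageError("tada", f"missing intermediate {path}; run the filter stage")
    records = core_io.read_dnm_table(path)
    return core_io.count_extreme_by_gene(records, min_votes=config.min_votes)


def stage_tada(config: PipelineConfig) -> dict[str, Path]:
    """Per-source TADA: Bayes factors, both q-values, simulation p-values."""
    out = _outdir(config)
    counts = _load_counts(config)
    params = config.tada_params()
    paths = {}
    for source_name, rate_path in config.rate_tables.items():
        rates = tada.read_rate_table(rate_path, source_name)
        results, skipped = tada.run_tada(counts, rates, config.n_trios, params)
        results = tada.bayesian_qvalues(results, params.pi)
        results = tada.simulation_pvalues(results, params)
        results = tada.attach_bh_qvalues(results)
        path = out / f"tada_{source_name}.tsv"
        tada.write_tada_results(results, path)
        if skipped:
            (out / f"tada_{source_name}_skipped.txt").write_text(
                "\n".join(skipped) + "\n"
            )
        paths[source_name] = path
    return paths


def stage_consensus(config: PipelineConfig) -> Path:
    out = _outdir(config)
    counts = _load_counts(config)
    per_source = {}
    for source_name in config.rate_tables:
        path = out / f"tada_{source_name}.tsv"
        if not path.exists():
            raise StageError("consensus", f"missing intermediate {path}")
        per_source[tada.RateSource(source_name)] = tada.read_tada_results(path)
    results = tada.consensus_call(
        per_source,
        counts,
        q_threshold=config.q_threshold,
        min_sources=config.min_sources,
        min_dnms=config.min_dnms,
        relaxed_threshold=config.relaxed_threshold,
        q_method=config.q_method,
    )
    path = out / "consensus.tsv"
    tada.write_consensus(results, path)
    return path


def _load_consensus_genes(config: PipelineConfig) -> tuple[list[str], list[str]]:
    """Return (high-confidence genes, relaxed q<0.3 candidates)."""
    path = Path(config.outdir) / "consensus.tsv"
    if not path.exists():
        raise StageError("network", f"missing intermediate {path}")
    high, relaxed = [], []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            if f[idx["high_confidence"]] == "true":
                high.append(f[idx["gene"]])
            if f[idx["candidate_03"]] == "true":
                relaxed.append(f[idx["gene"]])
    return high, relaxed


def stage_network(config: PipelineConfig) -> dict[str, Any]:
    """Permutation connectivity tests on the PPI and co-expression networks."""
    out = _outdir(config)
    high, _ = _load_consensus_genes(config)
    if not high:
        logger.warning("network: no high-confidence genes; skipping")
        return {}
    partners: list[str] = []
    if config.gene_sets:
        collection = core_io.read_gmt(config.gene_sets)
        if config.partners_set in collection.sets:
            partners = sorted(collection[config.partners_set])
    if not partners:
        raise StageError(
            "network", f"partner gene set {config.partners_set!r} not available"
        )
    query = [g for g in high if g not in set(partners)]
    summary: dict[str, Any] = {}
    if config.ppi_edges:
        net = network.read_ppi(config.ppi_edges, score_cutoff=config.ppi_score_cutoff)
        res = network.permutation_connectivity_test(
            net, query, partners, n_iter=config.n_iter, seed=config.seed
        )
        summary["ppi"] = _perm_summary(res)
    if config.expression:
        expr = modules.read_expression(config.expression, config.expression_samples)
        coexp = network.coexpression_edges(
            expr, query, partners, r_threshold=config.r_threshold
        )
        res = network.permutation_connectivity_test(
            coexp, [g for g in query if g in coexp.universe], partners,
            n_iter=config.n_iter, seed=config.seed,
        )
        summary["coexpression"] = _perm_summary(res)
        network.write_edge_list(coexp, out / "coexpression_edges.tsv")
    (out / "network_permutation.json").write_text(json.dumps(summary, indent=1))
    return summary


def _perm_summary(res: network.PermutationTestResult) -> dict[str, Any]:
    return {
        "observed_nodes": res.observed.n_connected_nodes,
        "observed_edges": res.observed.n_edges,
        "p_nodes": res.p_nodes,
        "p_edges": res.p_edges,
        "p_nodes_uncorrected": res.p_nodes_uncorrected,
        "p_edges_uncorrected": res.p_edges_uncorrected,
        "n_iter": res.n_iter,
        "seed": res.seed,
    }


def stage_modules(config: PipelineConfig) -> Path:
    """WGCNA-style module discovery on the high-confidence genes."""
    out = _outdir(config)
    high, _ = _load_consensus_genes(config)
    if config.expression is None:
        raise StageError("modules", "no expression matrix configured")
    expr = modules.read_expression(config.expression, config.expression_samples)
    sub = expr.subset(high).drop_zero_variance()
    if len(sub.genes) < max(config.n_modules, 3):
        raise StageError("modules", f"only {len(sub.genes)} usable genes")
    adj = modules.soft_adjacency(sub, power=config.power)
    tom = modules.tom_similarity(adj)
    assignment = modules.cluster_modules(
        tom, min_module_size=config.min_module_size, n_modules=config.n_modules
    )
    assignment.power = config.power
    path = out / "module_assignment.tsv"
    modules.write_assignment(assignment, path)
    trajectories = modules.module_eigengene(sub, assignment)
    modules.write_eigengenes(
        trajectories, out / "eigengenes.tsv", out / "eigengene_periods.tsv"
    )
    return path


def stage_burden(config: PipelineConfig) -> dict[str, Any]:
    """Gene-set enrichment, intolerance burden, module mutation burden."""
    out = _outdir(config)
    high, _ = _load_consensus_genes(config)
    counts = _load_counts(config)
    summary: dict[str, Any] = {}
    if config.gene_sets:
        collection = core_io.read_gmt(config.gene_sets)
        universe = collection.universe
        if universe is None:
            # default background: all genes in any rate table
            universe = frozenset()
            for source_name, rate_path in config.rate_tables.items():
                universe |= tada.read_rate_table(rate_path, source_name).genes()
        results = enrichment.fisher_gene_set_enrichment(
            [g for g in high if g in universe], collection, universe
        )
        enrichment.write_enrichment(results, out / "gene_set_enrichment.tsv")
        summary["gene_sets"] = {
            r.set_name: {"odds_ratio": r.odds_ratio, "p_corrected": r.p_corrected}
            for r in results
        }
    if config.intolerance:
        annotations = enrichment.read_intolerance(config.intolerance)
        results = enrichment.intolerance_burden(high, annotations, annotations.keys())
        enrichment.write_enrichment(results, out / "intolerance_burden.tsv")
        summary["intolerance"] = {
            r.set_name: {"odds_ratio": r.odds_ratio, "p_value": r.p_value}
            for r in results
        }
    assignment_path = out / "module_assignment.tsv"
    if assignment_path.exists():
        labels = {}
        with assignment_path.open() as fh:
            fh.readline()
            for line in fh:
                gene, label = line.rstrip("\n").split("\t")
                labels[gene] = int(label)
        assignment = modules.ModuleAssignment(
            labels=labels, power=config.power,
            min_module_size=config.min_module_size, cut=f"n_modules={config.n_modules}",
        )
        if len(assignment.module_labels()) >= 2:
            results = enrichment.module_mutation_burden(counts, assignment)
            enrichment.write_module_burden(results, out / "module_burden.tsv")
            summary["module_burden"] = [
                {
                    "level": r.level,
                    "class": r.mutation_class,
                    "odds_ratio": r.odds_ratio,
                    "p_value": r.p_value,
                }
                for r in results
            ]
    return summary


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all configured stages; returns and writes the JSON summary."""
    config.validate()
    out = _outdir(config)
    summary: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_trios": config.n_trios,
    }
    stage = "filter"
    try:
        stage_filter(config)
        counts = _load_counts(config)
        summary["n_genes_with_extreme_dnms"] = sum(
            1 for c in counts.values() if c.n_extreme > 0
        )
        stage = "tada"
        stage_tada(config)
        stage = "consensus"
        stage_consensus(config)
        high, relaxed = _load_consensus_genes(config)
        summary["n_high_confidence"] = len(high)
        summary["n_candidate_q03"] = len(relaxed)
        if config.ppi_edges or config.expression:
            stage = "network"
            summary["network"] = stage_network(config)
        if config.expression:
            stage = "modules"
            expr = modules.read_expression(config.expression, config.expression_samples)
            usable = [g for g in high if g in expr.values.index]
            # need room for n_modules clusters of at least min_module_size
            if len(usable) < config.n_modules * config.min_module_size:
                logger.warning(
                    "modules: only %d high-confidence genes with expression "
                    "(need >= %d); skipping module discovery",
                    len(usable),
                    config.n_modules * config.min_module_size,
                )
                summary["modules_skipped"] = (
                    f"{len(usable)} usable genes < "
                    f"{config.n_modules * config.min_module_size}"
                )
            else:
                stage_modules(config)
                labels = {}
                with (out / "module_assignment.tsv").open() as fh:
                    fh.readline()
                    for line in fh:
                        gene, label = line.rstrip("\n").split("\t")
                        labels[gene] = int(label)
                sizes: dict[int, int] = {}
                for lab in labels.values():
                    sizes[lab] = sizes.get(lab, 0) + 1
                summary["module_sizes"] = {str(k): v for k, v in sorted(sizes.items())}
        if config.gene_sets or config.intolerance:
            stage = "burden"
            summary["burden"] = stage_burden(config)
    except StageError:
        raise
    except Exception as exc:  # halt with the stage name; partial outputs remain
        raise StageError(stage, str(exc)) from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
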