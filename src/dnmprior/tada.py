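"""TADA-Denovo: Bayesian gene-level prioritization from de novo counts.

Model. For a gene and a mutation class c (LoF or damaging missense), the
observed de novo count in N trios is

    null:        x_c ~ Poisson(lambda_c),        lambda_c = 2 N mu_c
    alternative: x_c ~ Poisson(lambda_c * gamma), gamma ~ Gamma(gamma_bar*beta, beta)

where mu_c is the per-haploid-genome per-generation background mutation rate
and gamma the relative risk. Marginalizing gamma, the alternative count is
negative binomial with size r = gamma_bar*beta and success probability
p = beta/(beta + lambda_c), so the class Bayes factor has the closed form

    BF_c = NB(x_c; r, p) / Poisson(x_c; lambda_c)

computed in log space. Per-gene evidence is the product over classes; the
Bayesian FDR (q-value) of the k-th gene in the BF ranking is the running
mean of posterior null probabilities over the top k. Simulation p-values
come from Monte Carlo draws of null count pairs; Benjamini-Hochberg turns
them into the second q-value. A gene is a high-confidence call when its
q-value clears the threshold under at least ``min_sources`` of the four
background rate models and the gene carries at least ``min_dnms`` DNMs.
"""

from __future__ import annotations

import enum
import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import ExtremeCountTable, GeneCounts

logger = logging.getLogger(__name__)


class RateSource(str, enum.Enum):
    """The four background de novo mutation-rate models."""

    GC = "GC"  # GC-content based
    SC = "SC"  # sequence-context based
    MF = "MF"  # methylation based
    DM = "DM"  # divergence based


@dataclass(frozen=True)
class GeneRates:
    mu_lof: float
    mu_dmis: float

    def __post_init__(self) -> None:
        for name, mu in (("mu_lof", self.mu_lof), ("mu_dmis", self.mu_dmis)):
            if not math.isfinite(mu) or mu < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {mu}")


@dataclass
class GeneRateTable:
    """Per-gene background mutation rates for one rate model."""

    source: RateSource
    rates: dict[str, GeneRates]

    def __contains__(self, gene: str) -> bool:
        return gene in self.rates

    def __getitem__(self, gene: str) -> GeneRates:
        return self.rates[gene]

    def genes(self) -> set[str]:
        return set(self.rates)


@dataclass(frozen=True)
class TadaParams:
    """Prior hyperparameters and Monte Carlo settings.

    pi is the prior fraction of risk genes; gamma_bar/beta the prior mean and
    dispersion of the relative risk per class. Defaults are conventional
    TADA-Denovo settings for severe neurodevelopmental cohorts.
    """

    pi: float = 0.05
    gamma_bar_lof: float = 20.0
    beta_lof: float = 1.0
    gamma_bar_dmis: float = 4.7
    beta_dmis: float = 1.0
    n_null_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pi < 1.0):
            raise ValueError(f"pi must be in (0,1), got {self.pi}")
        for name, val in (
            ("gamma_bar_lof", self.gamma_bar_lof),
            ("gamma_bar_dmis", self.gamma_bar_dmis),
        ):
            if val <= 1.0:
                raise ValueError(f"{name} must be > 1, got {val}")
        for name, val in (("beta_lof", self.beta_lof), ("beta_dmis", self.beta_dmis)):
            if val <= 0.0:
                raise ValueError(f"{name} must be > 0, got {val}")
        if self.n_null_samples < 1000:
            raise ValueError("n_null_samples must be >= 1000")


@dataclass
class TadaGeneResult:
    gene: str
    x_lof: int
    x_dmis: int
    lambda_lof: float
    lambda_dmis: float
    bf_lof: float
    bf_dmis: float
    bf_total: float
    posterior_null: float
    p_value: float | None = None
    q_bayes: float | None = None
    q_bh: float | None = None


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------


def log_class_bayes_factor(
    x: int | np.ndarray, lam: float, gamma_bar: float, beta: float
) -> float | np.ndarray:
    """Natural log of the per-class Bayes factor (vectorized over x).

    lam = 0 is degenerate: with x = 0 both models assign probability one and
    log BF = 0 by convention; with x > 0 the observation is impossible under
    the null and the BF is undefined.
    """
    x_arr = np.asarray(x)
    if lam == 0.0:
        if np.any(x_arr > 0):
            raise ValueError("lambda = 0 with x > 0: impossible under the null")
        logger.info("lambda = 0 with x = 0: Bayes factor 1 by convention")
        return np.zeros_like(x_arr, dtype=float) if x_arr.ndim else 0.0
    if lam < 0 or not math.isfinite(lam):
        raise ValueError(f"lambda must be finite and >= 0, got {lam}")
    r = gamma_bar * beta
    p = beta / (beta + lam)
    out = stats.nbinom.logpmf(x_arr, r, p) - stats.poisson.logpmf(x_arr, lam)
    return float(out) if out.ndim == 0 else out


def class_bayes_factor(
    x: int, lam: float, gamma_bar: float, beta: float
) -> float:
    """Per-class Bayes factor NB(x; r, p) / Poisson(x; lambda)."""
    return float(np.exp(log_class_bayes_factor(x, lam, gamma_bar, beta)))


def posterior_null_probability(bf_total: float, pi: float) -> float:
    """P(null | data) under prior risk-gene fraction pi."""
    return (1.0 - pi) / ((1.0 - pi) + pi * bf_total)


def gene_bayes_factor(
    gene: str,
    counts: GeneCounts,
    rates: GeneRates,
    n_trios: int,
    params: TadaParams,
) -> TadaGeneResult:
    """Combine per-class Bayes factors for one gene (product over classes)."""
    if n_trios <= 0:
        raise ValueError(f"n_trios must be positive, got {n_trios}")
    lam_lof = 2.0 * n_trios * rates.mu_lof
    lam_dmis = 2.0 * n_trios * rates.mu_dmis
    log_bf_lof = log_class_bayes_factor(
        counts.n_lof, lam_lof, params.gamma_bar_lof, params.beta_lof
    )
    log_bf_dmis = log_class_bayes_factor(
        counts.n_dmis, lam_dmis, params.gamma_bar_dmis, params.beta_dmis
    )
    bf_total = float(np.exp(log_bf_lof + log_bf_dmis))
    return TadaGeneResult(
        gene=gene,
        x_lof=counts.n_lof,
        x_dmis=counts.n_dmis,
        lambda_lof=lam_lof,
        lambda_dmis=lam_dmis,
        bf_lof=float(np.exp(log_bf_lof)),
        bf_dmis=float(np.exp(log_bf_dmis)),
        bf_total=bf_total,
        posterior_null=posterior_null_probability(bf_total, params.pi),
    )


def run_tada(
    counts: ExtremeCountTable,
    rates: GeneRateTable,
    n_trios: int,
    params: TadaParams,
    genes: Iterable[str] | None = None,
) -> tuple[list[TadaGeneResult], list[str]]:
    """Score genes against one rate model.

    ``genes`` defaults to every gene in the rate table (genes without any
    observed DNM enter with zero counts). Genes carrying DNMs but missing
    from the rate table are returned in the skipped list, never silently
    dropped.
    """
    gene_list = sorted(set(genes) if genes is not None else rates.genes())
    skipped = sorted(g for g in counts if g not in rates)
    if skipped:
        logger.warning(
            "%d genes with DNMs absent from %s rate table: %s%s",
            len(skipped),
            rates.source.value,
            ", ".join(skipped[:5]),
            "..." if len(skipped) > 5 else "",
        )
    results = [
        gene_bayes_factor(g, counts.counts_for(g), rates[g], n_trios, params)
        for g in gene_list
        if g in rates
    ]
    return results, skipped


# ---------------------------------------------------------------------------
# q-values and p-values
# ---------------------------------------------------------------------------


def bayesian_qvalues(
    results: Sequence[TadaGeneResult], pi: float
) -> list[TadaGeneResult]:
    """Attach Bayesian-FDR q-values (running mean of posterior null).

    Genes are ranked by decreasing total Bayes factor; the q-value at rank k
    is the mean posterior null probability over the top k genes, so it
    estimates the FDR of calling the top k significant. Ties in BF share the
    q of the worst (largest-k) tied position. Results are returned in the
    input order.
    """
    n = len(results)
    if n == 0:
        return []
    bf = np.array([r.bf_total for r in results])
    post = np.array([posterior_null_probability(b, pi) for b in bf])
    order = np.argsort(-bf, kind="stable")
    running = np.cumsum(post[order]) / np.arange(1, n + 1)
    q_sorted = running.copy()
    # tie groups take the running mean at their last member
    sorted_bf = bf[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_bf[j + 1] == sorted_bf[i]:
            j += 1
        q_sorted[i : j + 1] = running[j]
        i = j + 1
    q = np.empty(n)
    q[order] = q_sorted
    return [replace(r, q_bayes=float(qi)) for r, qi in zip(results, q)]


def _gene_rng(master_seed: int, gene: str) -> np.random.Generator:
    # crc32 gives a stable per-gene stream independent of gene ordering;
    # Python's hash() is process-salted and would break reproducibility
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(gene.encode("utf-8"))])
    )


def simulation_pvalues(
    results: Sequence[TadaGeneResult],
    params: TadaParams,
    randomized: bool = False,
) -> list[TadaGeneResult]:
    """Attach Monte Carlo p-values for each gene's total Bayes factor.

    Per gene, M null count pairs are drawn from the Poisson background at
    that gene's own lambdas, the null BF recomputed, and
    p = (#{BF_null >= BF_obs} + 1) / (M + 1). Gene streams are seeded from
    (master seed, gene), so results do not depend on gene order.

    Because counts are small integers the null BF is heavily tied, which
    makes this p-value conservative (super-uniform) under the null. With
    ``randomized=True`` ties are broken uniformly,
    p = (#{BF > BF_obs} + U * (#{BF == BF_obs} + 1)) / (M + 1), giving an
    exactly uniform null p — the right object for calibration checks, not
    for reporting (it can fall below 1/(M+1)).
    """
    m = params.n_null_samples
    out = []
    for res in results:
        rng = _gene_rng(params.seed, res.gene)
        x_lof = rng.poisson(res.lambda_lof, size=m)
        x_dmis = rng.poisson(res.lambda_dmis, size=m)
        # counts are small; evaluate the log BF once per achievable count.
        # the observed BF is recomputed from the same lookup tables so that
        # null draws equal to the observed counts tie exactly in float space
        log_bf_null = np.zeros(m)
        log_bf_obs = 0.0
        for x_vals, x_obs, lam, gbar, beta in (
            (x_lof, res.x_lof, res.lambda_lof, params.gamma_bar_lof, params.beta_lof),
            (x_dmis, res.x_dmis, res.lambda_dmis, params.gamma_bar_dmis, params.beta_dmis),
        ):
            if lam == 0.0:
                continue  # all draws are 0; log BF contribution 0
            table = np.asarray(
                log_class_bayes_factor(
                    np.arange(max(int(x_vals.max()), x_obs) + 1), lam, gbar, beta
                )
            )
            log_bf_null += table[x_vals]
            log_bf_obs += float(table[x_obs])
        if randomized:
            n_gt = int(np.sum(log_bf_null > log_bf_obs))
            n_eq = int(np.sum(log_bf_null == log_bf_obs))
            p = (n_gt + rng.uniform() * (n_eq + 1)) / (m + 1)
        else:
            n_ge = int(np.sum(log_bf_null >= log_bf_obs))
            p = (n_ge + 1) / (m + 1)
        out.append(replace(res, p_value=p))
    return out


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def attach_bh_qvalues(results: Sequence[TadaGeneResult]) -> list[TadaGeneResult]:
    pvals = [r.p_value for r in results]
    if any(p is None for p in pvals):
        raise ValueError("simulation_pvalues must run before BH adjustment")
    qs = bh_adjust(pvals)
    return [replace(r, q_bh=q) for r, q in zip(results, qs)]


# ---------------------------------------------------------------------------
# Consensus across rate models
# ---------------------------------------------------------------------------


@dataclass
class ConsensusResult:
    gene: str
    q_by_source: dict[RateSource, float | None]
    n_sources_significant: int
    n_dnms: int
    high_confidence: bool
    candidate_03: bool


def consensus_call(
    per_source_results: Mapping[RateSource, Sequence[TadaGeneResult]],
    counts: ExtremeCountTable,
    q_threshold: float = 0.1,
    min_sources: int = 3,
    min_dnms: int = 2,
    relaxed_threshold: float = 0.3,
    q_method: str = "bh",
) -> list[ConsensusResult]:
    """Call high-confidence risk genes across the four rate models.

    A gene is high-confidence when its q-value is below ``q_threshold``
    under at least ``min_sources`` rate models and it carries at least
    ``min_dnms`` DNMs; a relaxed candidate tier is computed the same way at
    ``relaxed_threshold``. A gene absent from a source's rate table simply
    does not count as significant there. ``q_method`` selects which q-value
    drives the call: "bh" (BH on simulation p-values) or "bayes".
    """
    if not per_source_results:
        raise ConfigurationError("at least one rate source is required")
    if min_sources > len(per_source_results):
        raise ConfigurationError(
            f"min_sources={min_sources} exceeds the {len(per_source_results)} "
            "rate sources provided"
        )
    if q_method not in ("bh", "bayes"):
        raise ConfigurationError(f"unknown q_method {q_method!r}")

    def q_of(res: TadaGeneResult) -> float | None:
        return res.q_bh if q_method == "bh" else res.q_bayes

    q_maps: dict[RateSource, dict[str, float | None]] = {
        src: {r.gene: q_of(r) for r in results}
        for src, results in per_source_results.items()
    }
    all_genes = sorted(set().union(*(m.keys() for m in q_maps.values())))
    out = []
    for gene in all_genes:
        q_by_source = {src: q_maps[src].get(gene) for src in q_maps}
        # a gene missing from a source contributes q=None: not significant there
        qs = [q for q in q_by_source.values() if q is not None]
        n_sig = sum(q < q_threshold for q in qs)
        n_sig_relaxed = sum(q < relaxed_threshold for q in qs)
        n_dnms = counts.counts_for(gene).n_total_dnms
        out.append(
            ConsensusResult(
                gene=gene,
                q_by_source=q_by_source,
                n_sources_significant=n_sig,
                n_dnms=n_dnms,
                high_confidence=n_sig >= min_sources and n_dnms >= min_dnms,
                candidate_03=n_sig_relaxed >= min_sources and n_dnms >= min_dnms,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_rate_table(
    path: str | Path,
    source: RateSource | str,
    lof_split: float = 0.1,
    dmis_split: float = 0.3,
) -> GeneRateTable:
    """Read a per-gene rate TSV: gene, mu_lof, mu_dmis — or gene, mu_total.

    When only a total gene mutation rate is provided, it is split into
    classes by the configurable fractions (defaults 0.1 LoF / 0.3 D-Mis).
    """
    source = RateSource(source)
    path = Path(path)
    rates: dict[str, GeneRates] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "gene" not in header:
            raise ConfigurationError(f"{path}: missing 'gene' column")
        split_mode = "mu_total" in header and "mu_lof" not in header
        if split_mode:
            logger.info(
                "%s: splitting mu_total as %.2f LoF / %.2f D-Mis",
                path,
                lof_split,
                dmis_split,
            )
        elif "mu_lof" not in header or "mu_dmis" not in header:
            raise ConfigurationError(
                f"{path}: need mu_lof+mu_dmis columns, or mu_total"
            )
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            gene = fields[idx["gene"]].strip()
            if gene in rates:
                raise ConfigurationError(
                    f"{path} line {lineno}: duplicate gene {gene!r}"
                )
            if split_mode:
                mu_total = float(fields[idx["mu_total"]])
                rates[gene] = GeneRates(
                    mu_lof=lof_split * mu_total, mu_dmis=dmis_split * mu_total
                )
            else:
                rates[gene] = GeneRates(
                    mu_lof=float(fields[idx["mu_lof"]]),
                    mu_dmis=float(fields[idx["mu_dmis"]]),
                )
    return GeneRateTable(source=source, rates=rates)


def write_rate_table(table: GeneRateTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\tmu_lof\tmu_dmis\n")
        for gene in sorted(table.rates):
            r = table.rates[gene]
            fh.write(f"{gene}\t{r.mu_lof:.6g}\t{r.mu_dmis:.6g}\n")


def write_tada_results(results: Sequence[TadaGeneResult], path: str | Path) -> None:
    path = Path(path)

    def fmt(x: float | None) -> str:
        return "." if x is None else format(x, ".6g")

    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            "gene\tx_lof\tx_dmis\tlambda_lof\tlambda_dmis"
            "\tbf_lof\tbf_dmis\tbf_total\tposterior_null\tp_value\tq_bayes\tq_bh\n"
        )
        for r in sorted(results, key=lambda r: -r.bf_total):
            fh.write(
                "\t".join(
                    [
                        r.gene,
                        str(r.x_lof),
                        str(r.x_dmis),
                        fmt(r.lambda_lof),
                        fmt(r.lambda_dmis),
                        fmt(r.bf_lof),
                        fmt(r.bf_dmis),
                        fmt(r.bf_total),
                        fmt(r.posterior_null),
                        fmt(r.p_value),
                        fmt(r.q_bayes),
                        fmt(r.q_bh),
                    ]
                )
                + "\n"
            )


def read_tada_results(path: str | Path) -> list[TadaGeneResult]:
    """Read a per-source results TSV written by :func:`write_tada_results`."""
    results = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")

            def opt(name: str) -> float | None:
                return None if f[idx[name]] == "." else float(f[idx[name]])

            results.append(
                TadaGeneResult(
                    gene=f[idx["gene"]],
                    x_lof=int(f[idx["x_lof"]]),
                    x_dmis=int(f[idx["x_dmis"]]),
                    lambda_lof=float(f[idx["lambda_lof"]]),
                    lambda_dmis=float(f[idx["lambda_dmis"]]),
                    bf_lof=float(f[idx["bf_lof"]]),
                    bf_dmis=float(f[idx["bf_dmis"]]),
                    bf_total=float(f[idx["bf_total"]]),
                    posterior_null=float(f[idx["posterior_null"]]),
                    p_value=opt("p_value"),
                    q_bayes=opt("q_bayes"),
                    q_bh=opt("q_bh"),
                )
            )
    return results


def write_consensus(results: Sequence[ConsensusResult], path: str | Path) -> None:
    path = Path(path)
    sources = [RateSource.GC, RateSource.SC, RateSource.MF, RateSource.DM]
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            "gene\t"
            + "\t".join(f"q{s.value}" for s in sources)
            + "\tn_sources_significant\tn_dnms\thigh_confidence\tcandidate_03\n"
        )
        for r in results:
            qcols = [
                "."
                if r.q_by_source.get(s) is None
                else format(r.q_by_source[s], ".6g")
                for s in sources
            ]
            fh.write(
                "\t".join(
                    [r.gene]
                    + qcols
                    + [
                        str(r.n_sources_significant),
                        str(r.n_dnms),
                        str(r.high_confidence).lower(),
                        str(r.candidate_03).lower(),
                    ]
                )
                + "\n"
            )
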