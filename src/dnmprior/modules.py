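"""Weighted co-expression module discovery and eigengene trajectories.

A soft-thresholded adjacency ``a_ij = |cor(x_i, x_j)|^power`` (unsigned
network, default power 6) is converted to the topological overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with ``k_i = sum_u a_iu`` and ``TOM_ii = 1``; genes are clustered by
average-linkage hierarchical clustering on the dissimilarity ``1 - TOM``.
The tree is cut into a fixed number of modules (default 2) or at a fixed
height — dynamic tree cutting is deliberately not implemented. Each
module is summarized by its eigengene, the first principal component of
the gene-standardized module expression, sign-anchored to correlate
non-negatively with the module's mean profile, and traced across ordered
developmental periods (mean +/- 1.96 SEM per period).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: ordered developmental-period vocabulary of the human brain transcriptome,
#: post-conception weeks (PCW) through adulthood
PERIODS = (
    "4-8 PCW",
    "8-10 PCW",
    "10-13 PCW",
    "13-16 PCW",
    "16-19 PCW",
    "19-24 PCW",
    "24-38 PCW",
    "0-6 M",
    "6-12 M",
    "1-6 Y",
    "6-12 Y",
    "12-20 Y",
    "20-40 Y",
    "40-60 Y",
    "60+ Y",
)


@dataclass
class ExpressionMatrix:
    """genes x samples expression with per-sample region/period metadata.

    ``values``: DataFrame indexed by gene symbol, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with columns region, period
    (drawn from :data:`PERIODS`) and numeric age.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("expression columns must match sample metadata index")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        bad = set(self.samples["period"]) - set(PERIODS)
        if bad:
            raise ValueError(f"unknown developmental periods: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def subset(self, genes: Sequence[str], warn_missing: bool = True) -> "ExpressionMatrix":
        """Restrict to the given genes; absent genes are skipped with a warning."""
        present = [g for g in genes if g in self.values.index]
        missing = sorted(set(genes) - set(present))
        if missing and warn_missing:
            logger.warning(
                "%d of %d genes absent from expression matrix: %s%s",
                len(missing),
                len(genes),
                ", ".join(missing[:5]),
                "..." if len(missing) > 5 else "",
            )
        return ExpressionMatrix(self.values.loc[present], self.samples)

    def drop_zero_variance(self) -> "ExpressionMatrix":
        var = self.values.var(axis=1, ddof=1)
        keep = var > 0
        dropped = sorted(self.values.index[~keep])
        if dropped:
            logger.warning("dropping %d zero-variance genes: %s", len(dropped), dropped[:5])
        return ExpressionMatrix(self.values.loc[keep], self.samples)


@dataclass
class ModuleAssignment:
    """gene -> module label; positive integers, 0 = unassigned."""

    labels: dict[str, int]
    power: float
    min_module_size: int
    cut: str  # e.g. "n_modules=2" or "cut_height=0.25"

    def module_genes(self, label: int) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == label]

    def module_labels(self) -> list[int]:
        return sorted({lab for lab in self.labels.values() if lab > 0})


@dataclass
class EigengeneTrajectory:
    module: int
    scores: pd.Series  # per-sample eigengene, unit variance
    period_mean: pd.Series  # indexed by period, in PERIODS order
    period_half_width: pd.Series  # 1.96 * SEM per period

    def peak_period(self) -> str:
        return str(self.period_mean.idxmax())


# ---------------------------------------------------------------------------


def soft_adjacency(expr: ExpressionMatrix, power: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |Pearson r|^power with zero diagonal."""
    if power <= 0:
        raise ValueError(f"power must be positive, got {power}")
    if expr.values.shape[1] < 3:
        raise ValueError("need >= 3 samples to correlate")
    var = expr.values.var(axis=1, ddof=1)
    if (var == 0).any():
        raise ValueError(
            "zero-variance genes must be removed before soft_adjacency: "
            f"{sorted(expr.values.index[var == 0])[:5]}"
        )
    corr = np.corrcoef(expr.values.to_numpy())
    adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 0.0)
    adj = np.clip(adj, 0.0, 1.0)
    return pd.DataFrame(adj, index=expr.values.index, columns=expr.values.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity; TOM_ii = 1, entries in [0, 1]."""
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    shared = a @ a  # diagonal entries of a are 0, so u = i, j drop out
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def cluster_modules(
    tom: pd.DataFrame,
    min_module_size: int = 5,
    n_modules: int | None = None,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Average-linkage clustering on 1 - TOM into labelled modules.

    Exactly one of ``n_modules`` / ``cut_height`` applies (default: two
    modules). With ``n_modules`` the tree is cut into progressively more
    clusters until ``n_modules`` of them reach ``min_module_size`` — loosely
    attached genes (e.g. background noise) peel off as singletons first, so
    a fixed two-way cut would never separate the real modules. Clusters
    below the minimum size are labelled 0 (unassigned); surviving modules
    are numbered by decreasing size, module 1 largest.
    """
    if n_modules is not None and cut_height is not None:
        raise ValueError("give either n_modules or cut_height, not both")
    if n_modules is None and cut_height is None:
        n_modules = 2
    genes = list(tom.index)
    if n_modules is not None and n_modules > len(genes):
        raise ValueError(f"n_modules={n_modules} exceeds {len(genes)} genes")
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    if n_modules is not None:
        raw = best = hierarchy.fcluster(link, t=n_modules, criterion="maxclust")
        for t in range(n_modules, len(genes) + 1):
            raw = hierarchy.fcluster(link, t=t, criterion="maxclust")
            n_big = int((pd.Series(raw).value_counts() >= min_module_size).sum())
            if n_big >= n_modules:
                break
            if n_big > int((pd.Series(best).value_counts() >= min_module_size).sum()):
                best = raw
        else:
            raw = best  # never reached n_modules sizeable clusters
        cut = f"n_modules={n_modules}"
        max_kept = n_modules
    else:
        raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
        cut = f"cut_height={cut_height}"
        max_kept = len(genes)
    sizes = pd.Series(raw).value_counts()
    kept = [lab for lab in sizes.index if sizes[lab] >= min_module_size]
    # renumber by decreasing size (ties broken by original cluster id)
    kept.sort(key=lambda lab: (-sizes[lab], lab))
    kept = kept[:max_kept]
    relabel = {lab: i + 1 for i, lab in enumerate(kept)}
    labels = {g: relabel.get(lab, 0) for g, lab in zip(genes, raw)}
    return ModuleAssignment(
        labels=labels, power=float("nan"), min_module_size=min_module_size, cut=cut
    )


def module_eigengene(
    expr: ExpressionMatrix, assignment: ModuleAssignment
) -> dict[int, EigengeneTrajectory]:
    """First principal component per module, with per-period summaries.

    Expression is gene-standardized before the PCA; the eigengene is scaled
    to unit variance across samples and its sign fixed so that it correlates
    non-negatively with the module's mean standardized profile.
    """
    out: dict[int, EigengeneTrajectory] = {}
    periods = expr.samples["period"]
    for label in assignment.module_labels():
        genes = [g for g in assignment.module_genes(label) if g in expr.values.index]
        if not genes:
            continue
        x = expr.values.loc[genes].to_numpy(dtype=float)
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance gene in module {label}")
        z = (x - mean) / sd  # genes x samples
        if len(genes) == 1:
            logger.warning("module %d has a single gene; eigengene is its profile", label)
            scores = z[0]
        else:
            # samples as observations: right singular vectors of z
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            scores = vt[0]
        scores = scores / scores.std(ddof=1)
        mean_profile = z.mean(axis=0)
        if np.dot(scores, mean_profile) < 0:
            scores = -scores
        series = pd.Series(scores, index=expr.values.columns, name=f"M{label}")
        grouped = series.groupby(periods)
        present = [p for p in PERIODS if p in grouped.groups]
        pmean = grouped.mean().reindex(present)
        sem = grouped.apply(
            lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0
        ).reindex(present)
        out[label] = EigengeneTrajectory(
            module=label,
            scores=series,
            period_mean=pmean,
            period_half_width=1.96 * sem,
        )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_expression(
    expr_path: str | Path, samples_path: str | Path
) -> ExpressionMatrix:
    """Read expression TSV (first column gene) and sample metadata TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(values=values, samples=samples.loc[values.columns])


def write_expression(
    expr: ExpressionMatrix, expr_path: str | Path, samples_path: str | Path
) -> None:
    expr.values.to_csv(expr_path, sep="\t", index_label="gene")
    expr.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def write_assignment(assignment: ModuleAssignment, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\tmodule\n")
        for gene, label in assignment.labels.items():
            fh.write(f"{gene}\t{label}\n")


def write_eigengenes(
    trajectories: dict[int, EigengeneTrajectory],
    scores_path: str | Path,
    summary_path: str | Path,
) -> None:
    with Path(scores_path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tmodule\tscore\n")
        for label, traj in sorted(trajectories.items()):
            for sample, score in traj.scores.items():
                fh.write(f"{sample}\t{label}\t{score:.6g}\n")
    with Path(summary_path).open("w", encoding="utf-8") as fh:
        fh.write("module\tperiod\tmean\thalf_width\n")
        for label, traj in sorted(trajectories.items()):
            for period in traj.period_mean.index:
                fh.write(
                    f"{label}\t{period}\t{traj.period_mean[period]:.6g}"
                    f"\t{traj.period_half_width[period]:.6g}\n"
                )
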