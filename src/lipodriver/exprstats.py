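"""Expression-matrix statistics: normalization, rank-based differential
expression, gene-set tests, and the embedding/clustering primitives used
by the subtype analysis.

Differential expression is deliberately rank-based (two-sided Wilcoxon
rank-sum on log2-transformed normalized counts) rather than a
negative-binomial GLM; results carry a ``method`` tag so downstream users
know which estimator produced them. The +1 pseudocount on log2
transforms, the mid-rank tie handling, and the exact-vs-asymptotic
switch are documented on the functions below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

VALID_GROUPS = {"WD", "DD", "normal", "unknown"}


@dataclass
class ExpressionMatrix:
    """Genes × samples expression container.

    ``values`` holds raw counts or normalized values depending on
    ``normalized``; ``groups`` maps each sample to WD/DD/normal/unknown.
    """

    values: pd.DataFrame
    groups: pd.Series | None = None
    normalized: bool = False
    size_factors: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("gene and sample ids must be unique")
        if self.groups is None:
            self.groups = pd.Series("unknown", index=self.values.columns)
        self.groups = self.groups.reindex(self.values.columns).fillna("unknown")
        bad = set(self.groups.unique()) - VALID_GROUPS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups[self.groups == group].index)


def size_factor_normalize(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios normalization.

    For each sample j, factor_j is the median over genes of
    count_gj / geometric-mean_g, where genes with any zero count are
    excluded from both the geometric means and the median. Factors are
    rescaled to geometric mean 1 (a global scale with no effect on any
    ratio), which makes the procedure exactly idempotent: refitting on
    an already-normalized matrix returns unit factors. Normalized values
    are counts / factor.
    """
    counts = matrix.values
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene is nonzero in every sample; median-of-ratios undefined "
            "(consider adding a pseudocount before normalizing)")
    ref = counts[nonzero]
    log_geo = np.log(ref).mean(axis=1)
    log_factors = np.log(ref).sub(log_geo, axis=0).median(axis=0)
    factors = np.exp(log_factors - log_factors.mean())
    factors.name = "size_factor"
    normalized = counts.div(factors, axis=1)
    out = ExpressionMatrix(values=normalized, groups=matrix.groups.copy(),
                           normalized=True, size_factors=factors)
    return out, factors


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum.

    Exact null enumeration when both groups have <= 10 observations and
    the pooled data are tie-free; otherwise the normal approximation with
    mid-rank tie correction and continuity correction. All-tied input
    returns p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 10 and len(y) <= 10 and not ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def differential_expression(matrix: ExpressionMatrix, group_a: str, group_b: str,
                            method: str = "wilcoxon") -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE between two sample groups.

    Operates on log2(normalized + 1); log2FC is the log-ratio of group
    means of normalized values with a +1 pseudocount, oriented as group_b
    over group_a (so swapping groups negates it). BH adjustment across
    genes. Constant genes get p = 1, FC = 0.
    """
    if method != "wilcoxon":
        raise ValueError(f"unsupported DE method: {method}")
    if not matrix.normalized:
        warnings.warn("differential_expression called on unnormalized counts",
                      stacklevel=2)
    sa = matrix.samples_in(group_a)
    sb = matrix.samples_in(group_b)
    if len(sa) < 3 or len(sb) < 3:
        raise ValueError("need >= 3 samples per group for differential expression")
    va = matrix.values[sa]
    vb = matrix.values[sb]
    la = np.log2(va + 1.0)
    lb = np.log2(vb + 1.0)
    stats_p = np.array([_rank_sum_test(la.iloc[i].to_numpy(), lb.iloc[i].to_numpy())
                        for i in range(len(la))])
    log2fc = np.log2(vb.mean(axis=1) + 1.0) - np.log2(va.mean(axis=1) + 1.0)
    out = pd.DataFrame({
        "gene_id": matrix.values.index,
        "log2fc": log2fc.to_numpy(),
        "stat": stats_p[:, 0],
        "pvalue": stats_p[:, 1],
    }).set_index("gene_id")
    out["padj"] = multiple_test_adjust(out["pvalue"].to_numpy(), method="BH")
    out["method"] = "wilcoxon-ranksum"
    return out


def multiple_test_adjust(pvals, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment.

    Output is monotone in the input order statistics and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "BH":
        raise ValueError(f"unknown adjustment method: {method}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def hypergeometric_enrichment(query: list[str], gene_sets: dict[str, list[str]],
                              universe: list[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of each gene set in a
    query list, BH-adjusted across sets.

    Sets with no member in the universe are skipped with a warning.
    """
    uni = set(universe)
    q = set(query)
    if not q.issubset(uni):
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        s = set(members) & uni
        if not s:
            warnings.warn(f"gene set {name!r} has no overlap with the universe; skipped",
                          stacklevel=2)
            continue
        k = len(q & s)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(s), len(q)))
        rows.append((name, k, len(s), len(uni), min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "universe_size",
                                      "pvalue"]).set_index("set")
    if not out.empty:
        out["padj"] = multiple_test_adjust(out["pvalue"].to_numpy(), method="BH")
    return out


def geneset_shift_test(matrix: ExpressionMatrix, gene_sets: dict[str, list[str]],
                       group_a: str, group_b: str) -> pd.DataFrame:
    """Per-set Wilcoxon rank-sum on per-sample mean log2 set expression,
    two-sided, Bonferroni-adjusted across sets.

    Each sample is summarized as the mean log2(value + 1) over the set's
    measured genes, so the result is invariant to genes outside the set.
    Identical groups (all scores tied) yield p = 1.
    """
    sa = matrix.samples_in(group_a)
    sb = matrix.samples_in(group_b)
    rows = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in matrix.values.index]
        if len(present) < 2:
            raise ValueError(f"gene set {name!r} has fewer than 2 measured genes")
        scores = np.log2(matrix.values.loc[present] + 1.0).mean(axis=0)
        stat, p = _rank_sum_test(scores[sa].to_numpy(), scores[sb].to_numpy())
        rows.append((name, len(present), stat, p))
    out = pd.DataFrame(rows, columns=["set", "n_genes", "stat", "pvalue"]).set_index("set")
    out["padj"] = multiple_test_adjust(out["pvalue"].to_numpy(), method="bonferroni")
    return out


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame           # samples × PCs
    variance_ratio: np.ndarray     # fraction of total variance per PC
    linkage: np.ndarray            # scipy condensed merge list
    labels: pd.Series              # k-cut cluster labels (1..k)


def embed_and_cluster(matrix: ExpressionMatrix, genes: list[str] | None = None,
                      k: int = 2) -> EmbeddingResult:
    """PCA (covariance eigendecomposition) + Ward clustering of samples.

    Genes are log2(x+1)-transformed and z-scored; zero-variance genes are
    dropped with a warning. Principal components are sorted by variance
    with the sign fixed so each component's largest-magnitude loading is
    positive. Clustering is agglomerative with Euclidean distance and
    Ward linkage, cut into k clusters.
    """
    samples = list(matrix.values.columns)
    if k > len(samples):
        raise ValueError(f"k={k} exceeds the {len(samples)} available samples")
    vals = matrix.values if genes is None else matrix.values.loc[list(genes)]
    if vals.empty:
        raise ValueError("empty gene subset")
    X = np.log2(vals.to_numpy(dtype=float).T + 1.0)   # samples × genes
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes before PCA",
                      stacklevel=2)
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    n_pc = min(len(samples), eigvec.shape[1])
    coords = pd.DataFrame(X @ eigvec[:, :n_pc], index=samples,
                          columns=[f"PC{i + 1}" for i in range(n_pc)])
    total = np.trace(cov)
    variance_ratio = eigval[:n_pc] / total if total > 0 else np.zeros(n_pc)

    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    labels = pd.Series(hierarchy.fcluster(Z, t=k, criterion="maxclust"),
                       index=samples, name="cluster")
    return EmbeddingResult(coords=coords, variance_ratio=variance_ratio,
                           linkage=Z, labels=labels)
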