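"""Replication-dependent histone (RD-HIST) signature scoring and
HIST+/HIST− subtype classification of dedifferentiated tumors.

The signature score of a sample is the mean log2(normalized + 1)
expression over a catalog of RD-HIST genes grouped into the five
canonical families (H1, H2A, H2B, H3, H4). DD tumors are split into
HIST+DD / HIST−DD by a k = 2 Ward cut on the catalog genes; the cluster
with the higher mean score is labelled HIST+DD, which makes the labels
reproducible without any seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from lipodriver import io as lio
from lipodriver.exprstats import ExpressionMatrix, embed_and_cluster
from lipodriver.simdata import HIST_FAMILIES, hist_gene_ids


@dataclass
class GeneSetCatalog:
    """RD-HIST gene ids grouped into disjoint families."""

    families: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam, genes in self.families.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"gene(s) {sorted(overlap)} appear in multiple families")
            seen |= set(genes)

    @property
    def all_genes(self) -> list[str]:
        return [g for fam in self.families.values() for g in fam]

    @property
    def total(self) -> int:
        return len(self.all_genes)

    @classmethod
    def default(cls) -> "GeneSetCatalog":
        """The shipped 66-gene catalog (placeholder ids with family tags;
        users supply real gene ids matching their own annotation)."""
        with resources.as_file(resources.files("lipodriver") / "data" / "rd_hist.gmt") as p:
            return cls.from_gmt(p)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCatalog":
        sets = lio.read_gmt(path)
        families = {}
        for name, genes in sets.items():
            fam = name.rsplit("_", 1)[-1]
            if fam in HIST_FAMILIES:
                families[fam] = genes
        if not families:
            raise ValueError(f"no per-family histone sets found in {path!s} "
                             f"(expected set names ending in {HIST_FAMILIES})")
        return cls(families=families)

    def to_gmt(self, path, prefix: str = "RD_HIST") -> None:
        sets = {f"{prefix}_{fam}": genes for fam, genes in self.families.items()}
        sets[f"{prefix}_ALL"] = self.all_genes
        lio.write_gmt(sets, path)


def default_catalog_frame() -> pd.DataFrame:
    return hist_gene_ids(66)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    defined: bool = True


def histone_score(matrix: ExpressionMatrix, catalog: GeneSetCatalog) -> pd.DataFrame:
    """Per-sample overall and per-family RD-HIST scores.

    Scores are means of log2(value + 1) over the measured catalog genes;
    the overall score is the size-weighted mean of family scores by
    construction. Missing catalog genes are reported in a warning.
    """
    present = [g for g in catalog.all_genes if g in matrix.values.index]
    missing = sorted(set(catalog.all_genes) - set(present))
    if not present:
        raise ValueError("no catalog gene is measured in the matrix")
    if missing:
        warnings.warn(f"{len(missing)} catalog genes not measured: {missing[:10]}...",
                      stacklevel=2)
    log2v = np.log2(matrix.values.loc[present] + 1.0)
    out = pd.DataFrame({"score": log2v.mean(axis=0)})
    for fam, genes in catalog.families.items():
        fam_present = [g for g in genes if g in matrix.values.index]
        out[f"score_{fam}"] = (np.log2(matrix.values.loc[fam_present] + 1.0).mean(axis=0)
                               if fam_present else np.nan)
    out.index.name = "sample"
    return out


@dataclass
class SubtypeCall:
    labels: pd.Series           # DD sample -> "HIST+DD" / "HIST-DD"
    cluster_labels: pd.Series   # raw k-cut labels
    cluster_scores: pd.Series   # mean overall score per raw cluster
    singleton: bool             # a cluster of size 1 was produced


def classify_hist_subtype(matrix: ExpressionMatrix, catalog: GeneSetCatalog,
                          dd_samples: list[str]) -> SubtypeCall:
    """Split DD tumors into HIST+DD / HIST−DD.

    k = 2 Ward cut on the catalog genes restricted to the DD samples; the
    cluster with the higher mean overall score becomes HIST+DD. The
    relabelling is a deterministic function of the input. Singleton
    clusters are allowed but flagged.
    """
    dd_samples = list(dd_samples)
    if len(dd_samples) < 4:
        raise ValueError(f"need >= 4 DD samples to cluster, got {len(dd_samples)}")
    sub = ExpressionMatrix(values=matrix.values[dd_samples],
                           groups=matrix.groups[dd_samples],
                           normalized=matrix.normalized)
    present = [g for g in catalog.all_genes if g in sub.values.index]
    emb = embed_and_cluster(sub, genes=present, k=2)
    scores = histone_score(sub, catalog)["score"]
    cluster_scores = scores.groupby(emb.labels).mean()
    hist_pos_cluster = cluster_scores.idxmax()
    labels = emb.labels.map(lambda c: "HIST+DD" if c == hist_pos_cluster else "HIST-DD")
    labels.name = "subtype"
    singleton = bool((emb.labels.value_counts() == 1).any())
    return SubtypeCall(labels=labels, cluster_labels=emb.labels,
                       cluster_scores=cluster_scores, singleton=singleton)


def geneset_fold_change(matrix: ExpressionMatrix, genes: list[str],
                        group_a: str, group_b: str,
                        min_detect: float = 1.0) -> tuple[float, pd.DataFrame]:
    """Average fold change of a gene set between two groups.

    Per gene, FC = (mean normalized B + 1) / (mean normalized A + 1);
    the summary is the mean FC over the genes that pass a detection
    filter (mean normalized value >= ``min_detect`` in at least one
    group). The per-gene table reports every measured set gene with its
    detection flag, so the effective subset size is visible.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    present = [g for g in genes if g in matrix.values.index]
    if not present:
        raise ValueError("no set gene is measured in the matrix")
    sa = matrix.samples_in(group_a)
    sb = matrix.samples_in(group_b)
    if not sa or not sb:
        raise ValueError("both groups need at least one sample")
    mean_a = matrix.values.loc[present, sa].mean(axis=1)
    mean_b = matrix.values.loc[present, sb].mean(axis=1)
    table = pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b,
                          "fold_change": (mean_b + 1.0) / (mean_a + 1.0)})
    table["detected"] = (mean_a >= min_detect) | (mean_b >= min_detect)
    used = table[table["detected"]]
    if used.empty:
        raise ValueError("no set gene passes the detection filter")
    return float(used["fold_change"].mean()), table


def phenotype_correlation(scores: pd.Series, phenotype: pd.Series,
                          groups: pd.Series | None = None) -> CorrelationResult:
    """Pearson correlation of the signature score against a phenotype.

    Normal samples are excluded by contract (when ``groups`` is given);
    missing values are pairwise-dropped. Raises below 3 complete pairs.
    """
    df = pd.DataFrame({"score": scores, "pheno": phenotype}).dropna()
    if groups is not None:
        tumors = groups[groups != "normal"].index
        df = df.loc[df.index.intersection(tumors)]
    if len(df) < 3:
        raise ValueError(f"only {len(df)} complete score/phenotype pairs; need >= 3")
    if df["score"].std() == 0 or df["pheno"].std() == 0:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=len(df), defined=False)
    r, p = stats.pearsonr(df["score"], df["pheno"])
    return CorrelationResult(r=float(r), p=float(p), n=len(df))


def wd_score_outliers(scores: pd.Series, groups: pd.Series,
                      subtype: SubtypeCall) -> list[str]:
    """WD samples whose RD-HIST score reaches the HIST+DD range.

    Diagnostic only — the signature is treated as DD-internal and WD
    labels are never changed; this merely surfaces potential
    histone-high sub-clones inside WD tumors.
    """
    hist_pos = subtype.labels[subtype.labels == "HIST+DD"].index
    if len(hist_pos) == 0:
        return []
    cutoff = scores[hist_pos].min()
    wd = groups[groups == "WD"].index
    return sorted(s for s in wd if s in scores.index and scores[s] >= cutoff)
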