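"""Transcription-factor driver prioritization cascade.

The screen nominates upstream regulators of the RD-HIST signature in
four stages mirroring the driver-identification funnel:

1. expression filter — mean normalized count across tumor samples above
   a floor;
2. co-expression — Pearson R above a threshold against the mean log2
   profile of *each* of the five histone families (family aggregates by
   default; a strict per-gene mode is available), computed over DD
   samples only by default;
3. DD-specific focal amplification — the TF's gene interval overlaps a
   passing focal amplification call in enough DD samples, and the mean
   DD extra copies at the locus exceed the WD mean (amplified in both
   subtypes but more in DD still qualifies);
4. ranking of passers by maximum observed extra copies, then minimum
   family correlation, then gene id.

Funnel counts (total, expressed, co-expressed, passing) are emitted with
every run and are non-increasing along the cascade by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lipodriver.cnv import call_focal_amplifications, _gene_copy_estimate
from lipodriver.exprstats import ExpressionMatrix
from lipodriver.histone import CorrelationResult, GeneSetCatalog


@dataclass(frozen=True)
class ScreenConfig:
    corr_threshold: float = 0.6
    min_expr: float = 1.0           # mean normalized count floor for "expressed"
    min_dd_samples: int = 1
    extra_copy_threshold: float = 2.0
    max_focal_len: float = 20e6
    dd_only: bool = True            # correlations over DD samples only
    per_gene_mode: bool = False     # strict all-genes co-expression instead of families
    require_dd_gt_wd: bool = True   # mean DD extra copies must exceed WD mean

    def validate(self) -> None:
        if not 0.0 < self.corr_threshold <= 1.01:
            raise ValueError("corr_threshold must lie in (0, 1] (or just above to disable)")
        if self.min_dd_samples < 1:
            raise ValueError("min_dd_samples must be >= 1")


def funnel_percentage(count: int, total: int) -> float:
    """Share of the funnel surviving a stage, in percent, one decimal."""
    if total <= 0:
        raise ValueError("funnel total must be positive")
    return round(100.0 * count / total, 1)


def format_funnel_line(count: int, total: int) -> str:
    """Human-readable funnel entry, e.g. ``68 (3.4%)``."""
    return f"{count} ({funnel_percentage(count, total):g}%)"


def family_correlations(matrix: ExpressionMatrix, tf_ids: list[str],
                        catalog: GeneSetCatalog,
                        samples: list[str]) -> pd.DataFrame:
    """Pearson R of each TF against each histone-family mean profile.

    Correlations use log2(value + 1) across the given samples.
    Zero-variance vectors yield NaN (flagged undefined, never silently
    zero).
    """
    samples = list(samples)
    if len(samples) < 4:
        raise ValueError(f"need >= 4 samples for correlations, got {len(samples)}")
    log2v = np.log2(matrix.values[samples] + 1.0)
    fam_profiles = {}
    for fam, genes in catalog.families.items():
        present = [g for g in genes if g in log2v.index]
        if not present:
            raise ValueError(f"no measured genes for histone family {fam}")
        fam_profiles[fam] = log2v.loc[present].mean(axis=0).to_numpy()
    out = pd.DataFrame(index=pd.Index(tf_ids, name="tf"), columns=list(catalog.families),
                       dtype=float)
    for tf in tf_ids:
        x = log2v.loc[tf].to_numpy()
        if np.std(x) == 0:
            continue  # leave NaN
        for fam, prof in fam_profiles.items():
            if np.std(prof) == 0:
                continue
            out.loc[tf, fam] = float(np.corrcoef(x, prof)[0, 1])
    return out


def _per_gene_min_corr(matrix: ExpressionMatrix, tf: str, catalog: GeneSetCatalog,
                       samples: list[str]) -> float:
    log2v = np.log2(matrix.values[samples] + 1.0)
    x = log2v.loc[tf].to_numpy()
    if np.std(x) == 0:
        return float("nan")
    rs = []
    for g in catalog.all_genes:
        if g not in log2v.index:
            continue
        y = log2v.loc[g].to_numpy()
        if np.std(y) == 0:
            return float("nan")
        rs.append(float(np.corrcoef(x, y)[0, 1]))
    return min(rs) if rs else float("nan")


@dataclass
class ScreenResult:
    candidates: pd.DataFrame     # per-TF flags, correlations, extra copies, rank
    funnel: dict[str, int]
    config: ScreenConfig = field(repr=False, default_factory=ScreenConfig)

    def funnel_summary(self) -> str:
        total = self.funnel["n_tfs"]
        lines = [f"TFs considered\t{total}"]
        for key, label in (("n_expressed", "expressed"),
                           ("n_coexpressed", "co-expressed"),
                           ("n_passing", "amplified & passing")):
            lines.append(f"{label}\t{format_funnel_line(self.funnel[key], total)}")
        return "\n".join(lines)


def run_screen(matrix: ExpressionMatrix, annotation: pd.DataFrame,
               segments: dict[str, pd.DataFrame], catalog: GeneSetCatalog,
               config: ScreenConfig | None = None,
               groups: pd.Series | None = None) -> ScreenResult:
    """Execute the full driver-prioritization cascade.

    ``segments`` maps every tumor sample (WD and DD) to its copy-number
    segment table; group membership comes from ``groups`` (defaults to
    the matrix's labels). Raises if catalog genes are missing from the
    matrix, listing the missing ids.
    """
    config = config or ScreenConfig()
    config.validate()
    groups = matrix.groups if groups is None else groups
    missing = sorted(set(catalog.all_genes) - set(matrix.values.index))
    if missing:
        raise ValueError(f"catalog genes missing from the matrix: {missing}")

    tf_ids = [g for g in annotation.loc[annotation["is_tf"], "gene_id"]
              if g in matrix.values.index]
    dd = [s for s in groups[groups == "DD"].index if s in segments]
    wd = [s for s in groups[groups == "WD"].index if s in segments]
    tumor_cols = [s for s in matrix.values.columns if groups.get(s) in ("WD", "DD")]

    # stage 1: expressed
    mean_expr = matrix.values.loc[tf_ids, tumor_cols].mean(axis=1)
    expressed = mean_expr >= config.min_expr

    # stage 2: co-expression with every histone family
    corr_samples = dd if config.dd_only else tumor_cols
    fam_r = family_correlations(matrix, tf_ids, catalog, corr_samples)
    if config.per_gene_mode:
        min_r = pd.Series({tf: _per_gene_min_corr(matrix, tf, catalog, corr_samples)
                           for tf in tf_ids})
    else:
        min_r = fam_r.min(axis=1)
    coexpressed = expressed & (min_r > config.corr_threshold) & min_r.notna()

    # stage 3: DD-specific focal amplification at the TF locus
    ann = annotation.set_index("gene_id")
    focal = {s: call_focal_amplifications(seg, config.extra_copy_threshold,
                                          config.max_focal_len)
             for s, seg in segments.items()}
    amp_flags, max_extra, n_dd_amp = {}, {}, {}
    for tf in tf_ids:
        rec = ann.loc[tf]
        chrom, start, end = rec["chrom"], int(rec["start"]), int(rec["end"])
        hits = []
        for s in dd:
            f = focal[s]
            ov = f[(f["chrom"] == chrom) & (f["start"] < end) & (f["end"] > start)
                   & f["passes"]]
            if not ov.empty:
                hits.append(float(ov["extra_copies"].max()))
        n_dd_amp[tf] = len(hits)
        max_extra[tf] = max(hits) if hits else 0.0
        ok = len(hits) >= config.min_dd_samples
        if ok and config.require_dd_gt_wd:
            dd_extra = np.nanmean([_gene_copy_estimate(segments[s], chrom, start, end) - 2.0
                                   for s in dd])
            wd_extra = (np.nanmean([_gene_copy_estimate(segments[s], chrom, start, end) - 2.0
                                    for s in wd]) if wd else -np.inf)
            ok = bool(dd_extra > wd_extra)
        amp_flags[tf] = ok

    candidates = pd.DataFrame({
        "mean_expr": mean_expr,
        "expressed": expressed,
        "min_r": min_r,
        "coexpressed": coexpressed,
        "n_dd_amplified": pd.Series(n_dd_amp),
        "max_extra_copies": pd.Series(max_extra),
        "amplified": pd.Series(amp_flags),
    })
    for fam in fam_r.columns:
        candidates[f"r_{fam}"] = fam_r[fam]
    candidates["passes"] = (candidates["expressed"] & candidates["coexpressed"]
                            & candidates["amplified"])

    # rank passers: extra copies desc, min family R desc, gene id asc
    passers = candidates[candidates["passes"]].copy()
    passers["_gid"] = passers.index
    passers = passers.sort_values(["max_extra_copies", "min_r", "_gid"],
                                  ascending=[False, False, True], kind="mergesort")
    candidates["rank"] = pd.NA
    candidates.loc[passers.index, "rank"] = np.arange(1, len(passers) + 1)

    funnel = {
        "n_tfs": len(tf_ids),
        "n_expressed": int(expressed.sum()),
        "n_coexpressed": int(coexpressed.sum()),
        "n_passing": int(candidates["passes"].sum()),
    }
    return ScreenResult(candidates=candidates, funnel=funnel, config=config)


def candidate_cn_expression(matrix: ExpressionMatrix,
                            segments: dict[str, pd.DataFrame],
                            tf_id: str, annotation: pd.DataFrame,
                            samples: list[str] | None = None) -> CorrelationResult:
    """Pearson correlation between a TF's per-sample copy estimate and its
    log2 expression; flagged undefined on constant input."""
    from scipy import stats

    rec = annotation.set_index("gene_id").loc[tf_id]
    samples = [s for s in (samples or list(segments)) if s in segments]
    cn, ex = [], []
    for s in samples:
        c = _gene_copy_estimate(segments[s], rec["chrom"], int(rec["start"]),
                                int(rec["end"]))
        if np.isnan(c) or s not in matrix.values.columns:
            continue
        cn.append(c)
        ex.append(float(np.log2(matrix.values.loc[tf_id, s] + 1.0)))
    if len(cn) < 3:
        raise ValueError(f"only {len(cn)} samples with both copy number and "
                         f"expression for {tf_id}; need >= 3")
    if np.std(cn) == 0 or np.std(ex) == 0:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=len(cn), defined=False)
    r, p = stats.pearsonr(cn, ex)
    return CorrelationResult(r=float(r), p=float(p), n=len(cn))
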