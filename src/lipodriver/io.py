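"""Readers and writers for the plain-text formats the pipeline touches.

Conventions (also embedded in file headers where coordinates appear):

* TSV, tab separator, UTF-8, ``.`` decimal, no quoting, fixed column order.
* BED-like interval files are 0-based half-open and carry a ``#coords=``
  header line; per-site allele-count files are 1-based (VCF convention).
* Expression matrices are genes (rows) × samples (columns) with a header
  row of sample ids and the gene-id column named ``gene_id``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.6g"

ANNOTATION_COLS = ["chrom", "start", "end", "gene_id", "is_tf", "hist_family"]
DEPTH_COLS = ["chrom", "start", "end", "depth"]
SITE_COLS = ["chrom", "pos", "ref_t", "alt_t", "ref_n", "alt_n"]
SEGMENT_COLS = ["chrom", "start", "end", "copies", "n_bins"]
PHENOTYPE_COLS = ["sample", "mitotic_per_10hpf", "ki67_pct", "group"]


def _write_tsv(df: pd.DataFrame, path, header_lines=(), index=False) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FMT, lineterminator="\n")


def write_expression_tsv(values: pd.DataFrame, path) -> None:
    df = values.copy()
    df.index.name = "gene_id"
    _write_tsv(df, path, index=True)


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    df = annotation[ANNOTATION_COLS].copy()
    df["is_tf"] = df["is_tf"].astype(int)
    _write_tsv(df, path, header_lines=["#coords=0-based half-open"])


def read_annotation_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", names=None, header=0)
    missing = [c for c in ANNOTATION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path} missing columns: {missing}")
    df["is_tf"] = df["is_tf"].astype(bool)
    return df[ANNOTATION_COLS]


def write_depth_tsv(depth: pd.DataFrame, path) -> None:
    _write_tsv(depth[DEPTH_COLS], path, header_lines=["#coords=0-based half-open"])


def read_depth_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"depth file not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#", header=0)[DEPTH_COLS]


def write_sites_tsv(sites: pd.DataFrame, path) -> None:
    _write_tsv(sites[SITE_COLS], path, header_lines=["#coords=1-based"])


def read_sites_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=0)[SITE_COLS]


def write_segments_bed(segments: pd.DataFrame, path) -> None:
    _write_tsv(segments[SEGMENT_COLS], path, header_lines=["#coords=0-based half-open"])


def read_segments_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=0)[SEGMENT_COLS]
    df["copies"] = df["copies"].astype(float)
    return df


def write_phenotype_tsv(phenotypes: pd.DataFrame, path) -> None:
    _write_tsv(phenotypes[PHENOTYPE_COLS], path)


def read_phenotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=0)[PHENOTYPE_COLS]


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line in {path!s}: {line!r}")
            sets[fields[0]] = fields[2:]
    return sets


def config_hash(obj) -> str:
    """Stable SHA-256 over a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
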