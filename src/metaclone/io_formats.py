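"""Readers and writers for the on-disk formats the pipeline touches.

Probe-level log2-ratio tables (TSV), VCF 4.x variant calls with per-sample
allelic depths, SEG-like segment tables, gene x sample expression matrices
(TSV), Newick trees and the YAML run configuration.

Internal coordinates are 0-based half-open; VCF and SEG files on disk are
1-based inclusive, per the respective conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import pysam
import yaml

from ._genome import CHROM_LENGTHS, chrom_sort_key, normalize_chrom

CONFIG_SCHEMA_VERSION = 1

#: Columns of a SEG-like allele-specific segment table.
SEG_COLUMNS = [
    "sample", "chrom", "start", "end", "n_probes", "mean_log2",
    "total_cn", "major_cn", "minor_cn",
]


class FormatError(ValueError):
    """A file does not conform to the expected format."""


@dataclass
class ProbeTable:
    """Probe-level log2 ratios, sorted by (chromosome, position).

    ``df`` has columns chrom, pos (1-based), log2. ``skipped`` lists
    (line_number, reason) for malformed rows that were dropped.
    """

    df: pd.DataFrame
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def __len__(self) -> int:
        return len(self.df)


def read_probe_table(path, dialect: str = "tsv") -> ProbeTable:
    """Read a probe table with at least chrom/pos/log2 columns.

    Rows with a non-numeric position or log2 value are skipped and reported
    with their 1-based line number; a missing required column raises
    :class:`FormatError`.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = {"chrom", "pos", "log2"} - set(raw.columns)
    if missing:
        raise FormatError(f"probe table {path}: missing column(s) {sorted(missing)}")

    pos = pd.to_numeric(raw["pos"], errors="coerce")
    log2 = pd.to_numeric(raw["log2"], errors="coerce")
    bad = pos.isna() | log2.isna() | ~np.isfinite(log2.fillna(np.inf)) | (pos < 1)
    skipped = []
    for idx in raw.index[bad]:
        # +2: header line plus 1-based indexing
        skipped.append((int(idx) + 2, f"malformed row: pos={raw.at[idx, 'pos']!r} log2={raw.at[idx, 'log2']!r}"))

    df = pd.DataFrame({
        "chrom": raw.loc[~bad, "chrom"].map(normalize_chrom),
        "pos": pos[~bad].astype(np.int64),
        "log2": log2[~bad].astype(float),
    })
    order = df["chrom"].map(lambda c: chrom_sort_key(c)[0])
    df = df.assign(_o=order).sort_values(["_o", "pos"], kind="stable").drop(columns="_o")
    return ProbeTable(df.reset_index(drop=True), skipped)


def write_probe_table(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "log2"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF

def read_vcf_variants(path, min_depth: int = 0) -> pd.DataFrame:
    """Read per-sample allelic depths from a VCF into a long-form table.

    Returns one row per site x sample with columns chrom, pos (1-based),
    ref, alt, sample, ref_count, alt_count, depth, germline, insufficient.
    Sites with depth below ``min_depth`` are flagged ``insufficient``, not
    dropped. Requires the per-sample AD (allelic depth) FORMAT field.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if "AD" not in rec.format and samples:
                raise FormatError(f"{path}: record {rec.chrom}:{rec.pos} lacks FORMAT field AD")
            alt = rec.alts[0] if rec.alts else "."
            germ = bool(rec.info.get("GERMLINE", False))
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or ad[0] is None:
                    ref_c, alt_c = 0, 0
                else:
                    ref_c = int(ad[0])
                    alt_c = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
                depth = ref_c + alt_c
                rows.append((normalize_chrom(rec.chrom), rec.pos, rec.ref, alt, s,
                             ref_c, alt_c, depth, germ, depth < min_depth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample",
                                     "ref_count", "alt_count", "depth",
                                     "germline", "insufficient"])
    return df


def write_vcf(df: pd.DataFrame, samples: list[str], path, germline: bool = False) -> None:
    """Write a long-form variant table (as from :func:`read_vcf_variants`)
    to a VCF 4.2 file with per-sample AD fields."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##INFO=<ID=GERMLINE,Number=0,Type=Flag,Description="Germline variant">')
    for chrom, length in CHROM_LENGTHS.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for s in samples:
        header.add_sample(s)

    key = ["chrom", "pos", "ref", "alt"]
    df = df.assign(_o=df["chrom"].map(lambda c: chrom_sort_key(c)[0])).sort_values(["_o", "pos"])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref, alt), grp in df.groupby(key, sort=False):
            rec = out.new_record(contig=chrom, start=int(pos) - 1,
                                 alleles=(str(ref), str(alt)))
            is_germ = germline or ("germline" in grp and bool(grp["germline"].iloc[0]))
            if is_germ:
                rec.info["GERMLINE"] = True
            counts = {r["sample"]: (int(r["ref_count"]), int(r["alt_count"]))
                      for _, r in grp.iterrows()}
            for s in samples:
                rec.samples[s]["AD"] = counts.get(s, (0, 0))
            out.write(rec)


# ---------------------------------------------------------------------------
# SEG

def write_seg(df: pd.DataFrame, path) -> None:
    """Write an allele-specific segment table (1-based inclusive on disk)."""
    out = df.copy()
    out["start"] = out["start"].astype(np.int64) + 1  # 0-based half-open -> 1-based incl.
    out["end"] = out["end"].astype(np.int64)
    cols = [c for c in SEG_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in SEG_COLUMNS]
    out[cols + extra].to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "start", "end"}.issubset(df.columns):
        raise FormatError(f"{path}: not a SEG-like table")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["start"] = df["start"].astype(np.int64) - 1  # back to 0-based half-open
    df["end"] = df["end"].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# Expression

def read_expression_tsv(path) -> pd.DataFrame:
    """Read a gene x sample expression matrix (genes as rows, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample names")
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Newick

def write_tree_newick(tree: dendropy.Tree, path) -> None:
    """Serialize a tree to Newick; duplicate leaf labels are an error."""
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True,
                       real_value_format_specifier=".6f")
    )


def read_tree_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# Config

def load_config(path) -> dict:
    """Load a versioned YAML configuration; unknown top-level keys warn."""
    known = {
        "schema_version", "seed", "samples", "probe_spacing", "het_spacing",
        "depth", "log2_sigma", "n_genes", "n_de", "n_lineage_genes",
        "expression_sigma", "out_dir", "purity", "penalty", "min_probes",
        "fc_threshold", "p_threshold", "n_variable_genes",
    }
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    version = cfg.get("schema_version", CONFIG_SCHEMA_VERSION)
    if version > CONFIG_SCHEMA_VERSION:
        raise FormatError(f"config schema_version {version} is newer than supported "
                          f"({CONFIG_SCHEMA_VERSION})")
    for key in cfg:
        if key not in known:
            warnings.warn(f"config: unknown key {key!r} ignored", stacklevel=2)
    return cfg
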