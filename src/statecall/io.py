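"""Readers and writers for the pipeline's file formats.

Supported dialects:

* expression matrices: GCT 1.2 (``#1.2`` header, dimensions line,
  Name/Description columns) and plain TSV (first column gene id);
* gene lists: one identifier per line, ``#`` comments allowed;
* sample-to-tissue maps: two-column TSV;
* chromatin segmentations: BED4 with the state in column 4 ("E1".."E15"
  or "1".."15");
* gene models: BED12 (exon blocks) or GTF (exon features aggregated per
  gene);
* run configuration: YAML; run manifests: JSON.

All matrix readers enforce non-negative values and unique gene ids, with
a distinct diagnostic per failure mode.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

__all__ = [
    "read_expression",
    "read_gct",
    "write_gct",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "read_gene_list",
    "write_gene_list",
    "read_sample_map",
    "write_sample_map",
    "read_bed_segmentation",
    "read_bed12_genes",
    "read_gtf_exons",
    "read_yaml_config",
    "write_manifest",
]


def _validate_matrix(df: pd.DataFrame, path) -> pd.DataFrame:
    dupes = df.index[df.index.duplicated()].unique()
    if len(dupes):
        raise FormatError(
            f"{path}: duplicate gene id(s): {list(map(str, dupes[:5]))}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric abundance values")
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite abundance values")
    if (values < 0).any():
        gene = df.index[(values < 0).any(axis=1)][0]
        raise FormatError(f"{path}: negative abundance for gene {gene!r}")
    df.index.name = "gene_id"
    return df


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 matrix into a genes x samples DataFrame."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(
                f"{path}: expected GCT header '#1.2', got {version!r}"
            )
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimensions line")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed GCT dimensions line") from exc
        body = pd.read_csv(fh, sep="\t")
    if body.columns[0] != "Name" or body.columns[1] != "Description":
        raise FormatError(
            f"{path}: GCT body must start with Name and Description columns"
        )
    if body.shape[0] != n_genes or body.shape[1] - 2 != n_samples:
        raise FormatError(
            f"{path}: dimensions line says {n_genes} x {n_samples} but body "
            f"is {body.shape[0]} x {body.shape[1] - 2}"
        )
    df = body.drop(columns="Description").set_index("Name")
    return _validate_matrix(df, path)


def write_gct(df: pd.DataFrame, path, descriptions=None) -> None:
    """Write a genes x samples DataFrame as GCT 1.2."""
    path = Path(path)
    desc = (
        descriptions if descriptions is not None
        else pd.Series("na", index=df.index)
    )
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = df.copy()
        out.insert(0, "Description", desc)
        out.index.name = "Name"
        out.to_csv(fh, sep="\t")


def read_tsv_matrix(path) -> pd.DataFrame:
    """Read a plain TSV matrix (first column gene id, rest samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return _validate_matrix(df, path)


def write_tsv_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_expression(path, format: str | None = None) -> pd.DataFrame:
    """Read an expression matrix, auto-detecting GCT by its header."""
    path = Path(path)
    if format is None:
        with open(path) as fh:
            format = "gct" if fh.readline().startswith("#1.2") else "tsv"
    if format == "gct":
        return read_gct(path)
    if format == "tsv":
        return read_tsv_matrix(path)
    raise FormatError(f"unknown expression format {format!r}")


def read_gene_list(path) -> list[str]:
    """One gene id per line; '#' comments and blank lines ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_sample_map(path) -> pd.Series:
    """Two-column TSV (sample_id, tissue) -> Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: sample map needs two columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="tissue")
    if s.index.duplicated().any():
        dupes = s.index[s.index.duplicated()].unique()
        raise FormatError(f"{path}: duplicate sample id(s): {list(dupes[:5])}")
    return s


def write_sample_map(tissue_of: pd.Series, path) -> None:
    pd.DataFrame(
        {"sample_id": tissue_of.index, "tissue": tissue_of.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_bed_segmentation(path) -> pd.DataFrame:
    """BED4 chromatin segmentation -> chrom, start, end, state."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "state"],
        dtype={0: str, 3: str},
    )
    if df.empty:
        raise FormatError(f"{path}: empty segmentation")
    return df


def write_bed_segmentation(seg: pd.DataFrame, path) -> None:
    seg[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed12_genes(path) -> pd.DataFrame:
    """BED12 gene models -> gene_id, chrom, start, end, exon lists.

    Exon intervals are reconstructed from blockStarts/blockSizes; all
    coordinates stay 0-based half-open.
    """
    cols = [
        "chrom", "start", "end", "name", "score", "strand", "thick_start",
        "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#",
                     dtype={0: str, 3: str})
    rows = []
    for row in df.itertuples(index=False):
        try:
            sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
            offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        except ValueError as exc:
            raise FormatError(
                f"{path}: malformed block columns for {row.name!r}"
            ) from exc
        if len(sizes) != int(row.block_count) or len(sizes) != len(offsets):
            raise FormatError(
                f"{path}: block count mismatch for gene {row.name!r}"
            )
        starts = [int(row.start) + o for o in offsets]
        ends = [s + z for s, z in zip(starts, sizes)]
        rows.append(
            {
                "gene_id": row.name, "chrom": row.chrom,
                "start": int(row.start), "end": int(row.end),
                "exon_starts": starts, "exon_ends": ends,
            }
        )
    out = pd.DataFrame(rows)
    if out["gene_id"].duplicated().any():
        dupes = out.loc[out["gene_id"].duplicated(), "gene_id"].unique()
        raise FormatError(f"{path}: duplicate gene id(s): {list(dupes[:5])}")
    return out


def write_bed12_genes(genes: pd.DataFrame, path) -> None:
    """Write the gene-model table produced by the simulator as BED12."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            sizes = [e - s for s, e in zip(row.exon_starts, row.exon_ends)]
            offsets = [s - row.start for s in row.exon_starts]
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            row.chrom, row.start, row.end, row.gene_id, 0,
                            "+", row.start, row.end, "0,0,0", len(sizes),
                            ",".join(map(str, sizes)) + ",",
                            ",".join(map(str, offsets)) + ",",
                        ],
                    )
                )
                + "\n"
            )


def read_gtf_exons(path) -> pd.DataFrame:
    """Aggregate GTF exon features per gene into the gene-model table.

    Only ``exon`` features are used; the gene body is the min/max span of
    a gene's exons. GTF is 1-based closed; output is 0-based half-open.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "feature", "start", "end", "score",
               "strand", "frame", "attributes"],
        dtype={0: str},
    )
    exons = df[df["feature"] == "exon"].copy()
    if exons.empty:
        raise FormatError(f"{path}: no exon features found")
    gene_ids = exons["attributes"].str.extract(r'gene_id "([^"]+)"')[0]
    if gene_ids.isna().any():
        raise FormatError(f"{path}: exon feature without a gene_id attribute")
    exons["gene_id"] = gene_ids
    rows = []
    for (gid, chrom), grp in exons.groupby(["gene_id", "chrom"], sort=True):
        starts = sorted(int(s) - 1 for s in grp["start"])
        ends = sorted(int(e) for e in grp["end"])
        rows.append(
            {
                "gene_id": gid, "chrom": chrom,
                "start": starts[0], "end": ends[-1],
                "exon_starts": starts, "exon_ends": ends,
            }
        )
    return pd.DataFrame(rows)


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
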