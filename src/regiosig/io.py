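"""Readers and writers for the plain-text formats the pipeline exchanges.

Bulk counts travel as TSV (gene rows, sample columns) next to a sample
metadata TSV; single-cell counts as MatrixMarket MTX with features.tsv and
barcodes.tsv; gene sets as GMT; universes as one-column gene lists; reports
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ConfigError, CountMatrix, GeneSet

__all__ = [
    "write_counts_tsv", "read_counts_tsv",
    "write_mtx_dir", "read_mtx_dir",
    "write_gmt", "read_gmt",
    "write_gene_list", "read_gene_list",
    "write_json", "read_json",
]


def write_counts_tsv(m: CountMatrix, counts_path, meta_path=None) -> None:
    counts_path = Path(counts_path)
    m.to_frame().to_csv(counts_path, sep="\t")
    if meta_path is not None:
        m.samples.to_csv(Path(meta_path), sep="\t")


def read_counts_tsv(counts_path, meta_path=None) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta = meta.loc[df.columns]
    else:
        meta = pd.DataFrame(index=df.columns)
    return CountMatrix(
        counts=df.to_numpy(dtype=np.int64), gene_ids=df.index, samples=meta
    )


def write_mtx_dir(m: CountMatrix, outdir) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv (+ metadata.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csc_matrix(m.counts))
    pd.Series(m.gene_ids).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(m.sample_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    m.samples.to_csv(outdir / "metadata.tsv", sep="\t")


def read_mtx_dir(indir) -> CountMatrix:
    indir = Path(indir)
    counts = np.asarray(spio.mmread(indir / "matrix.mtx").todense(), dtype=np.int64)
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    meta_path = indir / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0).loc[barcodes]
    else:
        meta = pd.DataFrame(index=pd.Index(barcodes))
    return CountMatrix(counts=counts, gene_ids=pd.Index(genes), samples=meta)


def write_gmt(sets, path) -> None:
    """GMT: one set per line — name, description, tab-separated gene ids."""
    with open(path, "w") as fh:
        for gs in sets:
            desc = json.dumps(gs.provenance, sort_keys=True) if gs.provenance else "."
            fh.write("\t".join([gs.name, desc, *map(str, gs.genes)]) + "\n")


def read_gmt(path) -> list:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ConfigError(f"malformed GMT line: {line!r}")
            sets.append(GeneSet(name=parts[0], genes=parts[2:]))
    return sets


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def read_gene_list(path) -> list:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
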