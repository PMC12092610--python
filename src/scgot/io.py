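"""Readers and writers for every interchange format the pipeline uses.

FASTQ pairs (read 1 = cell barcode + UMI, read 2 = amplicon sequence), a
MatrixMarket count matrix with gene/barcode TSVs, and tab-separated tables
with a commented schema header. Every writer round-trips losslessly through
its paired reader.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData
from Bio import SeqIO

from .config import LocusSpec
from .genotyping import AmpliconRead

__all__ = [
    "ParseError",
    "write_fastq_pair",
    "read_fastq_pair",
    "write_count_matrix",
    "read_count_matrix",
    "write_tsv",
    "read_tsv",
    "file_checksum",
]

SCHEMA_VERSION = "1"


class ParseError(ValueError):
    """Raised on malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq_pair(
    reads: pd.DataFrame,
    locus: LocusSpec,
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    """Write amplicon reads (cell_barcode, umi, locus_base) as a FASTQ pair.

    Read 1 carries barcode + UMI concatenated; read 2 is the locus context
    carrying the wild-type or mutant base at the variant offset. Qualities
    are constant dummies; the pipeline never consumes them.
    """
    ctx = {"WT": locus.wt_context, "MUT": locus.mut_context}
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for i, row in enumerate(reads.itertuples(index=False)):
            name = f"read{i + 1}"
            r1 = row.cell_barcode + row.umi
            r2 = ctx[row.locus_base]
            f1.write(f"@{name} 1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name} 2\n{r2}\n+\n{'I' * len(r2)}\n")


def read_fastq_pair(
    r1_path: str | Path,
    r2_path: str | Path,
    locus: LocusSpec,
    barcode_length: int = 16,
    umi_length: int = 12,
) -> Iterator[AmpliconRead]:
    """Parse a FASTQ pair into amplicon reads.

    Read 1 is split into the first ``barcode_length`` bases (cell barcode)
    and the next ``umi_length`` bases (UMI); read 2 is classified against the
    locus contexts into WT / MUT / OTHER.
    """
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    idx = 0
    for rec1 in it1:
        idx += 1
        rec2 = next(it2, None)
        if rec2 is None:
            raise ParseError(f"unpaired record {idx}: read 2 file is shorter")
        s1 = str(rec1.seq)
        if len(s1) < barcode_length + umi_length:
            raise ParseError(
                f"record {idx}: read 1 length {len(s1)} shorter than "
                f"barcode+UMI ({barcode_length + umi_length})"
            )
        yield AmpliconRead(
            cell_barcode=s1[:barcode_length],
            umi=s1[barcode_length : barcode_length + umi_length],
            locus_base=locus.classify_read(str(rec2.seq)),
        )
    if next(it2, None) is not None:
        raise ParseError(f"unpaired record {idx + 1}: read 1 file is shorter")


# ---------------------------------------------------------------------------
# MatrixMarket count matrix
# ---------------------------------------------------------------------------

def write_count_matrix(
    adata: AnnData,
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write counts as genes x cells MatrixMarket plus gene/barcode TSVs."""
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(str(mtx_path), X.T.tocoo(), field="integer")
    pd.Series(adata.var_names).to_csv(genes_path, sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(
        barcodes_path, sep="\t", index=False, header=False
    )


def read_count_matrix(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> AnnData:
    """Read a genes x cells MatrixMarket matrix into an AnnData (cells as obs)."""
    M = scipy.io.mmread(str(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    M = sp.csr_matrix(M)
    if M.shape != (len(genes), len(barcodes)):
        raise ParseError(
            f"matrix shape {M.shape} does not match {len(genes)} genes x "
            f"{len(barcodes)} barcodes"
        )
    if M.nnz == 0 and (len(genes) == 0 or len(barcodes) == 0):
        raise ParseError("empty count matrix")
    return AnnData(
        X=M.T.tocsr(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


# ---------------------------------------------------------------------------
# TSV with commented schema header
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """Write a table as UTF-8 TSV with a commented schema/provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# scgot schema={SCHEMA_VERSION}")
        if params:
            fh.write(" " + " ".join(f"{k}={v}" for k, v in sorted(params.items())))
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"cell_barcode": str})


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
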