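"""Plain-text I/O helpers: FASTQ, FASTA, barcode and coordinate tables.

Coordinates in every table are 0-based, half-open.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path):
    """Iterate (name, sequence, quality) triples from a FASTQ file."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence, entry.quality


def write_fasta(path, records: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_barcode_table(path, barcodes: Mapping[str, str]) -> None:
    pd.Series(barcodes, name="barcode").rename_axis("accession").to_csv(
        path, sep="\t"
    )


def read_barcode_table(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["accession"], df["barcode"]))


def write_cds_table(path, cds_table: pd.DataFrame) -> None:
    cds_table.to_csv(path, sep="\t")


def read_cds_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("transcript_id")


def read_genotype_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.fillna(-1).astype("int8")
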