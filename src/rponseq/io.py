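"""Readers and writers for the standard interchange formats.

Internally everything is 0-based half-open; GFF3 is written/read 1-based
inclusive, BED 0-based half-open.  FASTA goes through Biopython, GFF3
reading through gffutils, tabular formats through pandas.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(path, sequence: str, seq_id: str = "genome", width: int = 70) -> None:
    rec = SeqRecord(Seq(sequence), id=seq_id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def read_fasta(path) -> tuple[str, str]:
    """First record of a FASTA file as (seq_id, sequence)."""
    try:
        rec = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise ValueError(f"no FASTA records in {path}") from None
    return rec.id, str(rec.seq).upper()


def write_gff3(path, genes, seq_id: str = "genome", source: str = "rponseq") -> None:
    """Write gene features; input intervals are 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{seq_id}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_gff3(path) -> list[tuple[str, int, int, str]]:
    """Gene features as (gene_id, start, end, strand), 0-based half-open."""
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    out = []
    for f in db.features_of_type("gene", order_by="start"):
        out.append((f.id, f.start - 1, f.end, f.strand))
    return out


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(path, records: list[tuple]) -> None:
    """Write BED6 records (chrom, start, end, name, score, strand)."""
    df = pd.DataFrame(records, columns=BED6_COLUMNS)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLUMNS)


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_yaml(path, obj) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
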