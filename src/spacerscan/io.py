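"""File-format plumbing: FASTA/FASTQ via Biopython, tables via pandas."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .targetmatch import TargetRecord, parse_target_header

FASTQ_QUALITY_CHAR = "I"  # fixed quality; never used downstream


def _open_maybe_gz(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file (optionally gzipped)."""
    with _open_maybe_gz(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records, path) -> None:
    """Write (id, seq) or (id, description, seq) tuples as FASTA."""
    recs = []
    for r in records:
        if len(r) == 2:
            rid, seq = r
            desc = ""
        else:
            rid, desc, seq = r
        recs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTQ file (optionally gzipped)."""
    with _open_maybe_gz(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(reads, path) -> None:
    """Write reads ((id, seq) pairs or a simdata.ReadSet) with fixed quality."""
    records = reads.records() if hasattr(reads, "records") else reads
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{FASTQ_QUALITY_CHAR * len(seq)}\n")


def read_targets(path) -> list[TargetRecord]:
    """Target database FASTA with ``vOTU=`` / ``category=`` header keys."""
    out = []
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            header = rec.description if rec.description else rec.id
            out.append(parse_target_header(header, str(rec.seq).upper()))
    return out


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def clusters_to_table(clusters) -> pd.DataFrame:
    """One row per member: cluster id, representative flag, sequence, source,
    provenance."""
    rows = []
    for c in clusters:
        for seq, source, prov in c.members:
            rows.append({"cluster": c.id,
                         "is_representative": int(seq == c.representative),
                         "sequence": seq, "source": source, "provenance": prov,
                         "threshold": c.threshold})
    return pd.DataFrame(rows, columns=["cluster", "is_representative",
                                       "sequence", "source", "provenance",
                                       "threshold"])
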