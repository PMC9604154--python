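"""Readers and writers for the plain-text formats the pipeline exchanges.

Count tables use mothur's "shared" layout
(``label<TAB>Group<TAB>numOtus<TAB>counts...``); taxonomy files are
``taxon<TAB>rank1;rank2;...`` TSV; metadata is a samples-by-variables TSV.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(records: dict[str, str], path):
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        os.fspath(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(os.fspath(path), "fasta")}


def write_fastq(records, path):
    """records: iterable of (id, sequence, phred quality list)."""
    def gen():
        for name, seq, quals in records:
            r = SeqRecord(Seq(seq), id=name, description="")
            r.letter_annotations["phred_quality"] = list(quals)
            yield r
    SeqIO.write(gen(), os.fspath(path), "fastq")


def read_fastq(path):
    for r in SeqIO.parse(os.fspath(path), "fastq"):
        yield r.id, str(r.seq), r.letter_annotations["phred_quality"]


# -- shared count tables -----------------------------------------------------


def write_shared(table: pd.DataFrame, path, label: str = "0.02"):
    """Write a samples x units integer count table in mothur shared format."""
    with open(path, "w") as fh:
        cols = list(table.columns)
        fh.write("label\tGroup\tnumOtus\t" + "\t".join(cols) + "\n")
        for sample, row in table.iterrows():
            vals = "\t".join(str(int(v)) for v in row.values)
            fh.write(f"{label}\t{sample}\t{len(cols)}\t{vals}\n")


def read_shared(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.drop(columns=["label", "numOtus"]).set_index("Group")
    df.index.name = "sample"
    return df.astype(int)


# -- taxonomy ---------------------------------------------------------------


def write_taxonomy(taxonomy: dict[str, str], path):
    with open(path, "w") as fh:
        for taxon, lineage in taxonomy.items():
            fh.write(f"{taxon}\t{lineage}\n")


def read_taxonomy(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                taxon, lineage = line.rstrip("\n").split("\t")
                out[taxon] = lineage
    return out


# -- metadata ---------------------------------------------------------------


def write_metadata(meta: pd.DataFrame, path):
    meta.to_csv(path, sep="\t", index_label="sample")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")
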