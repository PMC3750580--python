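"""File format helpers: FASTA/FASTQ via Biopython, minimal GFF3, TSV maps.

All coordinates are 0-based half-open in memory; GFF3 I/O converts to/from
the 1-based inclusive convention of the format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene interval (0-based half-open internally)."""

    seq_id: str
    start: int
    end: int
    strand: str
    name: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Return an insertion-ordered mapping id -> sequence (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")}


def write_fastq(path: str | os.PathLike, seqs: Mapping[str, str], quality: int = 40) -> None:
    records = []
    for name, s in seqs.items():
        rec = SeqRecord(Seq(s), id=name, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(s)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_gff3(path: str | os.PathLike) -> List[GeneAnnotation]:
    out: List[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seq_id, _source, _type, start, end, _score, strand, _phase, attrs = cols
            name = ""
            for field in attrs.split(";"):
                if field.startswith(("Name=", "ID=")) and not name:
                    name = field.split("=", 1)[1]
            out.append(
                GeneAnnotation(
                    seq_id=seq_id,
                    start=int(start) - 1,  # GFF3 is 1-based inclusive
                    end=int(end),
                    strand=strand,
                    name=name,
                )
            )
    return out


def write_gff3(path: str | os.PathLike, annotations: Iterable[GeneAnnotation],
               source: str = "hgtscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                "\t".join(
                    [
                        a.seq_id,
                        source,
                        "gene",
                        str(a.start + 1),
                        str(a.end),
                        ".",
                        a.strand,
                        ".",
                        f"ID={a.name};Name={a.name}",
                    ]
                )
                + "\n"
            )


def read_taxmap(path: str | os.PathLike) -> Dict[str, str]:
    """Read a two-column species -> taxon_group TSV."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            species, group = line.split("\t")[:2]
            out[species] = group
    return out


def write_taxmap(path: str | os.PathLike, taxmap: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for species in sorted(taxmap):
            fh.write(f"{species}\t{taxmap[species]}\n")


def read_tsv_rows(path: str | os.PathLike) -> List[List[str]]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip() and not line.startswith("#")]


def species_of_subject(subject_id: str) -> str:
    """Subject ids follow the '<species>|<protein>' convention; bare ids are
    treated as their own species."""
    return subject_id.split("|", 1)[0]
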