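"""Sequence, annotation and table I/O plus shared primitive sequence operations.

Internal conventions
--------------------
* Coordinates are 0-based, half-open.  GFF3 (1-based, inclusive) is converted
  at the parsing boundary.
* All sequences are stored in the DNA alphabet {A, C, G, T}; ``U`` is accepted
  on input and silently mapped to ``T``.  Degenerate IUPAC codes are rejected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T} (after U->T)."""


class SchemaError(ValueError):
    """A delimited table does not carry the expected columns."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T, and verify the DNA alphabet.

    Raises
    ------
    AlphabetError
        If the normalized sequence is empty or contains a non-ACGT character
        (degenerate IUPAC codes are rejected rather than guessed).
    """
    s = seq.strip().upper().replace("U", "T")
    if not s:
        raise AlphabetError("empty sequence")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-ACGT characters after normalization: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string."""
    s = normalize_sequence(seq)
    return s.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    s = normalize_sequence(seq)
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class NucleotideSequence:
    """A named DNA sequence, e.g. one terminator part."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, reverse_complement(self.seq), self.description)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with the boundary where its downstream window begins.

    ``stop_codon_end`` is the genomic coordinate immediately past the stop
    codon *on the gene strand*: equal to ``interval.end`` for ``+`` genes and
    ``interval.start`` for ``-`` genes (the downstream window of a minus-strand
    gene extends leftwards and is read as reverse complement).
    """

    gene_id: str
    interval: GenomicInterval

    @property
    def stop_codon_end(self) -> int:
        return self.interval.end if self.interval.strand == "+" else self.interval.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-)FASTA file into normalized :class:`NucleotideSequence`."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(NucleotideSequence(rec.id, str(rec.seq), rec.description))
    return records


def write_fasta(records: list[NucleotideSequence], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneModel]:
    """Parse gene models from a GFF3 file.

    1-based inclusive GFF coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            if feat.strand not in ("+", "-"):
                raise ValueError(
                    f"unknown strand {feat.strand!r} for feature at "
                    f"{feat.seqid}:{feat.start}-{feat.end}"
                )
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            genes.append(GeneModel(gene_id, interval))
    return genes


def write_gff(genes: list[GeneModel], path: str | Path, source: str = "haloterm") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.contig}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a delimited text table (separator auto-detected by extension)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"table {path} missing required column(s): {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep_for(path), index=False)
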