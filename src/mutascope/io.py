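"""Format helpers: FASTA/FASTQ via Biopython, TSV via pandas."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import NucleotideSequence
from .synthetic_data import ReadSet


def write_fasta(seqs: list[NucleotideSequence] | NucleotideSequence, path) -> None:
    if isinstance(seqs, NucleotideSequence):
        seqs = [seqs]
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[NucleotideSequence]:
    return [
        NucleotideSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_single_fasta(path) -> NucleotideSequence:
    seqs = read_fasta(path)
    if len(seqs) != 1:
        raise ValueError(f"{path} must contain exactly one sequence, found {len(seqs)}")
    return seqs[0]


def write_fastq(reads: ReadSet, path) -> None:
    Path(path).write_bytes(reads.fastq_bytes())


def read_fastq(path) -> ReadSet:
    with open(path) as handle:
        return ReadSet.from_fastq(handle)


def read_sam_anchored(path) -> list[tuple[str, int]]:
    """Read (bases, 1-based offset) pairs from a SAM of ungapped alignments.

    Alignments whose CIGAR contains anything other than aligned-match
    operations (M/=/X) are rejected; unmapped records are skipped.
    """
    import pysam

    pairs: list[tuple[str, int]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if any(op not in (0, 7, 8) for op, _ in rec.cigartuples or []):
                raise ValueError(
                    f"read {rec.query_name}: only ungapped alignments are "
                    f"supported (CIGAR {rec.cigarstring})"
                )
            pairs.append((rec.query_sequence.upper(), rec.reference_start + 1))
    return pairs
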