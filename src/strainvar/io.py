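"""Readers and writers for the formats the caller consumes and emits.

The pipeline works in a marker-gene frame: a FASTA allele database whose
headers encode gene and allele identity (rMLST-style, e.g. ``BACT000001_12``),
FASTQ reads with per-base Phred qualities, and SAM alignments of reads against
database alleles.  Coordinates are 0-based half-open internally; 1-based only
in human-readable report files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

#: CIGAR operation codes used internally (a subset of the SAM spec).
OP_MATCH, OP_INS, OP_DEL, OP_SOFTCLIP = 0, 1, 2, 4


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class Allele:
    allele_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


class AlleleDatabase:
    """Marker-gene allele database: gene id -> known allele sequences.

    Serves two roles: source of alignment templates and the novelty oracle
    (a substitution is *novel* when no allele of the gene carries it).
    """

    def __init__(self, genes: Mapping[str, Sequence[Allele]] | None = None):
        self.genes: dict[str, list[Allele]] = {}
        if genes:
            for gene_id, alleles in genes.items():
                for allele in alleles:
                    self.add(gene_id, allele.allele_id, allele.sequence)

    def add(self, gene_id: str, allele_id: str, sequence: str) -> None:
        sequence = sequence.upper()
        if not sequence:
            raise FormatError(f"empty sequence for {gene_id}/{allele_id}")
        bad = set(sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"non-DNA characters {sorted(bad)} in {gene_id}/{allele_id}"
            )
        alleles = self.genes.setdefault(gene_id, [])
        if any(a.allele_id == allele_id for a in alleles):
            raise FormatError(f"duplicate allele header: {gene_id}/{allele_id}")
        alleles.append(Allele(allele_id, sequence))

    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def alleles(self, gene_id: str) -> list[Allele]:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene: {gene_id}") from None

    def get(self, gene_id: str, allele_id: str) -> Allele:
        for allele in self.alleles(gene_id):
            if allele.allele_id == allele_id:
                return allele
        raise KeyError(f"unknown allele: {gene_id}/{allele_id}")

    def n_alleles(self) -> int:
        return sum(len(v) for v in self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def to_fasta(self, path: str | Path, header_separator: str = "_") -> None:
        records = [
            SeqRecord(Seq(a.sequence), id=f"{g}{header_separator}{a.allele_id}",
                      description="")
            for g, alleles in self.genes.items() for a in alleles
        ]
        SeqIO.write(records, str(path), "fasta")


def split_reference_name(name: str, header_separator: str = "_") -> tuple[str, str]:
    """Split ``<gene><sep><allele>`` on the last separator occurrence."""
    gene, sep, allele = name.rpartition(header_separator)
    if not sep or not gene or not allele:
        raise FormatError(
            f"header {name!r} does not contain gene{header_separator}allele"
        )
    return gene, allele


def load_allele_db(path: str | Path, header_separator: str = "_") -> AlleleDatabase:
    """Load a marker-gene allele database from FASTA.

    Headers must contain gene and allele tokens joined by *header_separator*;
    the gene id is everything before the last separator.  Sequences are
    upper-cased.  Duplicate (gene, allele) headers and empty files are errors.
    """
    db = AlleleDatabase()
    for record in SeqIO.parse(str(path), "fasta"):
        gene_id, allele_id = split_reference_name(record.id, header_separator)
        db.add(gene_id, allele_id, str(record.seq))
    if len(db) == 0:
        raise FormatError(f"no FASTA records in {path}")
    return db


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: np.ndarray  # integer Phred scores, same length as sequence

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    @property
    def mean_quality(self) -> float:
        """Arithmetic mean of the Phred integers (NaN for an empty read)."""
        if len(self.qualities) == 0:
            return float("nan")
        return float(self.qualities.mean())


def filter_reads_by_quality(
    reads: Iterable[Read],
    min_q: float = 14.0,
    *,
    stats: dict | None = None,
) -> list[Read]:
    """Retain reads whose arithmetic mean Phred score is >= *min_q*.

    Whole-read quality trimming is the only read-level filter applied; reads
    are otherwise used as aligned.  Order is preserved and the operation is
    idempotent.  Empty reads are excluded and counted in ``stats['skipped_empty']``
    when a *stats* dict is supplied.
    """
    if min_q < 0:
        raise ValueError("min_q must be >= 0")
    kept: list[Read] = []
    removed = skipped = 0
    for read in reads:
        if len(read.sequence) == 0:
            skipped += 1
            continue
        if read.mean_quality >= min_q:
            kept.append(read)
        else:
            removed += 1
    if skipped:
        logger.warning("filter_reads_by_quality: skipped %d empty reads", skipped)
    if stats is not None:
        stats.update(kept=len(kept), removed=removed, skipped_empty=skipped)
    return kept


def read_fastq(path: str | Path) -> Iterator[Read]:
    for record in SeqIO.parse(str(path), "fastq"):
        yield Read(
            record.id,
            str(record.seq).upper(),
            np.asarray(record.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in read.qualities]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


@dataclass
class AlignmentRecord:
    """One read-to-allele alignment, CIGAR-backed.

    ``cigar`` is a list of (op, length) with SAM numeric op codes restricted to
    match (0), insertion (1), deletion (2) and soft-clip (4; leading/trailing
    only).  Soft-clipped bases are present in ``sequence`` but excluded from
    the aligned columns.
    """

    read_id: str
    gene_id: str
    allele_id: str
    ref_start: int
    cigar: list[tuple[int, int]]
    sequence: str
    qualities: np.ndarray | None = None
    _cols: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities)

    def column_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(ref_pos, read_pos) over match/deletion columns; read_pos -1 at deletions."""
        if self._cols is None:
            refs: list[np.ndarray] = []
            rpos: list[np.ndarray] = []
            r = self.ref_start
            q = 0
            for op, length in self.cigar:
                if op == OP_MATCH:
                    refs.append(np.arange(r, r + length, dtype=np.int64))
                    rpos.append(np.arange(q, q + length, dtype=np.int64))
                    r += length
                    q += length
                elif op == OP_DEL:
                    refs.append(np.arange(r, r + length, dtype=np.int64))
                    rpos.append(np.full(length, -1, dtype=np.int64))
                    r += length
                elif op in (OP_INS, OP_SOFTCLIP):
                    q += length
                else:  # pragma: no cover - guarded by readers
                    raise ValueError(f"unsupported CIGAR op {op}")
            if refs:
                self._cols = (np.concatenate(refs), np.concatenate(rpos))
            else:
                self._cols = (
                    np.empty(0, dtype=np.int64),
                    np.empty(0, dtype=np.int64),
                )
            if len(self._cols[1]) and self._cols[1].max() >= len(self.sequence):
                raise ValueError(f"{self.read_id}: CIGAR overruns read length")
        return self._cols

    @property
    def aligned_pairs(self) -> list[tuple[int | None, int | None]]:
        """All aligned columns as (ref_pos | None, read_pos | None).

        Matches/mismatches give both coordinates, deletions a None read
        position and insertions a None reference position; soft-clips are
        excluded.
        """
        pairs: list[tuple[int | None, int | None]] = []
        r = self.ref_start
        q = 0
        for op, length in self.cigar:
            if op == OP_MATCH:
                pairs.extend((r + i, q + i) for i in range(length))
                r += length
                q += length
            elif op == OP_DEL:
                pairs.extend((r + i, None) for i in range(length))
                r += length
            elif op == OP_INS:
                pairs.extend((None, q + i) for i in range(length))
                q += length
            elif op == OP_SOFTCLIP:
                q += length
        return pairs

    @property
    def ref_end(self) -> int:
        """End (exclusive) of the reference span."""
        return self.ref_start + sum(
            length for op, length in self.cigar if op in (OP_MATCH, OP_DEL)
        )

    def base_at(self, ref_pos: int) -> str | None:
        """Read base aligned to *ref_pos*; '-' at a deletion; None if uncovered."""
        refs, rpos = self.column_arrays()
        idx = np.searchsorted(refs, ref_pos)
        if idx >= len(refs) or refs[idx] != ref_pos:
            return None
        q = rpos[idx]
        return "-" if q < 0 else self.sequence[q]


def read_sam(
    path: str | Path,
    db: AlleleDatabase,
    header_separator: str = "_",
) -> list[AlignmentRecord]:
    """Parse a SAM file into alignment records against *db* alleles.

    Secondary, supplementary and unmapped records are dropped.  Reference
    names must resolve to a (gene, allele) present in the database; unknown
    names raise an error listing the offenders.  Records with no CIGAR are
    skipped with a warning.
    """
    records: list[AlignmentRecord] = []
    unknown: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.cigartuples is None:
                warnings.warn(f"record {aln.query_name} has no CIGAR; skipped")
                continue
            gene_id, allele_id = split_reference_name(
                aln.reference_name, header_separator
            )
            if gene_id not in db or not any(
                a.allele_id == allele_id for a in db.alleles(gene_id)
            ):
                unknown.add(aln.reference_name)
                continue
            cigar = [(op, length) for op, length in aln.cigartuples]
            bad_ops = {op for op, _ in cigar} - {OP_MATCH, OP_INS, OP_DEL, OP_SOFTCLIP}
            if bad_ops:
                raise FormatError(
                    f"record {aln.query_name}: unsupported CIGAR ops {sorted(bad_ops)}"
                )
            quals = (
                np.asarray(aln.query_qualities, dtype=np.int64)
                if aln.query_qualities is not None
                else None
            )
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    gene_id=gene_id,
                    allele_id=allele_id,
                    ref_start=aln.reference_start,
                    cigar=cigar,
                    sequence=(aln.query_sequence or "").upper(),
                    qualities=quals,
                )
            )
    if unknown:
        raise FormatError(
            "SAM reference names absent from the allele database: "
            + ", ".join(sorted(unknown))
        )
    return records


def write_sam(
    records: Sequence[AlignmentRecord],
    db: AlleleDatabase,
    path: str | Path,
    header_separator: str = "_",
) -> None:
    """Write alignment records as plain-text SAM against the database alleles."""
    names: list[str] = []
    lengths: list[int] = []
    for gene_id, alleles in db.genes.items():
        for allele in alleles:
            names.append(f"{gene_id}{header_separator}{allele.allele_id}")
            lengths.append(len(allele.sequence))
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in zip(names, lengths)],
    }
    index = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.query_sequence = rec.sequence
            if rec.qualities is not None:
                seg.query_qualities = [int(q) for q in rec.qualities]
            seg.reference_id = index[
                f"{rec.gene_id}{header_separator}{rec.allele_id}"
            ]
            seg.reference_start = rec.ref_start
            seg.cigartuples = rec.cigar
            seg.mapping_quality = 60
            seg.flag = 0
            out.write(seg)


def write_calls_tsv(calls, path: str | Path) -> None:
    """Write final variant calls as TSV (positions 1-based for reporting)."""
    with open(path, "w") as fh:
        fh.write("gene\tposition\tref\talt\tdepth\tcount\tabundance\tflags\n")
        for c in calls:
            flags = []
            if c.is_novel:
                flags.append("novel")
            if c.is_proximal:
                flags.append("proximal")
            if c.density_M:
                flags.append(f"density={c.density_M}")
            if c.cooccurring:
                flags.append("cooccurring")
            fh.write(
                f"{c.gene_id}\t{c.position + 1}\t{c.ref_base}\t{c.alt_base}\t"
                f"{c.depth}\t{c.count}\t{c.abundance:.6f}\t{','.join(flags)}\n"
            )
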