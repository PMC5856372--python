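"""Readers/writers and the shared coordinate/data model.

Everything downstream works in a single coordinate convention: 0-based,
half-open intervals on named reference sequences.  Aligned bisulfite reads
are represented by :class:`BsAlignment`, which carries a per-reference-position
methylation call string in the Bismark dialect:

====== =========================================
char   meaning
====== =========================================
z / Z  cytosine in CpG context (converted / unconverted)
x / X  cytosine in CHG context
h / H  cytosine in CHH context
u / U  cytosine in unknown context
.      not a cytosine on the read's parent strand
====== =========================================

Uppercase = unconverted, read as methylated.  The call string is stored in
reference orientation (left to right along the top strand), matching how
SAM stores SEQ and the XM tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional

import pysam
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
CALL_CHARS = frozenset("zZxXhHuU.")

#: bisulfite strand labels: original top/bottom and their PCR complements
BS_STRANDS = ("OT", "OB", "CTOT", "CTOB")

#: bs_strand values whose methylation calls report on the top (+) strand
TOP_PARENT = frozenset({"OT", "CTOT"})

#: bs_strand values whose read 5' end sits at the *right* edge of the
#: reference footprint (Bismark single-end flag-16 orientations)
REVERSE_READ = frozenset({"OB", "CTOT"})


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass
class ReferenceGenome:
    """Ordered mapping of sequence name -> uppercase nucleotide string."""

    records: Dict[str, str]

    def __post_init__(self) -> None:
        clean: Dict[str, str] = {}
        for name, seq in self.records.items():
            if not name:
                raise FormatError("empty sequence name")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"record {name!r}: illegal character(s) {sorted(bad)}"
                )
            clean[name] = seq
        self.records = clean

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def items(self):
        return self.records.items()

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class BsAlignment:
    """An ungapped aligned bisulfite read with its methylation call string."""

    read_id: str
    interval: GenomicInterval
    bs_strand: str
    call_string: str
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.bs_strand not in BS_STRANDS:
            raise ValueError(f"unknown bs_strand {self.bs_strand!r}")
        if len(self.call_string) != len(self.interval):
            raise ValueError(
                f"read {self.read_id}: call string length "
                f"{len(self.call_string)} != footprint {len(self.interval)}"
            )
        bad = set(self.call_string) - CALL_CHARS
        if bad:
            raise ValueError(f"read {self.read_id}: bad call chars {bad}")

    @property
    def parent_strand(self) -> str:
        """Strand whose cytosines the call string reports on."""
        return "+" if self.bs_strand in TOP_PARENT else "-"

    @property
    def read_is_reverse(self) -> bool:
        """True when the read's 5' end maps to the right footprint edge."""
        return self.bs_strand in REVERSE_READ

    def with_call_string(self, call_string: str) -> "BsAlignment":
        return replace(self, call_string=call_string)


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise ValueError(f"read {self.read_id}: illegal characters {bad}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> ReferenceGenome:
    """Read a multi-record FASTA into a :class:`ReferenceGenome`.

    Sequences are upcased; input order is preserved.  Malformed input raises
    :class:`FormatError` naming the offending line where it can be located.
    """
    records: Dict[str, str] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not parsed:
        raise FormatError(f"{path}: no FASTA records (malformed header?)")
    for rec in parsed:
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}:{_find_bad_line(path, bad)}: "
                f"illegal character(s) {sorted(bad)} in record {rec.id!r}"
            )
        records[rec.id] = seq
    return ReferenceGenome(records)


def _find_bad_line(path, bad_chars) -> int:
    bad_upper = {c.upper() for c in bad_chars}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_upper:
                return lineno
    return 0


def write_fasta(path, genome: ReferenceGenome, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED intervals


def read_intervals(path) -> List[GenomicInterval]:
    """Read BED3+ into 0-based half-open intervals; strand column honoured."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_intervals(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is None and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t0\t{iv.strand if iv.strand != '.' else '+'}\n"
                )


# ---------------------------------------------------------------------------
# SAM/BAM alignments (Bismark XM/XR/XG tag dialect)

# XG (genome conversion) CT -> parent strand top, GA -> bottom;
# combined with XR (read conversion) to distinguish originals from
# their PCR complements.
_TAG_TO_STRAND = {
    ("CT", "CT"): "OT",
    ("GA", "CT"): "CTOT",
    ("CT", "GA"): "OB",
    ("GA", "GA"): "CTOB",
}


@dataclass
class AlignmentStream:
    """Single-pass iterator of :class:`BsAlignment` with skip counters."""

    _iter: Iterator[BsAlignment] = field(repr=False)
    skipped_gapped: int = 0
    skipped_unmapped: int = 0

    def __iter__(self) -> Iterator[BsAlignment]:
        return self._iter

    def __next__(self) -> BsAlignment:
        return next(self._iter)


def read_alignments(path) -> AlignmentStream:
    """Stream BsAlignments from a SAM/BAM file carrying XM/XR/XG tags.

    Only ungapped alignments (pure-match CIGAR) are accepted; gapped or
    clipped records are skipped and counted on the returned stream.  A
    mapped record without an XM tag is a hard error.
    """
    stream = AlignmentStream(_iter=iter(()))

    def gen() -> Iterator[BsAlignment]:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for rec in af:
                if rec.is_unmapped:
                    stream.skipped_unmapped += 1
                    continue
                cig = rec.cigartuples or []
                if any(op not in (0, 7, 8) for op, _ in cig):
                    stream.skipped_gapped += 1
                    continue
                if not rec.has_tag("XM"):
                    raise FormatError(
                        f"{path}: read {rec.query_name} lacks an XM call-string tag"
                    )
                xm = rec.get_tag("XM")
                xr = rec.get_tag("XR") if rec.has_tag("XR") else "CT"
                xg = rec.get_tag("XG") if rec.has_tag("XG") else "CT"
                bs_strand = _TAG_TO_STRAND.get((xr, xg))
                if bs_strand is None:
                    raise FormatError(
                        f"{path}: read {rec.query_name}: bad XR/XG pair ({xr},{xg})"
                    )
                iv = GenomicInterval(
                    rec.reference_name, rec.reference_start, rec.reference_end
                )
                yield BsAlignment(
                    read_id=rec.query_name,
                    interval=iv,
                    bs_strand=bs_strand,
                    call_string=xm,
                    is_duplicate=rec.is_duplicate,
                )

    stream._iter = gen()
    return stream


_STRAND_TO_TAG = {v: k for k, v in _TAG_TO_STRAND.items()}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_alignments(
    path,
    alignments: Iterable[BsAlignment],
    chrom_lengths: Dict[str, int],
    sequences: Optional[Dict[str, str]] = None,
) -> int:
    """Write alignments as SAM.  Returns the number of records written.

    ``sequences`` optionally maps read_id -> read sequence (read
    orientation); when absent SEQ is written as '*'.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in chrom_lengths.items()],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_name = aln.interval.chrom
            rec.reference_start = aln.interval.start
            rec.mapping_quality = 255
            rec.cigarstring = f"{len(aln.interval)}M"
            flag = 0
            if aln.read_is_reverse:
                flag |= 0x10
            if aln.is_duplicate:
                flag |= 0x400
            rec.flag = flag
            if sequences and aln.read_id in sequences:
                seq = sequences[aln.read_id]
                # SAM stores SEQ in reference orientation
                rec.query_sequence = revcomp(seq) if aln.read_is_reverse else seq
            xr, xg = _STRAND_TO_TAG[aln.bs_strand]
            rec.set_tags(
                [("XM", aln.call_string, "Z"), ("XR", xr, "Z"), ("XG", xg, "Z")]
            )
            out.write(rec)
            n += 1
    return n


def read_raw_reads(path) -> List[RawRead]:
    """Read FASTQ or plain one-sequence-per-line text into RawReads."""
    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return [
            RawRead(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(path, "fastq")
        ]
    out: List[RawRead] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if line:
                out.append(RawRead(f"read{i}", line.upper()))
    return out
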