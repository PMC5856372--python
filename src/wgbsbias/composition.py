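"""Mono-/dinucleotide composition and the observed-vs-expected bias report.

A bisulfite library that faithfully sampled its genome would show read
footprints whose base composition matches the genomic one.  Bisulfite-induced
degradation depletes C-containing sequence, PCR amplification enriches
G-containing (or, for some polymerases, AT-rich) sequence; both leave a
fingerprint in the log2 ratio of observed to expected k-mer fractions.
Composition of read footprints is always taken from the *reference* sequence
under the footprint, never the read itself, because conversion rewrites
unmethylated C as T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, Optional

import pandas as pd

from .refio import BsAlignment, ReferenceGenome

BASES = ("A", "C", "G", "T")
DINUCLEOTIDES = tuple("".join(p) for p in product(BASES, repeat=2))


@dataclass
class CompositionTable:
    """Raw mono- and dinucleotide counts with derived fractions."""

    mono_counts: Dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in BASES}
    )
    di_counts: Dict[str, int] = field(
        default_factory=lambda: {d: 0 for d in DINUCLEOTIDES}
    )

    @property
    def total_mono(self) -> int:
        return sum(self.mono_counts.values())

    @property
    def total_di(self) -> int:
        return sum(self.di_counts.values())

    def mono_fraction(self, base: str) -> float:
        t = self.total_mono
        return self.mono_counts[base] / t if t else float("nan")

    def di_fraction(self, di: str) -> float:
        t = self.total_di
        return self.di_counts[di] / t if t else float("nan")

    def percent(self, kmer: str) -> float:
        if len(kmer) == 1:
            return 100.0 * self.mono_fraction(kmer)
        return 100.0 * self.di_fraction(kmer)

    def add_sequence(self, seq: str) -> None:
        """Tally one contiguous stretch; windows containing N are skipped."""
        mono = self.mono_counts
        for ch in seq:
            if ch in mono:
                mono[ch] += 1
        di = self.di_counts
        for i in range(len(seq) - 1):
            pair = seq[i : i + 2]
            if pair in di:
                di[pair] += 1

    def __add__(self, other: "CompositionTable") -> "CompositionTable":
        return CompositionTable(
            {b: self.mono_counts[b] + other.mono_counts[b] for b in BASES},
            {d: self.di_counts[d] + other.di_counts[d] for d in DINUCLEOTIDES},
        )


def genome_composition(
    genome: ReferenceGenome, exclude_n: bool = True
) -> CompositionTable:
    """Composition of a reference genome.

    Dinucleotides are counted over every overlapping adjacent pair within a
    record (never across record boundaries); any window containing N is
    skipped.  With ``exclude_n`` false, N still contributes nothing to the
    ACGT counts, so the flag only matters for bookkeeping symmetry with
    observed tallies.
    """
    if not genome.records or genome.total_length == 0:
        raise ValueError("empty genome")
    table = CompositionTable()
    for _, seq in genome.items():
        table.add_sequence(seq)
    return table


def observed_composition(
    alignments: Iterable[BsAlignment],
    genome: ReferenceGenome,
    include_duplicates: bool = False,
) -> CompositionTable:
    """Composition of the genomic sequence under aligned read footprints.

    Each retained read of footprint length L contributes L mono counts and
    L-1 overlapping dinucleotide counts (coverage-weighted: a base covered
    by two reads is counted twice).
    """
    table = CompositionTable()
    for aln in alignments:
        if aln.is_duplicate and not include_duplicates:
            continue
        iv = aln.interval
        if iv.chrom not in genome:
            raise ValueError(f"read {aln.read_id}: unknown reference {iv.chrom}")
        seq = genome[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"read {aln.read_id}: footprint {iv.chrom}:{iv.start}-{iv.end} "
                f"beyond reference length {len(seq)}"
            )
        table.add_sequence(seq[iv.start : iv.end])
    return table


@dataclass(frozen=True)
class BiasEntry:
    kmer: str
    observed_fraction: float
    expected_fraction: float
    log2_ratio: Optional[float]  # None when either fraction is zero
    undefined: bool


@dataclass
class CompositionBiasReport:
    """Per-k-mer observed/expected fractions with log2 ratios (bam2nuc)."""

    entries: Dict[str, BiasEntry]
    observed: CompositionTable
    expected: CompositionTable

    def log2_ratio(self, kmer: str) -> Optional[float]:
        return self.entries[kmer].log2_ratio

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for kmer, e in self.entries.items():
            if len(kmer) == 1:
                gcount = self.expected.mono_counts[kmer]
                scount = self.observed.mono_counts[kmer]
            else:
                gcount = self.expected.di_counts[kmer]
                scount = self.observed.di_counts[kmer]
            rows.append(
                {
                    "(di)nucleotide": kmer,
                    "genome_count": gcount,
                    "genome_percent": round(100 * e.expected_fraction, 4),
                    "sample_count": scount,
                    "sample_percent": round(100 * e.observed_fraction, 4),
                    "log2_ratio": (
                        round(e.log2_ratio, 4) if e.log2_ratio is not None else None
                    ),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


def bias_report(
    observed: CompositionTable, expected: CompositionTable
) -> CompositionBiasReport:
    """log2(observed fraction / expected fraction) per mono- and dinucleotide.

    Ratios are defined only when both fractions are positive; degenerate
    entries are flagged rather than fabricated.
    """
    if observed.total_mono == 0 or expected.total_mono == 0:
        raise ValueError("degenerate composition table (zero total)")
    entries: Dict[str, BiasEntry] = {}
    for kmer in BASES + DINUCLEOTIDES:
        if len(kmer) == 1:
            obs, exp = observed.mono_fraction(kmer), expected.mono_fraction(kmer)
        else:
            obs, exp = observed.di_fraction(kmer), expected.di_fraction(kmer)
        if obs > 0 and exp > 0:
            entries[kmer] = BiasEntry(kmer, obs, exp, math.log2(obs / exp), False)
        else:
            entries[kmer] = BiasEntry(kmer, obs, exp, None, True)
    return CompositionBiasReport(entries, observed, expected)


def write_strand_content_wig(
    genome: ReferenceGenome, window: int, base: str, path=None
) -> str:
    """fixedStep wiggle of top-strand G or C fraction per window.

    Bottom-strand G content equals top-strand C content (and vice versa),
    so the two top-strand tracks describe both strands.  A final partial
    window is emitted as its own fixedStep block with its true span.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if base not in ("G", "C"):
        raise ValueError("base must be G or C")
    lines = []
    for name, seq in genome.items():
        w = min(window, len(seq))
        pos = 0
        current_span = None
        while pos < len(seq):
            chunk = seq[pos : pos + w]
            span = len(chunk)
            if span != current_span:
                lines.append(
                    f"fixedStep chrom={name} start={pos + 1} step={span} span={span}"
                )
                current_span = span
            denom = sum(1 for c in chunk if c != "N")
            frac = chunk.count(base) / denom if denom else 0.0
            lines.append(f"{frac:.6g}")
            pos += span
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
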