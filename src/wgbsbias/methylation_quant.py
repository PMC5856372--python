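"""Per-cytosine methylation extraction and quantification strategies.

The central object is :class:`PerCytosineMethylation`: per (chrom, position,
strand) counts of methylated and total calls by cytosine context.  On top of
it sit the two region-quantification strategies whose divergence under
coverage bias motivates this toolkit:

* ``pooled`` — all calls in a region pooled, 100 * sum(meth) / sum(total);
  implicitly coverage-weighted, so any correlation between coverage and
  methylation (e.g. degradation sparing methylated molecules) biases it.
* ``cytosine_mean`` — each cytosine's percent computed first, then averaged
  unweighted across cytosines in the region.

Plus global levels, fixed-cytosine-count tiling, differential-region
selection by raw percent difference, and strand-resolved position profiles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .refio import BsAlignment, GenomicInterval, ReferenceGenome

CONTEXTS = ("CG", "CHG", "CHH")
CH_CONTEXTS = frozenset({"CHG", "CHH"})

_CALL_CONTEXT = {
    "z": "CG",
    "Z": "CG",
    "x": "CHG",
    "X": "CHG",
    "h": "CHH",
    "H": "CHH",
    "u": "unknown",
    "U": "unknown",
}

Key = Tuple[str, int, str]  # (chrom, position, strand)


@dataclass
class CytosineRecord:
    context: str
    meth_count: int = 0
    total_count: int = 0
    #: set by corrections that operate on percentages (background
    #: subtraction); when present it supersedes the count-derived percent
    percent_override: Optional[float] = None

    @property
    def percent(self) -> Optional[float]:
        if self.percent_override is not None:
            return self.percent_override
        if self.total_count == 0:
            return None
        return 100.0 * self.meth_count / self.total_count


@dataclass
class PerCytosineMethylation:
    """Per-position, per-strand methylation call counts by context."""

    records: Dict[Key, CytosineRecord] = field(default_factory=dict)
    #: optional coordinate frame for mismatch checks
    chrom_sizes: Optional[Dict[str, int]] = None
    context_conflicts: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: Key) -> CytosineRecord:
        return self.records[key]

    def __contains__(self, key: Key) -> bool:
        return key in self.records

    def items(self):
        return self.records.items()

    def copy(self) -> "PerCytosineMethylation":
        return PerCytosineMethylation(
            records={
                k: CytosineRecord(
                    r.context, r.meth_count, r.total_count, r.percent_override
                )
                for k, r in self.records.items()
            },
            chrom_sizes=dict(self.chrom_sizes) if self.chrom_sizes else None,
            context_conflicts=self.context_conflicts,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": chrom,
                "start": pos,
                "end": pos + 1,
                "strand": strand,
                "context": rec.context,
                "meth_count": rec.meth_count,
                "total_count": rec.total_count,
                "percent": rec.percent,
            }
            for (chrom, pos, strand), rec in sorted(self.records.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "strand",
                "context", "meth_count", "total_count", "percent",
            ],
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


def extract_per_cytosine(
    alignments: Iterable[BsAlignment],
    contexts: Optional[Set[str]] = None,
    include_duplicates: bool = False,
    genome: Optional[ReferenceGenome] = None,
) -> PerCytosineMethylation:
    """Aggregate call strings into per-cytosine counts.

    Every non-'.' call increments total_count at its reference position on
    the read's parent strand; uppercase additionally increments meth_count.
    Context is taken from the call character class.  When reads disagree on
    a position's context the majority wins and a conflict is counted.
    """
    if contexts is None:
        contexts = set(CONTEXTS)
    counts: Dict[Key, List[int]] = {}
    ctx_votes: Dict[Key, Counter] = {}
    for aln in alignments:
        if aln.is_duplicate and not include_duplicates:
            continue
        strand = aln.parent_strand
        chrom = aln.interval.chrom
        start = aln.interval.start
        for i, ch in enumerate(aln.call_string):
            if ch == ".":
                continue
            context = _CALL_CONTEXT[ch]
            if context not in contexts:
                continue
            key = (chrom, start + i, strand)
            entry = counts.setdefault(key, [0, 0])
            entry[1] += 1
            if ch.isupper():
                entry[0] += 1
            ctx_votes.setdefault(key, Counter())[context] += 1
    table = PerCytosineMethylation(
        chrom_sizes=genome.lengths if genome is not None else None
    )
    for key, (meth, total) in counts.items():
        votes = ctx_votes[key]
        context = votes.most_common(1)[0][0]
        if len(votes) > 1:
            table.context_conflicts += 1
        table.records[key] = CytosineRecord(context, meth, total)
    return table


@dataclass(frozen=True)
class RegionMethylation:
    interval: GenomicInterval
    strategy: str
    value: Optional[float]  # percent, None when inclusion rules unmet
    n_cytosines_used: int
    n_calls_used: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def region_methylation(
    per_cytosine: PerCytosineMethylation,
    regions: Sequence[GenomicInterval],
    strategy: str = "cytosine_mean",
    min_region_obs: int = 3,
    min_cytosine_cov: int = 0,
    contexts: Optional[Set[str]] = None,
) -> List[RegionMethylation]:
    """Quantify methylation per region with one of the two strategies.

    A region is reported only when its total call count reaches
    ``min_region_obs``; cytosines below ``min_cytosine_cov`` coverage are
    dropped from both strategies (note the toolkit's own diagnostics show
    that raising this floor reinforces coverage bias).
    """
    if strategy not in ("pooled", "cytosine_mean"):
        raise ValueError(f"unknown strategy {strategy!r}")
    by_chrom: Dict[str, List[Tuple[int, Key]]] = {}
    for key in per_cytosine.records:
        by_chrom.setdefault(key[0], []).append((key[1], key))
    for lst in by_chrom.values():
        lst.sort()
    import bisect

    out: List[RegionMethylation] = []
    for region in regions:
        positions = by_chrom.get(region.chrom, [])
        lo = bisect.bisect_left(positions, (region.start, ("", -1, "")))
        recs = []
        for pos, key in positions[lo:]:
            if pos >= region.end:
                break
            rec = per_cytosine.records[key]
            if contexts is not None and rec.context not in contexts:
                continue
            if rec.total_count < min_cytosine_cov:
                continue
            if rec.percent is None:
                continue
            recs.append(rec)
        n_calls = sum(r.total_count for r in recs)
        if not recs or n_calls < min_region_obs:
            out.append(RegionMethylation(region, strategy, None, len(recs), n_calls))
            continue
        if strategy == "pooled":
            num = sum(
                r.total_count * r.percent for r in recs
            )  # = 100*meth when no overrides
            value = num / n_calls
        else:
            value = sum(r.percent for r in recs) / len(recs)
        out.append(
            RegionMethylation(region, strategy, value, len(recs), n_calls)
        )
    return out


def global_methylation(
    per_cytosine: PerCytosineMethylation,
    contexts: Set[str] = frozenset({"CG"}),
) -> float:
    """Coverage-weighted global percent methylation over a context set.

    Equals 100 * sum(meth) / sum(total) for uncorrected tables; for tables
    carrying percent overrides it is the coverage-weighted mean of percents.
    """
    num = 0.0
    denom = 0
    for rec in per_cytosine.records.values():
        if rec.context not in contexts:
            continue
        pct = rec.percent
        if pct is None:
            continue
        num += rec.total_count * pct
        denom += rec.total_count
    if denom == 0:
        raise ValueError(f"no covered cytosines in contexts {sorted(contexts)}")
    return num / denom


def _context_positions_from_genome(
    genome: ReferenceGenome, context: str
) -> Dict[str, List[int]]:
    """Top-strand positions of cytosines in the given context."""
    out: Dict[str, List[int]] = {}
    for name, seq in genome.items():
        positions = []
        n = len(seq)
        for i in range(n):
            if seq[i] != "C":
                continue
            nxt = seq[i + 1] if i + 1 < n else ""
            nxt2 = seq[i + 2] if i + 2 < n else ""
            if context == "CG":
                if nxt == "G":
                    positions.append(i)
            elif context == "CHG":
                if nxt in "ACT" and nxt2 == "G":
                    positions.append(i)
            elif context == "CHH":
                if nxt in "ACT" and nxt2 in "ACT":
                    positions.append(i)
        out[name] = positions
    return out


def cytosine_tiles(
    source, n: int, context: str = "CG"
) -> List[GenomicInterval]:
    """Non-overlapping windows each containing exactly ``n`` context positions.

    ``source`` is either a :class:`ReferenceGenome` (positions are top-strand
    cytosines of the context) or a :class:`PerCytosineMethylation` (positions
    are covered cytosines of the context, strands collapsed).  The trailing
    remainder of fewer than ``n`` positions is discarded.  Window bounds run
    from the first to one past the last contained position.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(source, ReferenceGenome):
        by_chrom = _context_positions_from_genome(source, context)
    else:
        tmp: Dict[str, Set[int]] = {}
        for (chrom, pos, _), rec in source.records.items():
            if rec.context == context:
                tmp.setdefault(chrom, set()).add(pos)
        by_chrom = {c: sorted(ps) for c, ps in tmp.items()}
    tiles: List[GenomicInterval] = []
    for chrom, positions in by_chrom.items():
        for i in range(0, len(positions) - n + 1, n):
            group = positions[i : i + n]
            tiles.append(GenomicInterval(chrom, group[0], group[-1] + 1))
    return tiles


@dataclass
class DifferentialRegions:
    """Tiles whose methylation differs by more than a cutoff, by direction."""

    higher_in_a: List[GenomicInterval]
    higher_in_b: List[GenomicInterval]
    n_undefined: int
    min_diff_pp: float

    @property
    def selected(self) -> List[GenomicInterval]:
        return self.higher_in_a + self.higher_in_b


def differential_regions(
    values_a: Sequence[RegionMethylation],
    values_b: Sequence[RegionMethylation],
    min_diff_pp: float = 20.0,
) -> DifferentialRegions:
    """Select tiles with |a - b| strictly greater than ``min_diff_pp``.

    Both inputs must cover the same tile frame; tiles undefined in either
    input are excluded and counted.
    """
    if len(values_a) != len(values_b):
        raise ValueError("mismatched tile sets (different lengths)")
    higher_a: List[GenomicInterval] = []
    higher_b: List[GenomicInterval] = []
    undefined = 0
    for ra, rb in zip(values_a, values_b):
        if ra.interval != rb.interval:
            raise ValueError(
                f"mismatched tile sets at {ra.interval} vs {rb.interval}"
            )
        if ra.value is None or rb.value is None:
            undefined += 1
            continue
        diff = ra.value - rb.value
        if diff > min_diff_pp:
            higher_a.append(ra.interval)
        elif -diff > min_diff_pp:
            higher_b.append(ra.interval)
    return DifferentialRegions(higher_a, higher_b, undefined, min_diff_pp)


def overlap_count(
    set_a: Iterable[GenomicInterval], set_b: Iterable[GenomicInterval]
) -> Tuple[int, int, int]:
    """(a_only, shared, b_only) by tile identity over a common frame."""
    a, b = set(set_a), set(set_b)
    return (len(a - b), len(a & b), len(b - a))


@dataclass
class PositionProfile:
    """Per-position, per-strand percent methylation on one reference.

    Top strand carries positive sign, bottom strand negative, for the usual
    mirror-plot rendering.
    """

    reference: str
    values: Dict[Tuple[int, str], Optional[float]]  # (pos, strand) -> percent

    def signed(self, pos: int, strand: str) -> Optional[float]:
        v = self.values.get((pos, strand))
        if v is None:
            return None
        return v if strand == "+" else -v

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "position": pos,
                "strand": strand,
                "percent": v,
                "signed_percent": (None if v is None else (v if strand == "+" else -v)),
            }
            for (pos, strand), v in sorted(self.values.items())
        ]
        return pd.DataFrame(
            rows, columns=["position", "strand", "percent", "signed_percent"]
        )


def per_position_profile(
    alignments: Iterable[BsAlignment],
    contexts: Set[str] = CH_CONTEXTS,
    include_duplicates: bool = True,
    table: Optional[PerCytosineMethylation] = None,
) -> PositionProfile:
    """Strand-resolved per-position methylation profile on a single reference.

    Intended for consensus references (satellite monomers, spike-ins) where
    read stacks are deep; duplicates are therefore included by default.  A
    pre-built (possibly background-corrected) per-cytosine table may be
    passed instead of alignments.
    """
    if table is None:
        table = extract_per_cytosine(
            alignments, contexts=set(contexts), include_duplicates=include_duplicates
        )
    chroms = {chrom for chrom, _, _ in table.records}
    if len(chroms) > 1:
        raise ValueError(f"profile expects a single reference, got {sorted(chroms)}")
    reference = chroms.pop() if chroms else ""
    values: Dict[Tuple[int, str], Optional[float]] = {}
    for (chrom, pos, strand), rec in table.records.items():
        if rec.context not in contexts:
            continue
        values[(pos, strand)] = rec.percent
    return PositionProfile(reference, values)
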