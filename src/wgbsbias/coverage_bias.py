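"""Coverage-level bias diagnostics.

Bisulfite-induced degradation depletes C-rich unmethylated sequence, which
shows up as (i) skewed strand representation at loci with strand GC skew
(satellites, mtDNA, telomeres), (ii) loss of high-tandem-count C-strand
telomere reads, (iii) a falling read-count trend against tile %C, and
(iv) distorted relative coverage over features such as CpG islands.  These
diagnostics quantify each signature; none of them *corrects* coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .refio import BsAlignment, GenomicInterval, RawRead, ReferenceGenome, revcomp


@dataclass
class StrandCoverage:
    """Read counts assigned to the original top vs bottom strand."""

    reference_name: str
    top_count: int
    bottom_count: int

    @property
    def total(self) -> int:
        return self.top_count + self.bottom_count

    @property
    def top_proportion(self) -> Optional[float]:
        return self.top_count / self.total if self.total else None

    @property
    def bottom_proportion(self) -> Optional[float]:
        return self.bottom_count / self.total if self.total else None


def strand_read_counts(
    alignments: Iterable[BsAlignment],
    reference_name: str,
    include_duplicates: bool = True,
) -> StrandCoverage:
    """Count reads per original strand on one reference.

    OT/CTOT reads derive from the original top strand, OB/CTOB from the
    bottom.  Duplicates are included by default because the high-copy
    repeat references this is aimed at are analysed without deduplication.
    """
    top = bottom = 0
    for aln in alignments:
        if aln.interval.chrom != reference_name:
            continue
        if aln.is_duplicate and not include_duplicates:
            continue
        if aln.parent_strand == "+":
            top += 1
        else:
            bottom += 1
    return StrandCoverage(reference_name, top, bottom)


@dataclass
class TandemHistogram:
    """Distribution of tandem-motif units per read."""

    motif: str
    counts: Dict[int, int]
    min_units_applied: int = 0

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    def to_rows(self) -> List[Tuple[int, int]]:
        return sorted(self.counts.items())


def tandem_unit_histogram(
    reads: Iterable[RawRead], motif: str, orientation: str = "as_given"
) -> TandemHistogram:
    """Histogram of non-overlapping motif occurrences per raw read.

    Raw (unmapped) reads are used because tandem repeats like the telomeric
    hexamer are not mappable.  ``orientation="reversed"`` reverse-complements
    the motif, for post-bisulfite libraries that read the complementary
    strand (e.g. TTAGGG -> CCCTAA).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if orientation == "reversed":
        motif = revcomp(motif.upper())
    elif orientation != "as_given":
        raise ValueError(f"unknown orientation {orientation!r}")
    else:
        motif = motif.upper()
    counts: Dict[int, int] = {}
    for read in reads:
        # str.count is exactly left-to-right non-overlapping counting
        n = read.sequence.upper().count(motif)
        counts[n] = counts.get(n, 0) + 1
    return TandemHistogram(motif, counts)


def filter_min_units(
    hist: TandemHistogram, min_units: int = 5
) -> TandemHistogram:
    """Drop histogram bins below ``min_units`` (non-tandem-origin reads)."""
    if min_units < 0:
        raise ValueError("min_units must be >= 0")
    return TandemHistogram(
        motif=hist.motif,
        counts={u: c for u, c in hist.counts.items() if u >= min_units},
        min_units_applied=max(min_units, hist.min_units_applied),
    )


def high_coverage_mask(
    alignments: Iterable[BsAlignment],
    genome: ReferenceGenome,
    window: int = 1000,
    max_reads: int = 1000,
    include_duplicates: bool = False,
) -> List[GenomicInterval]:
    """Windows with read count strictly above ``max_reads`` (likely artefacts).

    Reads are assigned to the window containing their start; downstream
    diagnostics accept the mask and drop reads starting in masked windows.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    counts: Dict[Tuple[str, int], int] = {}
    for aln in alignments:
        if aln.is_duplicate and not include_duplicates:
            continue
        key = (aln.interval.chrom, aln.interval.start // window)
        counts[key] = counts.get(key, 0) + 1
    mask: List[GenomicInterval] = []
    for (chrom, w), n in sorted(counts.items()):
        if n > max_reads:
            end = min((w + 1) * window, len(genome[chrom]))
            mask.append(GenomicInterval(chrom, w * window, end))
    return mask


def _apply_mask(
    alignments: Iterable[BsAlignment],
    mask: Optional[Sequence[GenomicInterval]],
    window: int,
) -> Iterable[BsAlignment]:
    if not mask:
        yield from alignments
        return
    masked = {(iv.chrom, iv.start // window) for iv in mask}
    for aln in alignments:
        if (aln.interval.chrom, aln.interval.start // window) not in masked:
            yield aln


@dataclass
class GcCoverageProfile:
    """Mean normalised read count per G- or C-content bin of genome tiles."""

    axis: str
    bin_edges: np.ndarray  # length bins+1, percent scale
    mean_norm_count: np.ndarray  # NaN where a bin holds no tiles
    tile_count: np.ndarray
    total_reads: int
    #: unbinned per-tile values, for statistics that need full resolution
    per_tile_percent: np.ndarray = None
    per_tile_norm_count: np.ndarray = None

    @property
    def n_bins(self) -> int:
        return len(self.tile_count)

    def populated_bins(self) -> np.ndarray:
        return np.nonzero(self.tile_count > 0)[0]


def tile_gc_coverage(
    alignments: Iterable[BsAlignment],
    genome: ReferenceGenome,
    tile: int = 100,
    bins: int = 100,
    axis: str = "G",
    mask: Optional[Sequence[GenomicInterval]] = None,
    mask_window: int = 1000,
    include_duplicates: bool = False,
) -> GcCoverageProfile:
    """Read-coverage dependence on tile G or C content.

    The genome is cut into non-overlapping tiles; each tile's percent of
    the axis base comes from the *genomic* sequence (the read sequence is
    useless here, conversion rewrote its unmethylated Cs).  Each read is
    assigned to the tile containing its footprint midpoint; tile counts are
    normalised by the dataset total and averaged within ``bins`` equal-width
    content bins.  Empty bins are NaN, never zero.  Tiles containing N are
    excluded.
    """
    if tile < 1:
        raise ValueError("tile must be >= 1")
    if axis not in ("G", "C"):
        raise ValueError("axis must be G or C")
    tile_pct: Dict[Tuple[str, int], float] = {}
    for name, seq in genome.items():
        n_tiles = max(1, len(seq) // tile)
        for t in range(n_tiles):
            chunk = seq[t * tile : (t + 1) * tile] if len(seq) >= tile else seq
            if "N" in chunk or not chunk:
                continue
            tile_pct[(name, t)] = 100.0 * chunk.count(axis) / len(chunk)
    tile_reads: Dict[Tuple[str, int], int] = {k: 0 for k in tile_pct}
    total_reads = 0
    for aln in _apply_mask(alignments, mask, mask_window):
        if aln.is_duplicate and not include_duplicates:
            continue
        total_reads += 1
        mid = (aln.interval.start + aln.interval.end) // 2
        key = (aln.interval.chrom, mid // tile)
        if key in tile_reads:
            tile_reads[key] += 1
    edges = np.linspace(0.0, 100.0, bins + 1)
    sums = np.zeros(bins)
    tile_count = np.zeros(bins, dtype=int)
    per_tile_percent = np.empty(len(tile_pct))
    per_tile_norm = np.empty(len(tile_pct))
    for i, (key, pct) in enumerate(sorted(tile_pct.items())):
        b = min(int(pct / 100.0 * bins), bins - 1)
        norm = tile_reads[key] / total_reads if total_reads else 0.0
        sums[b] += norm
        tile_count[b] += 1
        per_tile_percent[i] = pct
        per_tile_norm[i] = norm
    with np.errstate(invalid="ignore"):
        mean = np.where(tile_count > 0, sums / np.maximum(tile_count, 1), np.nan)
    return GcCoverageProfile(
        axis, edges, mean, tile_count, total_reads,
        per_tile_percent=per_tile_percent, per_tile_norm_count=per_tile_norm,
    )


@dataclass
class RelativeCoverageTrend:
    """Relative coverage over scaled feature bodies with fixed flanks.

    Values are fold differences from the genome-wide mean per-base coverage,
    so 1 is the no-bias line.  Bin order: upstream flank, body (5'->3' in
    feature orientation), downstream flank.
    """

    label: str
    flank_values: Tuple[np.ndarray, np.ndarray]  # upstream, downstream
    body_values: np.ndarray
    n_features_used: int
    n_features_skipped: int

    @property
    def profile(self) -> np.ndarray:
        return np.concatenate(
            [self.flank_values[0], self.body_values, self.flank_values[1]]
        )


def feature_relative_coverage(
    alignments: Iterable[BsAlignment],
    genome: ReferenceGenome,
    features: Sequence[GenomicInterval],
    flank: int = 1000,
    body_bins: int = 20,
    flank_bins: int = 10,
    label: str = "features",
    include_duplicates: bool = False,
) -> RelativeCoverageTrend:
    """Average relative coverage trend over a feature set.

    Each feature body is scaled to ``body_bins`` bins; fixed-width flanks of
    ``flank`` bases are split into ``flank_bins`` bins each.  Read midpoints
    are counted per bin, converted to per-base density, averaged across
    features, and divided by the dataset's genome-wide mean per-base read
    density.  Minus-strand features are flipped.  Features shorter than
    ``body_bins`` bases are skipped and counted.
    """
    if not features:
        raise ValueError("feature set is empty")
    # one pass: bucket read midpoints per chromosome
    mids: Dict[str, List[int]] = {name: [] for name in genome}
    total_reads = 0
    for aln in alignments:
        if aln.is_duplicate and not include_duplicates:
            continue
        total_reads += 1
        mids[aln.interval.chrom].append(
            (aln.interval.start + aln.interval.end) // 2
        )
    for v in mids.values():
        v.sort()
    genome_density = total_reads / genome.total_length if total_reads else 0.0
    if genome_density == 0:
        raise ValueError("no reads")

    up = np.zeros(flank_bins)
    body = np.zeros(body_bins)
    down = np.zeros(flank_bins)
    used = skipped = 0
    flank_w = flank / flank_bins
    for feat in features:
        if len(feat) < body_bins:
            skipped += 1
            continue
        used += 1
        chrom_mids = np.asarray(mids.get(feat.chrom, []), dtype=float)
        body_w = len(feat) / body_bins
        # densities in reference orientation, flipped later if '-'
        u = np.zeros(flank_bins)
        b = np.zeros(body_bins)
        d = np.zeros(flank_bins)
        if chrom_mids.size:
            lo, hi = feat.start - flank, feat.end + flank
            sel = chrom_mids[(chrom_mids >= lo) & (chrom_mids < hi)]
            for m in sel:
                if m < feat.start:
                    u[int((m - lo) / flank_w)] += 1
                elif m < feat.end:
                    b[min(int((m - feat.start) / body_w), body_bins - 1)] += 1
                else:
                    d[min(int((m - feat.end) / flank_w), flank_bins - 1)] += 1
        u /= flank_w
        b /= body_w
        d /= flank_w
        if feat.strand == "-":
            u, d = d[::-1], u[::-1]
            b = b[::-1]
        up += u
        body += b
        down += d
    if used == 0:
        raise ValueError("all features skipped (shorter than body_bins)")
    up /= used * genome_density
    body /= used * genome_density
    down /= used * genome_density
    return RelativeCoverageTrend(label, (up, down), body, used, skipped)
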