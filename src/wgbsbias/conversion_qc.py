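"""Conversion-artefact controls.

Unmethylated cytosines that escape bisulfite conversion are read as
methylated; the artefact lands almost entirely in CH (non-CpG) context,
because CH sites outnumber CG sites >20-fold in mammalian genomes.  This
module implements the three coping strategies plus spike-in efficiency
estimation and leading-base trimming for post-bisulfite libraries:

1. ``threshold_filter`` — zero per-cytosine CH calls below a percent cutoff
   (the common but least effective practice);
2. ``filter_nonconversion_reads`` — the 3xC filter: drop any read carrying
   three or more consecutive unconverted CH calls, the signature of a
   poorly converted molecule;
3. ``background_subtract`` — subtract the per-cytosine signal of an
   unmethylated control library of the same genome, the only strategy that
   also removes conversion-resistant motifs (e.g. CCWGG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from .refio import BsAlignment
from .methylation_quant import CytosineRecord, PerCytosineMethylation

#: call-string characters that report a CH (non-CpG) cytosine
_CH_CHARS = "xXhH"
_UNKNOWN_CHARS = "uU"


@dataclass
class FilterOutcome:
    kept: List[BsAlignment] = field(default_factory=list)
    removed: List[BsAlignment] = field(default_factory=list)

    @property
    def seen(self) -> int:
        return len(self.kept) + len(self.removed)


def _is_nonconverted(
    call_string: str, min_run: int, mode: str, count_unknown: bool
) -> bool:
    relevant = _CH_CHARS + (_UNKNOWN_CHARS if count_unknown else "")
    if mode == "consecutive":
        run = 0
        for ch in call_string:
            if ch not in relevant:
                continue  # '.', CpG and filtered classes do not break a run
            if ch.isupper():
                run += 1
                if run >= min_run:
                    return True
            else:
                run = 0
        return False
    if mode == "total":
        total = sum(1 for ch in call_string if ch in relevant and ch.isupper())
        return total >= min_run
    raise ValueError(f"unknown mode {mode!r}")


def filter_nonconversion_reads(
    alignments: Iterable[BsAlignment],
    min_run: int = 3,
    mode: str = "consecutive",
    count_unknown: bool = True,
) -> FilterOutcome:
    """Partition reads by the non-conversion (3xC) criterion.

    ``consecutive`` removes a read iff ``min_run`` successive CH cytosine
    positions are all unconverted — successiveness is over CH sites only:
    non-cytosine and CpG positions are skipped when scanning, a *converted*
    CH call breaks the run.  ``total`` removes on the total unconverted CH
    count instead.  CpG calls never trigger removal.  Unknown-context calls
    count as CH unless ``count_unknown`` is off.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    outcome = FilterOutcome()
    for aln in alignments:
        if _is_nonconverted(aln.call_string, min_run, mode, count_unknown):
            outcome.removed.append(aln)
        else:
            outcome.kept.append(aln)
    return outcome


@dataclass
class TrimOutcome:
    alignments: List[BsAlignment]
    fully_masked: int = 0


def trim_call_string(
    alignments: Iterable[BsAlignment], n_start: int = 4
) -> TrimOutcome:
    """Mask the first ``n_start`` calls of each read (post-bisulfite M-bias).

    Masking is applied in *read* orientation: for reverse-mapped reads the
    read's first bases sit at the right edge of the reference-oriented call
    string.  The footprint is unchanged; masked positions become '.'.
    """
    if n_start < 0:
        raise ValueError("n_start must be >= 0")
    out = TrimOutcome(alignments=[])
    for aln in alignments:
        cs = aln.call_string
        if n_start == 0:
            out.alignments.append(aln)
            continue
        k = min(n_start, len(cs))
        if k == len(cs):
            out.fully_masked += 1
        if aln.read_is_reverse:
            trimmed = cs[: len(cs) - k] + "." * k
        else:
            trimmed = "." * k + cs[k:]
        out.alignments.append(aln.with_call_string(trimmed))
    return out


def threshold_filter(
    per_cytosine: PerCytosineMethylation, cutoff_percent: float
) -> PerCytosineMethylation:
    """Zero methylation at positions below a percent cutoff.

    Positions with percent < cutoff have their calls zeroed (coverage is
    retained); positions at or above the cutoff are untouched.  Idempotent.
    """
    if not (0 <= cutoff_percent <= 100):
        raise ValueError("cutoff_percent must be in [0, 100]")
    result = per_cytosine.copy()
    for rec in result.records.values():
        pct = rec.percent
        if pct is not None and pct < cutoff_percent:
            rec.meth_count = 0
            if rec.percent_override is not None:
                rec.percent_override = 0.0
    return result


@dataclass
class BackgroundSubtractOutcome:
    table: PerCytosineMethylation
    missing_in_control: int = 0


def background_subtract(
    sample: PerCytosineMethylation,
    control: PerCytosineMethylation,
    clip_at_zero: bool = True,
    min_control_cov: int = 0,
) -> BackgroundSubtractOutcome:
    """Subtract an unmethylated-control library's signal per cytosine.

    corrected% = sample% - control%, clipped at zero by default.  Positions
    absent from the control (or below ``min_control_cov`` there) pass
    through uncorrected and are counted.  Requires both tables to share a
    coordinate frame when chromosome sizes are recorded.
    """
    if (
        sample.chrom_sizes is not None
        and control.chrom_sizes is not None
        and sample.chrom_sizes != control.chrom_sizes
    ):
        raise ValueError("coordinate-frame mismatch between sample and control")
    out = BackgroundSubtractOutcome(table=sample.copy())
    for key, rec in out.table.records.items():
        pct = rec.percent
        if pct is None:
            continue
        ctrl = control.records.get(key)
        if ctrl is None or ctrl.total_count < min_control_cov or ctrl.percent is None:
            out.missing_in_control += 1
            continue
        corrected = pct - ctrl.percent
        if clip_at_zero and corrected < 0:
            corrected = 0.0
        rec.percent_override = corrected
    return out


@dataclass
class ConversionEstimate:
    """Conversion efficiency from a fully unmethylated spike-in reference."""

    converted_calls: int
    unconverted_calls: int
    by_context: Dict[str, Dict[str, int]]
    undefined: bool = False

    @property
    def efficiency(self) -> Optional[float]:
        total = self.converted_calls + self.unconverted_calls
        if total == 0:
            return None
        return self.converted_calls / total

    def context_efficiency(self, context: str) -> Optional[float]:
        d = self.by_context.get(context, {"converted": 0, "unconverted": 0})
        total = d["converted"] + d["unconverted"]
        return d["converted"] / total if total else None


_CONTEXT_OF = {
    "z": "CG", "Z": "CG",
    "x": "CHG", "X": "CHG",
    "h": "CHH", "H": "CHH",
    "u": "unknown", "U": "unknown",
}


def spike_in_conversion(
    alignments: Iterable[BsAlignment],
    spike_chroms: Optional[Iterable[str]] = None,
    include_duplicates: bool = True,
) -> ConversionEstimate:
    """Global conversion efficiency from reads on an unmethylated spike.

    Every cytosine call on the spike reference is, by assumption, an
    unmethylated cytosine: lowercase = converted, uppercase = a conversion
    failure.  Efficiency = converted / (converted + unconverted), with a
    per-context breakdown.
    """
    spike = set(spike_chroms) if spike_chroms is not None else None
    by_context = {
        c: {"converted": 0, "unconverted": 0}
        for c in ("CG", "CHG", "CHH", "unknown")
    }
    conv = unconv = 0
    for aln in alignments:
        if aln.is_duplicate and not include_duplicates:
            continue
        if spike is not None and aln.interval.chrom not in spike:
            continue
        for ch in aln.call_string:
            if ch == ".":
                continue
            ctx = _CONTEXT_OF[ch]
            if ch.isupper():
                unconv += 1
                by_context[ctx]["unconverted"] += 1
            else:
                conv += 1
                by_context[ctx]["converted"] += 1
    return ConversionEstimate(
        converted_calls=conv,
        unconverted_calls=unconv,
        by_context=by_context,
        undefined=(conv + unconv == 0),
    )
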