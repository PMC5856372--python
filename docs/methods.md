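# Methods

## The problem

Bisulfite treatment converts unmethylated cytosine to uracil (read as
thymine after PCR) while 5-methylcytosine and 5-hydroxymethylcytosine
resist conversion. Three side effects of library preparation distort the
resulting data:

1. **Degradation.** Bisulfite chemistry causes random base loss at
   unmethylated cytidines, breaking the backbone under heat and alkali.
   A molecule's survival therefore falls with its count of unmethylated
   cytosines: unmethylated C-rich sequence is depleted from the library,
   and because the *methylated* copies of a locus survive preferentially,
   global and local methylation levels are overestimated.
2. **Incomplete conversion.** A fraction of unmethylated cytosines escape
   conversion and read as methylated. The artefact lands almost entirely
   in non-CpG (CH) context, which outnumbers CpG more than twentyfold in
   mammalian genomes.
3. **PCR amplification.** Per-cycle copying efficiency depends on template
   composition (the converted genome is ~80% A+T), so amplification skews
   coverage along G content and multiplies whatever molecules degradation
   and conversion left behind.

`wgbsbias` provides the diagnostics that expose each mechanism in aligned
reads, the corrections for conversion artefacts, quantification strategies
robust to coverage bias, and a generative simulator that produces reads
with full ground truth so every diagnostic is validated by parameter
recovery rather than by eyeballing real data.

## Data model

Coordinates are 0-based half-open everywhere; BED is read natively and any
1-based output converts at serialisation. Aligned reads carry a
per-reference-position call string in the Bismark dialect (z/Z CpG, x/X
CHG, h/H CHH, u/U unknown, '.' non-cytosine; uppercase = unconverted).
`bs_strand` takes OT/OB (original top/bottom strand) or CTOT/CTOB (their
PCR complements); calls always report on the original strand (OT/CTOT →
top). Version 1 accepts only ungapped alignments — a gapped or clipped
record would desynchronise the call string from the reference footprint —
and skips them with a counter rather than guessing. Reads flagged
duplicate are skipped by default in genome-wide operations and included by
default in repeat/consensus operations (tandem counts, strand skew,
position profiles), where deduplication is meaningless; every operation
takes an `include_duplicates` switch. CH means CHG ∪ CHH throughout, and
unknown-context calls count as CH for read filtering (conservative
artefact removal, switchable).

## The simulator

Library preparation is factored into independent stages, each drawing from
its own named random substream of the root seed, so toggling one mechanism
never perturbs another's draws:

1. **Fragmentation** — uniform starts, truncated-normal lengths
   (default 150 ± 30 bp, minimum 30), strand chosen equiprobably;
   fragment count = genome_length × depth / mean_length.
2. **Methylome assignment** — per-molecule cytosine states drawn from
   context-level probabilities (`p_mCG`, `p_mCH`, `p_hmCG`), overridable
   per site, per region, or per chromosome (used for unmethylated
   spike-ins). Drawing per molecule reproduces the cell-to-cell
   heterogeneity that intermediate methylation levels describe.
3. **Bisulfite conversion** — whole-molecule survival
   `base_survival · (1−β_unmod)^k_u · (1−β_mod)^k_m` over the molecule's
   unmodified/modified cytosine counts (`β_mod ≤ β_unmod` encodes
   modification protection); then per-cytosine conversion. Breakage is
   modelled as survive-or-die rather than explicit breakpoint resampling:
   every diagnostic here consumes read counts and call strings, for which
   molecule loss is sufficient, and the closed form
   `β = 1 − R^(−1/(Δc·L))` lets a target recovery ratio R between pools
   differing by cytosine fraction Δc be dialled in exactly.
4. **Conversion failure** is a two-level mixture: a small fraction of
   molecules (`poor_conversion_fraction`) is poorly converted wholesale
   (every unmodified C fails with `poor_conversion_epsilon`, default 0.8),
   while the rest fail per call at the per-context rates
   (`epsilon_CG`, `epsilon_CH`), multiplied inside conversion-resistant
   motifs (IUPAC patterns such as CCWGG). The molecule-level component is
   essential, not decorative: with purely independent per-call failures at
   rate ε, three consecutive failures occur at rate ε³ and a read-level
   non-conversion filter could never work — whereas the filter's entire
   premise is that unconverted calls concentrate in poorly converted
   molecules. 5mC over-converts (reads as T) with probability `gamma`;
   5hmC never converts.
5. **PCR** — per cycle, each molecule is copied with efficiency
   `clamp(e0 + slope·(g_frac − g_ref), 0, 1)` where `g_frac` is the G
   fraction of the converted single strand (conversion rewrites a
   molecule's Cs, never its Gs); copying is binomial per cycle by default.
   `cycles = 0` is exactly the amplification-free case.
6. **Emission** — single-end reads from the molecule 5' end (pre-BS:
   OT/OB, the molecule itself; post-BS: CTOT/CTOB, the complementary
   strand synthesised on it, sequence reverse-complemented). When a target
   read count is set (default: the pre-PCR fragment count, so depth is
   preserved under amplification) the amplified pool is subsampled
   binomially — a sequencer samples a fixed number of molecules, it does
   not report every PCR copy. Copies of a fragment beyond the first are
   flagged duplicate.

The ground-truth bundle records every fragment's interval, strand,
per-cytosine states, survival, poor-conversion flag, copy and emission
counts, from which true global and per-position methylation are computed.

### Protocol presets

Published results report fold relationships between conversion protocols,
not absolute rates, so the presets are calibrated operating points, not
measured constants: `heat_like` sets β for a 2.0× recovery gap between
15%-C and 30%-C fragments of 150 bp (β ≈ 0.030) and a mean CH failure of
~0.3%; `alkaline_like` sets β for a 1.3× gap (β ≈ 0.012) and 4× the CH
failure (~1.2%); `ambs_like` uses a composition-neutral `base_survival`
of 0.35 (low but unbiased recovery); `kapa_like` pairs heat conversion
with a negative PCR slope (AT-tolerant polymerase); `pbat_like` is
heat conversion with `cycles = 0`, post-BS orientation; `null` switches
every mechanism off.

### Synthetic references

`random_genome` draws i.i.d. bases at a target GC and thins CpG
dinucleotides (G→A rewrite). Both the GC loss from the rewrite and the
shrinkage of the observed/expected denominator are undone by a fixed-point
calibration, so the realised composition hits the request: at GC 0.42 and
CpG obs/exp 0.2 — standard mammalian values — a 500-kb genome realises
GC 0.420, obs/exp 0.205, and a CH:CG cytosine ratio of ~23.
`skewed_reference` mimics the satellite/mtDNA strand asymmetry (top strand
13% C / 23.5% G by default); `tandem_reference` builds (motif)_n repeats;
`fragment_with_c_content` places an exact count of cytosines for
degradation-recovery experiments (synthetic stand-ins for the published
fixed-composition assay fragments, whose sequences are not redistributed
here).

What the generator does **not** emulate: mappability and alignment error,
sequencer base-call errors and quality scores, real CpG-island structure,
chimeric post-BS reads, strand reannealing, and any correlation between a
molecule's degradation and its conversion fate. Passing tests therefore
demonstrate that each diagnostic recovers the parameter it targets under
its own generative mechanism — not that real libraries contain no other
artefacts.

## Diagnostics and corrections: definitions and choices

**Composition report.** Read-footprint composition is always taken from
the reference sequence under the footprint (conversion rewrites the read
itself). A read of length L contributes L mono and L−1 overlapping
dinucleotide counts, coverage-weighted; windows containing N are excluded
from both observed and expected tallies (symmetric by construction);
log2(observed/expected fraction) is reported per 4+16 k-mers, flagged
(never fabricated) when a fraction is zero.

**Non-conversion (3xC) filter.** A read is removed when `min_run`
(default 3) successive CH cytosine positions are all unconverted.
"Successive" is over CH sites: non-cytosine and CpG positions do not break
a run, a converted CH call does. A `total` mode counts unconverted CH
calls regardless of adjacency. CpG calls never trigger removal.

**Threshold filter.** Per-cytosine percents below the cutoff are zeroed
(coverage retained), making the operation idempotent; positions at or
above the cutoff are untouched.

**Background subtraction.** corrected% = sample% − control% per position,
clipped at zero by default for per-position display. For *aggregate*
residuals the unclipped difference is the right estimator: clipping a
zero-centred signal biases its mean upward by E[max(X−Y,0)] > 0 at any
finite coverage. Positions absent from the control pass through and are
counted; no minimum control coverage is required by default (configurable).

**Coverage diagnostics.** Reads are assigned to 100-bp tiles by footprint
midpoint (avoids double counting at tile edges); tiles are binned by G or
C percent into 100 equal-width bins, with empty bins reported missing,
never zero; unbinned per-tile values are kept on the profile for
statistics that need full resolution. High-coverage masking drops
non-overlapping 1-kb windows with strictly more than 1000 read starts.
Tandem units are counted non-overlapping, left to right;
`orientation="reversed"` reverse-complements the motif, which is what a
post-bisulfite library requires (its reads are complementary to the
original strand — TTAGGG becomes CCCTAA, not GGGATT). Feature trends
scale each feature body to a fixed bin count, add fixed-width flank bins,
flip minus-strand features, and divide by the genome-wide mean per-base
read density so 1 is the no-bias line (a declared approximation of
relative-trend normalisation).

**Quantification.** `pooled` region methylation is 100·Σmeth/Σtotal —
implicitly coverage-weighted; `cytosine_mean` averages per-cytosine
percents unweighted. They agree exactly at equal coverage and diverge
under any coverage–methylation correlation, which degradation creates.
Regions require ≥3 total calls by default ("minimum of three
observations" is read as per region, not per cytosine; both knobs are
exposed). Differential tiles use strict inequality (>20 pp). Overlap
counting is by tile identity, since both value sets are built on one tile
frame. Undefined percents propagate as missing, never 0. Fixed-count
tiles partition each chromosome greedily into consecutive groups of n
context positions, discarding the remainder.

## Validation design and problem sizes

All validation is parameter recovery against simulator truth, at sizes
chosen so the asserted effect clears its own sampling noise:

- **Global null** (every mechanism off, 10-kb genome, 50×): composition
  log2 ratios within ±0.1, strand split 50 ± 3%, global mCG within a
  3-SE binomial band of truth. GC-coverage flatness is judged per tile on
  a 100-kb genome: with T tiles the null rank correlation has
  σ ≈ 1/√(T−1), so 100 tiles (σ ≈ 0.1) cannot support a ±0.1 band while
  1000 tiles (σ ≈ 0.03) make it a 3σ statement.
- **Degradation**: the closed-form calibration reproduces a 2.0 ± 0.1
  recovery ratio at 10,000 fragments per pool; C-containing dinucleotide
  depletion is asserted on an unmethylated, CpG-undepleted 300-kb genome
  at 50× (the per-dinucleotide effect at the calibrated β is only
  −0.01..−0.03 log2, and a CpG-depleted genome leaves the CG dinucleotide
  too rare to measure at desk scale); mCG overestimation is asserted on a
  70%-methylated 200-kb genome at 40×, where the ~0.7 pp analytic effect
  clears 3× counting noise. A methylated methylome is *not* used for the
  depletion check because modified cytosines are protected — with 70% mCG
  the CG dinucleotide legitimately stops depleting.
- **Conversion artefacts** (mean CH failure ~1%, zero true mCH, 750-kb
  genome at 20×): a 10% threshold removes almost nothing at ~7× per-strand
  coverage, where one failed call already reads as ≥10% — the realistic
  regime, and the reason the threshold approach is the weakest of the
  three; the 3xC filter cuts the residual below 0.1% by removing poorly
  converted molecules; background subtraction (unclipped aggregate)
  centres the residual on zero. The motif scenario plants 12 CCWGG
  instances in a 600-bp consensus sequenced at 800× with an 800×
  resistance multiplier: the concentrated ~40%-methylated positions pass
  both the threshold and the 3xC filter, and only the matched
  unmethylated control removes them.
- **Quantification strategies**: a bimodal site-level methylome (p = 0.05
  or 0.95 per CpG dyad, the realistic shape of CpG methylomes) on a
  CpG-dense 85-kb genome at 60× with degradation on, quantified over 1072
  five-CpG tiles. Per-cytosine averaging beats pooling on mean absolute
  error (~2.1 vs ~3.0 pp against molecular truth), and a ≥10× coverage
  floor multiplies the pooled error roughly fivefold by selecting exactly
  the coverage-inflated (methylated) cytosines.
- **Protocol contrasts**: heat vs alkaline conversion recovers the ~4×
  failure-rate ratio on 40-kb unmethylated libraries at 150× (wide CI —
  poor-molecule counts are Poisson); amplification-free vs amplified is
  compared over 10 replicate libraries because the two share the
  degradation bias and differ by PCR-added sampling variance (measured
  deviation spreads 0.77 vs 1.71 pp), so a single-library comparison is
  close to a coin flip and would be a meaningless assertion.

`scripts/acceptance.py` re-runs all of the above from scratch under a
caller-supplied seed and writes the measured quantities as JSON.

## Known limitations

- Ungapped alignments only; clipped/indel records are counted and skipped.
- Degradation is whole-molecule; fragment-length shortening by in-situ
  breakage (the post-BS fragmentation-as-feature) is approximated by
  applying survival before emission with `cycles = 0`.
- PCR efficiency depends on composition only; no correlation between a
  molecule's conversion fate and its amplification, so the model
  understates how amplification compounds conversion artefacts.
- The mean-coverage denominator of the feature trend is an approximation
  of relative-trend normalisation; it is exact for uniform coverage.
- Paired-end reads, quality scores and mappability are out of scope.
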