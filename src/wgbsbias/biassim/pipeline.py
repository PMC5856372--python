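"""The simulation pipeline: fragmentation through read emission.

Stages are pure functions over :class:`Fragment` lists so each bias can be
toggled independently; every stage draws from its own named random
substream derived from the root seed, so switching one stage on or off
never perturbs another stage's draws.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..refio import (
    BsAlignment,
    GenomicInterval,
    RawRead,
    ReferenceGenome,
    revcomp,
    write_alignments,
    write_fasta,
)
from .models import (
    Fragment,
    Methylome,
    PcrModel,
    ProtocolModel,
    STATE_5MC,
    STATE_5HMC,
    STATE_UNMOD,
    SimTruth,
)
from .synthgenome import random_genome

# named random substreams (root seed, stage id)
_STAGE_FRAGMENT = 0
_STAGE_METHYLOME = 1
_STAGE_CONVERT = 2
_STAGE_PCR = 3
_STAGE_EMIT = 4
_STAGE_GENOME = 5


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


_H = "ACT"
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "[AT]", "S": "[CG]", "R": "[AG]", "Y": "[CT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _context_char(seq: str, i: int, strand: str) -> str:
    """Call-string context class (z/x/h/u) of the C at top-coordinate i."""
    n = len(seq)
    if strand == "+":
        b1 = seq[i + 1] if i + 1 < n else None
        b2 = seq[i + 2] if i + 2 < n else None
    else:  # bottom strand reads right-to-left; complement of i-1, i-2
        b1 = seq[i - 1].translate(_COMP) if i - 1 >= 0 else None
        b2 = seq[i - 2].translate(_COMP) if i - 2 >= 0 else None
    if b1 is None or b1 == "N":
        return "u"
    if b1 == "G":
        return "z"
    if b2 is None or b2 == "N":
        return "u"
    if b1 in _H and b2 == "G":
        return "x"
    if b1 in _H and b2 in _H:
        return "h"
    return "u"


_COMP = str.maketrans("ACGTN", "TGCAN")


class GenomeIndex:
    """Per-chromosome cytosine positions, contexts and resistant motifs."""

    def __init__(
        self,
        genome: ReferenceGenome,
        resistant_motifs: Sequence[Tuple[str, float]] = (),
    ) -> None:
        self.genome = genome
        self.c_pos: Dict[Tuple[str, str], np.ndarray] = {}
        self.c_ctx: Dict[Tuple[str, str], List[str]] = {}
        self.resistant: Dict[Tuple[str, str, int], float] = {}
        for name, seq in genome.items():
            for strand, base in (("+", "C"), ("-", "G")):
                positions = [i for i, b in enumerate(seq) if b == base]
                self.c_pos[(name, strand)] = np.asarray(positions, dtype=np.int64)
                self.c_ctx[(name, strand)] = [
                    _context_char(seq, i, strand) for i in positions
                ]
        for motif, multiplier in resistant_motifs:
            pattern = "".join(_IUPAC[ch] for ch in motif.upper())
            rc_pattern = "".join(
                _IUPAC[ch] for ch in revcomp(motif.upper())
            )
            for name, seq in genome.items():
                for m in re.finditer(f"(?={pattern})", seq):
                    for j in range(m.start(), m.start() + len(motif)):
                        if seq[j] == "C":
                            key = (name, "+", j)
                            self.resistant[key] = max(
                                self.resistant.get(key, 1.0), multiplier
                            )
                for m in re.finditer(f"(?={rc_pattern})", seq):
                    for j in range(m.start(), m.start() + len(motif)):
                        if seq[j] == "G":
                            key = (name, "-", j)
                            self.resistant[key] = max(
                                self.resistant.get(key, 1.0), multiplier
                            )

    def cytosines_in(
        self, chrom: str, start: int, end: int, strand: str
    ) -> Tuple[List[int], List[str]]:
        pos = self.c_pos[(chrom, strand)]
        ctx = self.c_ctx[(chrom, strand)]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        return [int(p) for p in pos[lo:hi]], ctx[lo:hi]

    def multiplier(self, chrom: str, strand: str, pos: int) -> float:
        return self.resistant.get((chrom, strand, pos), 1.0)


def fragment_genome(
    genome: ReferenceGenome,
    mean_length: float = 150.0,
    length_sd: float = 30.0,
    depth: float = 10.0,
    seed: int = 0,
    min_length: int = 30,
    rng: Optional[np.random.Generator] = None,
) -> List[Fragment]:
    """Sonication model: uniform starts, truncated-normal lengths.

    The fragment count targets ``depth`` x coverage:
    round(genome_length * depth / mean_length).  Each fragment yields one
    single-strand molecule, top or bottom strand equiprobably (the two
    strands separate at denaturation and are processed independently).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if mean_length < min_length:
        raise ValueError("mean_length below the minimum fragment length")
    if rng is None:
        rng = stage_rng(seed, _STAGE_FRAGMENT)
    names = list(genome)
    lengths = np.array([len(genome[n]) for n in names], dtype=float)
    n_frags = int(round(lengths.sum() * depth / mean_length))
    chrom_idx = rng.choice(len(names), size=n_frags, p=lengths / lengths.sum())
    raw_len = rng.normal(mean_length, length_sd, size=n_frags)
    fragments: List[Fragment] = []
    for k in range(n_frags):
        chrom = names[chrom_idx[k]]
        chrom_len = int(lengths[chrom_idx[k]])
        frag_len = int(np.clip(round(raw_len[k]), min_length, chrom_len))
        start = int(rng.integers(0, chrom_len - frag_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        fragments.append(
            Fragment(index=k, chrom=chrom, start=start, end=start + frag_len,
                     strand=strand)
        )
    return fragments


def apply_methylome(
    fragments: Sequence[Fragment],
    index: GenomeIndex,
    methylome: Methylome,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> List[Fragment]:
    """Draw per-molecule cytosine states from the methylome.

    States are drawn independently per molecule, so two molecules covering
    the same cytosine can disagree — exactly the cell-to-cell heterogeneity
    that partial methylation levels describe.
    """
    if rng is None:
        rng = stage_rng(seed, _STAGE_METHYLOME)
    for frag in fragments:
        positions, contexts = index.cytosines_in(
            frag.chrom, frag.start, frag.end, frag.strand
        )
        frag.c_positions = positions
        frag.c_contexts = contexts
        states: List[str] = []
        for pos, ctx in zip(positions, contexts):
            p_m = methylome.p_meth(frag.chrom, pos, frag.strand, ctx)
            p_hm = methylome.p_hmCG if ctx == "z" else 0.0
            u = rng.random()
            if u < p_m:
                states.append(STATE_5MC)
            elif u < p_m + p_hm:
                states.append(STATE_5HMC)
            else:
                states.append(STATE_UNMOD)
        frag.states = states
    return list(fragments)


def bisulfite_convert(
    fragments: Sequence[Fragment],
    index: GenomeIndex,
    protocol: ProtocolModel,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> List[Fragment]:
    """Degradation survival and per-cytosine conversion.

    Survival probability is ``base_survival * (1-beta_unmod)^k_u *
    (1-beta_mod)^k_m``.  Surviving molecules are poorly converted wholesale
    with ``poor_conversion_fraction``; otherwise each unmodified C fails
    conversion with its per-context epsilon times any resistant-motif
    multiplier.  Returns the surviving fragments; fate is recorded on every
    fragment either way.
    """
    survivors: List[Fragment] = []
    if rng is None:
        rng = stage_rng(seed, _STAGE_CONVERT)
    for frag in fragments:
        k_u = frag.n_unmodified
        k_m = frag.n_modified
        p_survive = (
            protocol.base_survival
            * (1.0 - protocol.beta_unmod) ** k_u
            * (1.0 - protocol.beta_mod) ** k_m
        )
        frag.survived = bool(rng.random() < p_survive)
        if not frag.survived:
            frag.converted = []
            continue
        frag.poorly_converted = bool(
            protocol.poor_conversion_fraction > 0
            and rng.random() < protocol.poor_conversion_fraction
        )
        converted: List[bool] = []
        for pos, ctx, state in zip(
            frag.c_positions, frag.c_contexts, frag.states
        ):
            if state == STATE_UNMOD:
                if frag.poorly_converted:
                    p_fail = protocol.poor_conversion_epsilon
                else:
                    base = (
                        protocol.epsilon_CG if ctx == "z" else protocol.epsilon_CH
                    )
                    p_fail = min(
                        1.0, base * index.multiplier(frag.chrom, frag.strand, pos)
                    )
                converted.append(bool(rng.random() >= p_fail))
            elif state == STATE_5MC:
                converted.append(bool(rng.random() < protocol.gamma))
            else:  # 5hmC resists conversion
                converted.append(False)
        frag.converted = converted
        seq = index.genome[frag.chrom][frag.start : frag.end]
        # G content of the converted molecule: conversion rewrites the
        # molecule's own Cs, leaving its G count unchanged
        if frag.strand == "+":
            frag.g_frac = seq.count("G") / len(seq)
        else:
            frag.g_frac = seq.count("C") / len(seq)
        survivors.append(frag)
    return survivors


def pcr_amplify(
    fragments: Sequence[Fragment],
    pcr: PcrModel,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> List[Fragment]:
    """Per-cycle copying with G-fraction-dependent efficiency.

    ``cycles=0`` is the identity (amplification-free).  Copy counts grow per
    molecule; emission later samples from the amplified pool, which is how
    the sequencer sees a PCR-skewed library.
    """
    if pcr.cycles == 0:
        return list(fragments)
    if rng is None:
        rng = stage_rng(seed, _STAGE_PCR)
    for frag in fragments:
        eff = pcr.efficiency(frag.g_frac)
        copies = frag.copies
        if pcr.stochastic:
            for _ in range(pcr.cycles):
                copies += int(rng.binomial(copies, eff))
        else:
            copies = int(round(copies * (1.0 + eff) ** pcr.cycles))
        frag.copies = copies
    return list(fragments)


def _call_string(frag: Fragment, wstart: int, wend: int) -> str:
    chars = ["."] * (wend - wstart)
    for pos, ctx, state, conv in zip(
        frag.c_positions, frag.c_contexts, frag.states, frag.converted
    ):
        if wstart <= pos < wend:
            chars[pos - wstart] = ctx.upper() if not conv else ctx
    return "".join(chars)


def _molecule_window_seq(
    genome: ReferenceGenome, frag: Fragment, wstart: int, wend: int
) -> str:
    """Converted molecule-strand sequence over [wstart, wend), 5'->3'."""
    top = genome[frag.chrom][wstart:wend]
    if frag.strand == "+":
        arr = list(top)
        for pos, conv in zip(frag.c_positions, frag.converted):
            if conv and wstart <= pos < wend:
                arr[pos - wstart] = "T"
        return "".join(arr)
    arr = list(top.translate(_COMP))  # bottom strand, reference orientation
    for pos, conv in zip(frag.c_positions, frag.converted):
        if conv and wstart <= pos < wend:
            arr[pos - wstart] = "T"
    return "".join(arr[::-1])  # bottom strand runs right-to-left


def emit_reads(
    fragments: Sequence[Fragment],
    genome: ReferenceGenome,
    read_length: int = 100,
    protocol_direction: str = "pre_bs",
    seed: int = 0,
    target_reads: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[BsAlignment], List[RawRead]]:
    """Emit single-end reads from the (possibly amplified) molecule pool.

    Reads start at the molecule's 5' end (shorter molecules are read
    whole).  ``pre_bs`` reads the converted molecule itself (OT/OB);
    ``post_bs`` reads the complementary strand synthesised on it, as
    post-bisulfite adaptor tagging does (CTOT/CTOB, sequence
    reverse-complemented).  When ``target_reads`` is set the amplified pool
    is subsampled binomially — the sequencer samples a fixed number of
    molecules, it does not report every PCR copy.  Emission beyond the
    first copy of a fragment is flagged duplicate.
    """
    if protocol_direction not in ("pre_bs", "post_bs"):
        raise ValueError(f"unknown protocol_direction {protocol_direction!r}")
    if rng is None:
        rng = stage_rng(seed, _STAGE_EMIT)
    total_copies = sum(f.copies for f in fragments)
    if target_reads is not None and total_copies > 0:
        rate = min(1.0, target_reads / total_copies)
    else:
        rate = 1.0
    alignments: List[BsAlignment] = []
    raw_reads: List[RawRead] = []
    for frag in fragments:
        n_emit = (
            frag.copies
            if rate >= 1.0
            else int(rng.binomial(frag.copies, rate))
        )
        frag.emitted = n_emit
        if n_emit == 0:
            continue
        if frag.strand == "+":
            wstart, wend = frag.start, min(frag.end, frag.start + read_length)
        else:
            wstart, wend = max(frag.start, frag.end - read_length), frag.end
        call = _call_string(frag, wstart, wend)
        mol_seq = _molecule_window_seq(genome, frag, wstart, wend)
        if protocol_direction == "pre_bs":
            bs_strand = "OT" if frag.strand == "+" else "OB"
            seq = mol_seq
        else:
            bs_strand = "CTOT" if frag.strand == "+" else "CTOB"
            seq = revcomp(mol_seq)
        iv = GenomicInterval(frag.chrom, wstart, wend)
        for c in range(n_emit):
            alignments.append(
                BsAlignment(
                    read_id=f"frag{frag.index}_c{c}",
                    interval=iv,
                    bs_strand=bs_strand,
                    call_string=call,
                    is_duplicate=(c > 0),
                )
            )
            raw_reads.append(RawRead(f"frag{frag.index}_c{c}", seq))
    return alignments, raw_reads


@dataclass
class SimConfig:
    """Bundle of all simulation stages' parameters."""

    seed: int = 0
    genome: Optional[ReferenceGenome] = None
    genome_length: int = 10_000
    genome_gc: float = 0.42
    genome_cpg_obs_exp: float = 0.2
    methylome: Methylome = field(default_factory=Methylome)
    protocol: ProtocolModel = field(default_factory=ProtocolModel)
    pcr: PcrModel = field(default_factory=PcrModel)
    mean_length: float = 150.0
    length_sd: float = 30.0
    depth: float = 10.0
    read_length: int = 100
    protocol_direction: str = "pre_bs"
    #: subsample the amplified pool to about this many reads; defaults to
    #: the pre-PCR fragment count so depth is preserved under amplification
    target_reads: Optional[int] = None
    spike_name: Optional[str] = None
    spike_length: int = 2_000
    spike_gc: float = 0.5


@dataclass
class SimBundle:
    genome: ReferenceGenome
    alignments: List[BsAlignment]
    raw_reads: List[RawRead]
    truth: SimTruth
    config: SimConfig


def simulate(config: SimConfig, out_dir=None) -> SimBundle:
    """Run the full pipeline; optionally write FASTA/SAM/FASTQ/truth TSVs."""
    seed = config.seed
    if config.genome is None:
        genome = random_genome(
            config.genome_length,
            gc=config.genome_gc,
            cpg_obs_exp=config.genome_cpg_obs_exp,
            rng=stage_rng(seed, _STAGE_GENOME),
        )
    else:
        genome = config.genome
    methylome = config.methylome
    if config.spike_name is not None:
        spike = random_genome(
            config.spike_length,
            gc=config.spike_gc,
            cpg_obs_exp=1.0,
            name=config.spike_name,
            rng=stage_rng(seed, _STAGE_GENOME + 100),
        )
        records = dict(genome.records)
        records[config.spike_name] = spike[config.spike_name]
        genome = ReferenceGenome(records)
        chrom_probs = dict(methylome.chrom_probs or {})
        chrom_probs[config.spike_name] = (0.0, 0.0)  # spike is unmethylated
        methylome = Methylome(
            p_mCG=methylome.p_mCG,
            p_mCH=methylome.p_mCH,
            p_hmCG=methylome.p_hmCG,
            site_probs=methylome.site_probs,
            region_probs=methylome.region_probs,
            chrom_probs=chrom_probs,
        )
    index = GenomeIndex(genome, config.protocol.resistant_motifs)
    fragments = fragment_genome(
        genome,
        mean_length=config.mean_length,
        length_sd=config.length_sd,
        depth=config.depth,
        seed=seed,
    )
    apply_methylome(fragments, index, methylome, seed=seed)
    survivors = bisulfite_convert(fragments, index, config.protocol, seed=seed)
    amplified = pcr_amplify(survivors, config.pcr, seed=seed)
    target = config.target_reads
    if target is None and config.pcr.cycles > 0:
        target = len(fragments)
    alignments, raw_reads = emit_reads(
        amplified,
        genome,
        read_length=config.read_length,
        protocol_direction=config.protocol_direction,
        seed=seed,
        target_reads=target,
    )
    truth = SimTruth(
        seed=seed,
        methylome=methylome,
        protocol=config.protocol,
        pcr=config.pcr,
        fragments=list(fragments),
    )
    bundle = SimBundle(genome, alignments, raw_reads, truth, config)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: SimBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(out_dir / "genome.fa", bundle.genome)
    sequences = {r.read_id: r.sequence for r in bundle.raw_reads}
    write_alignments(
        out_dir / "reads.sam",
        bundle.alignments,
        bundle.genome.lengths,
        sequences=sequences,
    )
    with open(out_dir / "reads.fastq", "w") as fh:
        for read in bundle.raw_reads:
            fh.write(
                f"@{read.read_id}\n{read.sequence}\n+\n"
                + "I" * len(read.sequence)
                + "\n"
            )
    with open(out_dir / "truth_positions.tsv", "w") as fh:
        fh.write("chrom\tpos\tstrand\tcontext\tn_modified\tn_molecules\n")
        for (chrom, pos, strand), (ctx, m, t) in sorted(
            bundle.truth.per_position_truth().items()
        ):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{ctx}\t{m}\t{t}\n")
    with open(out_dir / "truth_fragments.tsv", "w") as fh:
        fh.write(
            "index\tchrom\tstart\tend\tstrand\tn_unmod\tn_mod\t"
            "survived\tpoorly_converted\tcopies\temitted\n"
        )
        for f in bundle.truth.fragments:
            fh.write(
                f"{f.index}\t{f.chrom}\t{f.start}\t{f.end}\t{f.strand}\t"
                f"{f.n_unmodified}\t{f.n_modified}\t{int(bool(f.survived))}\t"
                f"{int(f.poorly_converted)}\t{f.copies}\t{f.emitted}\n"
            )
    cfg = bundle.config
    with open(out_dir / "config.json", "w") as fh:
        json.dump(
            {
                "seed": cfg.seed,
                "genome_length": bundle.genome.total_length,
                "depth": cfg.depth,
                "mean_length": cfg.mean_length,
                "read_length": cfg.read_length,
                "protocol_direction": cfg.protocol_direction,
                "protocol": {
                    "beta_unmod": cfg.protocol.beta_unmod,
                    "beta_mod": cfg.protocol.beta_mod,
                    "epsilon_CG": cfg.protocol.epsilon_CG,
                    "epsilon_CH": cfg.protocol.epsilon_CH,
                    "gamma": cfg.protocol.gamma,
                    "poor_conversion_fraction": cfg.protocol.poor_conversion_fraction,
                    "poor_conversion_epsilon": cfg.protocol.poor_conversion_epsilon,
                    "base_survival": cfg.protocol.base_survival,
                },
                "pcr": {
                    "cycles": cfg.pcr.cycles,
                    "efficiency_base": cfg.pcr.efficiency_base,
                    "efficiency_slope": cfg.pcr.efficiency_slope,
                    "g_ref": cfg.pcr.g_ref,
                    "stochastic": cfg.pcr.stochastic,
                },
                "methylome": {
                    "p_mCG": bundle.truth.methylome.p_mCG,
                    "p_mCH": bundle.truth.methylome.p_mCH,
                    "p_hmCG": bundle.truth.methylome.p_hmCG,
                },
            },
            fh,
            indent=2,
        )
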