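"""Model dataclasses for the bisulfite library-preparation simulator.

The generative model factors library preparation into four stochastic
stages, each with its own parameters:

1. fragmentation (sonication) — fragment starts and lengths;
2. methylome assignment — per-molecule cytosine states drawn from
   context-level or site-level probabilities;
3. bisulfite conversion — whole-molecule survival (degradation) as
   ``(1-beta_unmod)^k_u * (1-beta_mod)^k_m`` over the molecule's
   unmodified/modified cytosine counts, then per-cytosine conversion with
   molecule-level failure heterogeneity (a small fraction of molecules is
   poorly converted wholesale, which is what makes read-level
   non-conversion filters effective);
4. PCR — per-cycle copying with efficiency depending on the converted
   molecule's G fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ..refio import GenomicInterval

STATE_UNMOD = "C"
STATE_5MC = "5mC"
STATE_5HMC = "5hmC"


def _check_prob(value: float, label: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{label} must be in [0, 1], got {value}")


@dataclass
class Methylome:
    """Truth methylation probabilities per context, with optional overrides.

    ``p_mCG``/``p_mCH`` are the per-molecule probabilities that a CpG /
    non-CpG cytosine carries 5mC; ``p_hmCG`` the CpG 5hmC probability
    (5mC + 5hmC must not exceed 1).  ``site_probs`` pins individual
    (chrom, pos, strand) cytosines to a 5mC probability; ``region_probs``
    overrides CpG probability inside intervals; ``chrom_probs`` overrides
    both contexts per chromosome (used for unmethylated spike-ins).
    Resolution order: site > region > chromosome > context default.
    """

    p_mCG: float = 0.7
    p_mCH: float = 0.0
    p_hmCG: float = 0.0
    site_probs: Optional[Dict[Tuple[str, int, str], float]] = None
    region_probs: Optional[Sequence[Tuple[GenomicInterval, float]]] = None
    chrom_probs: Optional[Dict[str, Tuple[float, float]]] = None

    def __post_init__(self) -> None:
        _check_prob(self.p_mCG, "p_mCG")
        _check_prob(self.p_mCH, "p_mCH")
        _check_prob(self.p_hmCG, "p_hmCG")
        if self.p_mCG + self.p_hmCG > 1.0:
            raise ValueError("p_mCG + p_hmCG exceeds 1")

    def p_meth(self, chrom: str, pos: int, strand: str, context: str) -> float:
        """5mC probability for one cytosine (context: z/x/h/u char class)."""
        if self.site_probs is not None:
            v = self.site_probs.get((chrom, pos, strand))
            if v is not None:
                return v
        is_cpg = context == "z"
        if is_cpg and self.region_probs:
            for iv, p in self.region_probs:
                if iv.chrom == chrom and iv.start <= pos < iv.end:
                    return p
        if self.chrom_probs is not None and chrom in self.chrom_probs:
            pcg, pch = self.chrom_probs[chrom]
            return pcg if is_cpg else pch
        return self.p_mCG if is_cpg else self.p_mCH


@dataclass
class ProtocolModel:
    """Bisulfite conversion protocol: degradation + conversion parameters.

    Degradation: each unmodified cytosine independently breaks the backbone
    with probability ``beta_unmod`` (modified: ``beta_mod``), so a molecule
    survives intact with ``(1-beta_unmod)^k_u * (1-beta_mod)^k_m`` —
    modification protection requires ``beta_mod <= beta_unmod``.
    ``base_survival`` is a C-independent whole-molecule survival factor
    (models protocols with low but composition-neutral recovery).

    Conversion: a molecule is poorly converted wholesale with probability
    ``poor_conversion_fraction`` (every unmodified C then fails with
    ``poor_conversion_epsilon``); otherwise unmodified Cs fail with the
    per-context ``epsilon_CG``/``epsilon_CH``, multiplied at positions
    inside ``resistant_motifs`` (IUPAC motifs such as CCWGG whose
    conversion resistance is sequence-intrinsic).  5mC over-converts (reads
    as T) with probability ``gamma``; 5hmC never converts.
    """

    beta_unmod: float = 0.0
    beta_mod: float = 0.0
    epsilon_CG: float = 0.0
    epsilon_CH: float = 0.0
    gamma: float = 0.0
    resistant_motifs: Sequence[Tuple[str, float]] = ()
    poor_conversion_fraction: float = 0.0
    poor_conversion_epsilon: float = 0.8
    base_survival: float = 1.0

    def __post_init__(self) -> None:
        for label in (
            "beta_unmod", "beta_mod", "epsilon_CG", "epsilon_CH",
            "gamma", "poor_conversion_fraction", "poor_conversion_epsilon",
            "base_survival",
        ):
            _check_prob(getattr(self, label), label)
        if self.beta_mod > self.beta_unmod:
            raise ValueError(
                "beta_mod > beta_unmod would make modification *sensitising*; "
                "the protective direction requires beta_mod <= beta_unmod"
            )

    def mean_epsilon(self, context: str = "CH") -> float:
        """Expected per-call failure rate marginal over molecule class."""
        base = self.epsilon_CG if context == "CG" else self.epsilon_CH
        f = self.poor_conversion_fraction
        return (1 - f) * base + f * self.poor_conversion_epsilon


@dataclass
class PcrModel:
    """PCR amplification with G-content-dependent per-cycle efficiency.

    efficiency = clamp(efficiency_base + efficiency_slope * (g_frac - g_ref), 0, 1)

    where ``g_frac`` is the G fraction of the converted single-strand
    molecule.  ``cycles=0`` reproduces amplification-free behaviour
    exactly.  ``stochastic`` switches between per-cycle binomial copying
    and deterministic expectation growth.
    """

    cycles: int = 0
    efficiency_base: float = 0.8
    efficiency_slope: float = 0.0
    g_ref: float = 0.2
    stochastic: bool = True

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        _check_prob(self.efficiency_base, "efficiency_base")

    def efficiency(self, g_frac: float) -> float:
        e = self.efficiency_base + self.efficiency_slope * (g_frac - self.g_ref)
        return min(1.0, max(0.0, e))


@dataclass
class Fragment:
    """One double-strand-derived single-strand molecule and its fate."""

    index: int
    chrom: str
    start: int
    end: int
    strand: str  # '+' = top-strand molecule
    c_positions: List[int] = field(default_factory=list)
    c_contexts: List[str] = field(default_factory=list)  # z/x/h/u chars
    states: List[str] = field(default_factory=list)
    survived: Optional[bool] = None
    poorly_converted: bool = False
    converted: List[bool] = field(default_factory=list)  # True = reads as T
    copies: int = 1
    emitted: int = 0
    g_frac: float = 0.0

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def n_unmodified(self) -> int:
        return sum(1 for s in self.states if s == STATE_UNMOD)

    @property
    def n_modified(self) -> int:
        return len(self.states) - self.n_unmodified


@dataclass
class SimTruth:
    """Ground truth of one simulation: parameters plus per-fragment fates."""

    seed: int
    methylome: Methylome
    protocol: ProtocolModel
    pcr: PcrModel
    fragments: List[Fragment]

    def true_global_meth(self, contexts: str = "z") -> float:
        """Realised percent of modified cytosines over all molecules
        (pre-degradation), for call-class contexts (e.g. 'z' or 'xhu')."""
        mod = tot = 0
        for frag in self.fragments:
            for ctx, state in zip(frag.c_contexts, frag.states):
                if ctx in contexts:
                    tot += 1
                    if state != STATE_UNMOD:
                        mod += 1
        if tot == 0:
            raise ValueError("no cytosines in requested contexts")
        return 100.0 * mod / tot

    def per_position_truth(
        self,
    ) -> Dict[Tuple[str, int, str], Tuple[str, int, int]]:
        """(chrom, pos, strand) -> (context char, n modified, n molecules)."""
        out: Dict[Tuple[str, int, str], Tuple[str, int, int]] = {}
        for frag in self.fragments:
            for pos, ctx, state in zip(
                frag.c_positions, frag.c_contexts, frag.states
            ):
                key = (frag.chrom, pos, frag.strand)
                _, m, t = out.get(key, (ctx, 0, 0))
                out[key] = (ctx, m + (state != STATE_UNMOD), t + 1)
        return out

    @property
    def n_survived(self) -> int:
        return sum(1 for f in self.fragments if f.survived)

    @property
    def n_emitted_reads(self) -> int:
        return sum(f.emitted for f in self.fragments if f.survived)
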