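"""Synthetic reference sequences for simulation and testing.

These generators produce the genomic substrates the bias mechanisms act on:
a mammalian-like random genome (CpG-depleted), strand-GC-skewed references
mimicking satellite/mtDNA composition, tandem-repeat references, and
fixed-C-content fragments for degradation-recovery experiments.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..refio import ReferenceGenome

_BASES = np.array(list("ACGT"))


def random_genome(
    length: int,
    gc: float = 0.42,
    cpg_obs_exp: float = 0.2,
    seed: int = 0,
    name: str = "chr1",
    rng: Optional[np.random.Generator] = None,
) -> ReferenceGenome:
    """Random genome with a target GC fraction and CpG observed/expected.

    Bases are drawn i.i.d. at the target GC, then CpG dinucleotides are
    thinned: each CG occurrence is kept with probability ``cpg_obs_exp``,
    otherwise its G is rewritten to A — the standard way mammalian genomes
    deviate from base-composition independence (CpG obs/exp around 0.2 for
    mouse and human).  The base probabilities are pre-compensated for the
    GC the thinning removes, so realised GC tracks the target closely.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    # Two couplings to undo so the *realised* sequence hits the targets:
    # thinning rewrites G->A, deflating GC by (1-keep)*(gc/2)^2, and the
    # same G loss shrinks the obs/exp denominator, so the keep rate must
    # sit below the requested obs/exp.  Fixed-point iterate both.
    gc0, keep = gc, cpg_obs_exp
    for _ in range(8):
        keep = cpg_obs_exp * (1 - (1 - keep) * gc0 / 2)
        gc0 = gc + (1 - keep) * (gc0 / 2) ** 2
    p = np.array([(1 - gc0) / 2, gc0 / 2, gc0 / 2, (1 - gc0) / 2])
    arr = rng.choice(4, size=length, p=p)
    if cpg_obs_exp < 1.0:
        is_c = arr[:-1] == 1
        is_g = arr[1:] == 2
        cpg_idx = np.nonzero(is_c & is_g)[0]
        drop = rng.random(cpg_idx.size) >= keep
        arr[cpg_idx[drop] + 1] = 0  # G -> A
    seq = "".join(_BASES[arr])
    return ReferenceGenome({name: seq})


def skewed_reference(
    length: int,
    c_frac_top: float = 0.13,
    g_frac_top: float = 0.235,
    seed: int = 0,
    name: str = "satellite",
) -> ReferenceGenome:
    """Reference whose top strand is C-poor and G-rich (bottom the reverse).

    Default fractions mirror the 12-14% C / 23-24% C strand asymmetry of
    the mouse major satellite and mtDNA.
    """
    rng = np.random.default_rng(seed)
    at = 1.0 - c_frac_top - g_frac_top
    p = np.array([at / 2, c_frac_top, g_frac_top, at / 2])
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return ReferenceGenome({name: seq})


def tandem_reference(
    motif: str, n_units: int, name: str = "tandem"
) -> ReferenceGenome:
    """A pure tandem-repeat reference, e.g. (TTAGGG)_n for the telomere."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    return ReferenceGenome({name: motif.upper() * n_units})


def fragment_with_c_content(
    length: int,
    c_frac: float,
    seed: int = 0,
    name: str = "fragment",
    g_frac: float = 0.25,
) -> ReferenceGenome:
    """Synthetic fragment with an *exact* cytosine fraction.

    Synthetic stand-in for fixed-composition test fragments (the published
    degradation-recovery experiments used M13-derived fragments of 15% and
    30% C): exactly ``round(c_frac*length)`` cytosines, placed uniformly at
    random among a G/A/T background.
    """
    rng = np.random.default_rng(seed)
    n_c = round(c_frac * length)
    n_g = round(g_frac * length)
    n_rest = length - n_c - n_g
    pool = ["C"] * n_c + ["G"] * n_g + [
        "AT"[i % 2] for i in range(n_rest)
    ]
    arr = np.array(pool)
    rng.shuffle(arr)
    return ReferenceGenome({name: "".join(arr)})
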