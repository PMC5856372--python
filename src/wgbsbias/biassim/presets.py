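"""Named protocol presets.

Absolute breakage and conversion-failure rates for bisulfite protocols are
not published; what is published are fold relationships between protocols
(a twofold C-poor/C-rich recovery gap for harsh heat denaturation, a 1.3-fold
gap for alkaline, a roughly fourfold conversion-failure excess of alkaline
over heat, near-complete protection of a fully modified C-rich fragment).
The presets below are calibrated to reproduce those fold relationships on a
150-base fragment and are illustrative operating points, not measured
constants.

The degradation calibration: a per-unmodified-cytosine breakage probability
``beta`` gives two unmethylated pools with C fractions c1 < c2 a recovery
ratio of ``(1-beta)^(-(c2-c1)*L)``, so a target ratio R at fragment length L
needs ``beta = 1 - R^(-1/((c2-c1)*L))``.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .models import PcrModel, ProtocolModel


def degradation_beta_for_ratio(
    ratio: float, delta_c: float = 0.15, length: float = 150.0
) -> float:
    """Per-C breakage probability giving a target recovery ratio.

    ``delta_c`` is the C-fraction difference between the compared pools
    (default 0.30 - 0.15) and ``length`` the fragment length.
    """
    if ratio < 1.0:
        raise ValueError("ratio must be >= 1")
    return 1.0 - ratio ** (-1.0 / (delta_c * length))


_HEAT_BETA = degradation_beta_for_ratio(2.0)        # ~0.0303
_ALKALINE_BETA = degradation_beta_for_ratio(1.3)    # ~0.0116

# mean CH failure rates: heat ~0.3%, alkaline ~1.2% (the 4x relationship)
_HEAT_CONVERSION = dict(
    epsilon_CG=0.0002,
    epsilon_CH=0.0005,
    poor_conversion_fraction=0.003,
    poor_conversion_epsilon=0.8,
)
_ALKALINE_CONVERSION = dict(
    epsilon_CG=0.0008,
    epsilon_CH=0.002,
    poor_conversion_fraction=0.0125,
    poor_conversion_epsilon=0.8,
)

_RESISTANT = (("CCWGG", 100.0),)


def get_preset(name: str) -> Tuple[ProtocolModel, PcrModel, str]:
    """Return (protocol, pcr, direction) for a named preset."""
    presets: Dict[str, Tuple[ProtocolModel, PcrModel, str]] = {
        # all biases off: the global-null reference condition
        "null": (
            ProtocolModel(),
            PcrModel(cycles=0),
            "pre_bs",
        ),
        # harsh heat denaturation + GC-biasing polymerase, amplified
        "heat_like": (
            ProtocolModel(
                beta_unmod=_HEAT_BETA,
                beta_mod=0.0,
                gamma=0.001,
                resistant_motifs=_RESISTANT,
                **_HEAT_CONVERSION,
            ),
            PcrModel(cycles=12, efficiency_base=0.7, efficiency_slope=1.5),
            "pre_bs",
        ),
        # mild alkaline denaturation: less degradation, 4x the conversion
        # failures, amplified
        "alkaline_like": (
            ProtocolModel(
                beta_unmod=_ALKALINE_BETA,
                beta_mod=0.004,
                gamma=0.001,
                resistant_motifs=_RESISTANT,
                **_ALKALINE_CONVERSION,
            ),
            PcrModel(cycles=15, efficiency_base=0.7, efficiency_slope=1.5),
            "pre_bs",
        ),
        # high-molarity ammonium bisulfite: low but composition-neutral
        # recovery
        "ambs_like": (
            ProtocolModel(
                beta_unmod=0.001,
                beta_mod=0.001,
                base_survival=0.35,
                gamma=0.001,
                resistant_motifs=_RESISTANT,
                **_HEAT_CONVERSION,
            ),
            PcrModel(cycles=9, efficiency_base=0.7, efficiency_slope=1.5),
            "pre_bs",
        ),
        # low-GC-bias polymerase: heat conversion, AT-tolerant PCR
        "kapa_like": (
            ProtocolModel(
                beta_unmod=_HEAT_BETA,
                beta_mod=0.0,
                gamma=0.001,
                resistant_motifs=_RESISTANT,
                **_HEAT_CONVERSION,
            ),
            PcrModel(cycles=10, efficiency_base=0.8, efficiency_slope=-0.5),
            "pre_bs",
        ),
        # amplification-free post-bisulfite tagging
        "pbat_like": (
            ProtocolModel(
                beta_unmod=_HEAT_BETA,
                beta_mod=0.0,
                gamma=0.001,
                resistant_motifs=_RESISTANT,
                **_HEAT_CONVERSION,
            ),
            PcrModel(cycles=0),
            "post_bs",
        ),
    }
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        )
    return presets[name]


PRESET_NAMES = ("null", "heat_like", "alkaline_like", "ambs_like",
                "kapa_like", "pbat_like")
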