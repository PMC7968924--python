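"""Named drive-parameter bundles.

``ideal_*`` presets are the comparative-modeling parameter sets: 99%
germline cleavage for every architecture, 90% HDR for the homing drives
(HomeR, HGD), in-frame fractions of 0.5% (homing) or 0.1% (toxin–antidote),
maternal carryover at the germline cleavage rate (95% for TARE, which shows
weaker deposition), and dominant female fecundity costs of 5% (HomeR, TARE,
and the ClvR Cas9 cost) or 20% (HGD, whose disrupted target gene is not
rescued).

``homer_exp`` is the experimentally characterized HomeR: same cleavage,
no male HDR, 1% in-frame end joining.  ``fitted_homer`` is the
posterior-median parameter set estimated from the five drive cages
(c_F=99.2%, c_M=99.6%, ch_F=99.5%, ch_M=9.6%, cr=2.9%, s_F=0.3%); the
fitted model carries no maternal-deposition term, so d_F=0.
"""

from __future__ import annotations

from .genetics import DriveParams

__all__ = ["PRESETS", "preset_parameters"]

PRESETS: dict[str, DriveParams] = {
    "ideal_homer": DriveParams(
        c_F=0.99, c_M=0.99, ch_F=0.90, ch_M=0.90, cr_F=0.005, cr_M=0.005,
        d_F=0.99, dr_F=0.005, s_F=0.05,
    ),
    "homer_exp": DriveParams(
        c_F=0.99, c_M=0.99, ch_F=0.90, ch_M=0.0, cr_F=0.01, cr_M=0.01,
        d_F=0.99, dr_F=0.01, s_F=0.05,
    ),
    "ideal_hgd": DriveParams(
        c_F=0.99, c_M=0.99, ch_F=0.90, ch_M=0.90, cr_F=0.005, cr_M=0.005,
        d_F=0.99, dr_F=0.005, s_F=0.20,
    ),
    "ideal_clvr": DriveParams(
        c_F=0.99, c_M=0.99, cr_F=0.001, cr_M=0.001, d_F=0.99, dr_F=0.001, s_F=0.05,
    ),
    "ideal_tare": DriveParams(
        c_F=0.99, c_M=0.99, cr_F=0.001, cr_M=0.001, d_F=0.95, dr_F=0.001, s_F=0.05,
    ),
    "fitted_homer": DriveParams(
        c_F=0.992, c_M=0.996, ch_F=0.995, ch_M=0.096, cr_F=0.029, cr_M=0.029,
        d_F=0.0, dr_F=0.0, s_F=0.003,
    ),
    "mendelian": DriveParams(),
}


def preset_parameters(name: str) -> DriveParams:
    """Look up a named parameter bundle."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
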