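"""Glass-transition machinery: Gordon-Taylor mixing and the plasticization factor.

The Gordon-Taylor constant of water is fixed at 1 by the normalisation of
the mixing rule; the polymer and API constants can be estimated from pure
densities and glass-transition temperatures via the Simha-Boyer rule
K = (rho_w Tg_w)/(rho_i Tg_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "GordonTaylorSet",
    "gordon_taylor_tg",
    "simha_boyer_K",
    "plasticization_factor",
]


@dataclass(frozen=True)
class GordonTaylorSet:
    """Gordon-Taylor inputs of a water + polymer + API system (K_water = 1)."""

    tg_water: float  # K
    tg_polymer: Optional[float] = None  # K
    k_polymer: Optional[float] = None
    tg_api: Optional[float] = None  # K
    k_api: Optional[float] = None


def gordon_taylor_tg(
    w_api: float, w_polymer: float, w_water: float, gt: GordonTaylorSet
) -> float:
    """Glass-transition temperature of the ternary mixture (K).

    Tg = (Ka wa Tg0a + Kp wp Tg0p + ww Tg0w) / (Ka wa + Kp wp + ww).
    Components with zero weight need no parameters.
    """
    total = w_api + w_polymer + w_water
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"weights sum to {total:.8f}, not 1")
    num = w_water * gt.tg_water
    den = w_water
    if w_api > 0:
        if gt.tg_api is None or gt.k_api is None:
            raise ValueError("API Gordon-Taylor parameters missing")
        num += gt.k_api * w_api * gt.tg_api
        den += gt.k_api * w_api
    if w_polymer > 0:
        if gt.tg_polymer is None or gt.k_polymer is None:
            raise ValueError("polymer Gordon-Taylor parameters missing")
        num += gt.k_polymer * w_polymer * gt.tg_polymer
        den += gt.k_polymer * w_polymer
    if den <= 0:
        raise ValueError("all Gordon-Taylor weights are zero")
    return num / den


def simha_boyer_K(
    rho_i: float, tg_i: float, rho_w: float = 997.0, tg_w: float = 136.0
) -> float:
    """Simha-Boyer estimate of the Gordon-Taylor constant of component i.

    K_i = (rho_w Tg_w) / (rho_i Tg_i), densities in consistent units.
    """
    if min(rho_i, tg_i, rho_w, tg_w) <= 0:
        raise ValueError("Simha-Boyer inputs must be positive")
    return (rho_w * tg_w) / (rho_i * tg_i)


def plasticization_factor(tg_dry: float, tg_wet: float, T: float) -> float:
    """Psi_w = (Tg,dry - Tg,wet) / (Tg,dry - T).

    Normalised progress of water plasticization towards the glass transition:
    0 when dry, 1 when the wet glass transition reaches the system
    temperature. Undefined for a system that is already rubbery when dry.
    """
    if tg_dry <= T:
        raise ValueError(
            f"dry glass transition {tg_dry:.2f} K is not above T = {T:.2f} K; "
            "the plasticization factor is undefined for a rubbery dry system"
        )
    return (tg_dry - tg_wet) / (tg_dry - T)
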