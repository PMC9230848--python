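"""Water-sorption isotherms of neat polymers, neat APIs and their ASDs.

The water uptake at each relative humidity follows from the isofugacity
criterion f_w^L = f_w^V at total pressure equal to the water partial
pressure p_w = p_sat * RH. The condensed-phase fugacity is evaluated either
at the equilibrium (rubbery) volume or at the imposed non-equilibrium
(glassy) volume, and the branch whose solution predicts *more* water mole
fraction on the equilibrium side wins the transition rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .components import mass_to_mole_fractions
from .eos import PcSaft
from .glass import GordonTaylorSet, gordon_taylor_tg
from .netgp import (
    DryASDSpec,
    RH_EXPONENT_DEFAULT,
    dry_specific_volume,
    equilibrium_specific_volume,
    ne_ln_fugacity,
    ne_specific_volume,
    select_branch,
    swelling_coefficient,
)
from .registry import ParameterRegistry

log = logging.getLogger(__name__)

__all__ = [
    "SorptionSystem",
    "IsothermPoint",
    "vapor_water_fugacity",
    "solve_water_uptake",
    "isotherm_curve",
    "glassy_limit_rh",
    "NoRootError",
    "GlassyThroughoutRange",
]

WW_MAX = 0.95  # upper bracket for the water mass fraction root


class NoRootError(RuntimeError):
    """The isofugacity residual has no sign change in the water bracket."""


class GlassyThroughoutRange(RuntimeError):
    """The wet glass transition never reaches T within the RH range."""


@dataclass(frozen=True)
class IsothermPoint:
    """One point of a water-sorption isotherm."""

    rh: float
    temperature: float
    ww: float  # water mass fraction
    branch: str  # "EQ" | "NE"
    tg: float  # K, wet-mixture glass transition


class SorptionSystem:
    """A water + dry-matrix system bound to a parameter registry.

    Handles neat polymers (drug load 0), neat APIs (drug load 1) and ASDs;
    zero-weight dry components are dropped from the working mixture so the
    equation of state never sees exact-zero compositions.
    """

    def __init__(
        self,
        registry: ParameterRegistry,
        spec: DryASDSpec,
        water: str = "water",
        rh_exponent: float = RH_EXPONENT_DEFAULT,
        ideal_vapor: bool = False,
    ):
        self.registry = registry
        self.spec = spec
        self.rh_exponent = rh_exponent
        self.ideal_vapor = ideal_vapor
        self.dry = spec.dry_components  # name -> dry-basis mass fraction
        self.names = [water] + list(self.dry)
        self.mixture = registry.mixture(*self.names)
        self.eos = PcSaft(self.mixture)
        self.water_eos = PcSaft(registry.mixture(water))
        self.molar_masses = np.array([c.molar_mass for c in self.mixture.components])

        v0_map, kw_map = {}, {}
        for name in self.dry:
            entry = registry.ne_params[name]
            if entry.v0_ne is not None:
                v0_map[name] = entry.v0_ne
            else:
                v0_map[name] = equilibrium_specific_volume(PcSaft(registry.mixture(name)))
            kw_map[name] = entry.kw_ne
        self.v0_ne = dry_specific_volume(spec, v0_map)
        self.kw_ne = swelling_coefficient(spec, v0_map, kw_map)

        comp = registry.components
        self.gt = GordonTaylorSet(
            tg_water=comp[water].tg,
            tg_polymer=comp[spec.polymer].tg if spec.polymer else None,
            k_polymer=comp[spec.polymer].gordon_taylor_k if spec.polymer else None,
            tg_api=comp[spec.api].tg if spec.api else None,
            k_api=comp[spec.api].gordon_taylor_k if spec.api else None,
        )

    # ------------------------------------------------------------------
    def wet_mass_fractions(self, ww: float) -> np.ndarray:
        """Mass fractions [water, dry components...] at water fraction ww."""
        return np.array([ww] + [(1.0 - ww) * w for w in self.dry.values()])

    def water_mole_fraction(self, ww: float) -> float:
        if ww <= 0:
            return 0.0
        x = mass_to_mole_fractions(self.wet_mass_fractions(ww), self.molar_masses)
        return float(x[0])

    def tg(self, ww: float) -> float:
        """Wet-mixture Gordon-Taylor glass transition (K)."""
        w_api = (1.0 - ww) * self.spec.drug_load if self.spec.api else 0.0
        w_pol = (1.0 - ww) * self.spec.polymer_load if self.spec.polymer else 0.0
        return gordon_taylor_tg(w_api, w_pol, ww, self.gt)

    @property
    def tg_dry(self) -> float:
        return self.tg(0.0)

    # condensed-phase water fugacities --------------------------------
    def ln_fw_eq(self, T: float, p: float, ww: float) -> float:
        """Equilibrium branch: liquid-root density at (T, p), then ln f_w."""
        x = mass_to_mole_fractions(self.wet_mass_fractions(ww), self.molar_masses)
        state = self.eos.solve_density(T, p, x, "liquid")
        return float(self.eos.ln_fugacity(T, state.number_density, x)[0])

    def ln_fw_ne(self, T: float, rh: float, ww: float) -> float:
        """Glassy branch: ln f_w at the imposed non-equilibrium volume."""
        vol = ne_specific_volume(
            self.v0_ne, self.kw_ne, ww, rh, rh_exponent=self.rh_exponent
        )
        w = self.wet_mass_fractions(ww)
        return float(ne_ln_fugacity(self.eos, T, vol.v_ne, w)[0])

    def label(self) -> str:
        if self.spec.api and self.spec.polymer:
            return f"{self.spec.polymer}-{self.spec.api} (DL {self.spec.drug_load:g})"
        return self.spec.api or self.spec.polymer or "?"


def vapor_water_fugacity(
    system_or_eos, T: float, rh: float, ideal: Optional[bool] = None
) -> float:
    """Fugacity of water vapor at p_w = p_sat(T) * RH, in Pa.

    By default the vapor is the PC-SAFT vapor root of pure water at p_w; with
    ``ideal=True`` the vapor is an ideal gas (f = p_w). RH = 0 gives 0.
    """
    if isinstance(system_or_eos, SorptionSystem):
        eos = system_or_eos.water_eos
        if ideal is None:
            ideal = system_or_eos.ideal_vapor
    else:
        eos = system_or_eos
    if not 0.0 <= rh < 1.0:
        raise ValueError(f"RH = {rh} outside [0, 1)")
    if rh == 0.0:
        return 0.0
    psat, _, _ = eos.saturation_pressure(T)
    pw = psat * rh
    if ideal:
        return pw
    x = np.array([1.0])
    vap = eos.solve_density(T, pw, x, "vapor")
    return float(np.exp(eos.ln_fugacity(T, vap.number_density, x)[0]))


def _solve_ww(
    residual: Callable[[float], float], lo: float = 1e-8, hi: float = WW_MAX
) -> Optional[float]:
    """Root of the monotone isofugacity residual in ww, or None if none.

    Log-spaced 16-point bracket scan survives the flat low-RH region, then
    Brent refinement to full precision in ww. Water fractions that push the
    imposed-volume state beyond close packing read as a huge positive
    residual (condensed fugacity far above vapor), consistent with the
    residual's monotonicity.
    """
    from .eos import EosError

    inner = residual

    def residual(ww: float) -> float:
        try:
            return inner(ww)
        except EosError:
            return 1e6

    grid = np.logspace(math.log10(lo), math.log10(hi), 16)
    f_prev = residual(grid[0])
    if f_prev > 0:
        return None  # condensed fugacity already above vapor at trace water
    for i in range(1, len(grid)):
        f_cur = residual(grid[i])
        if f_prev == 0.0:
            return float(grid[i - 1])
        if f_prev < 0 <= f_cur:
            return float(
                brentq(residual, grid[i - 1], grid[i], xtol=1e-300, rtol=1e-15)
            )
        f_prev = f_cur
    return None


def solve_water_uptake(system: SorptionSystem, T: float, rh: float) -> IsothermPoint:
    """Water uptake at one RH via isofugacity on the EQ/NE transition rule.

    Both branch solutions are computed; the branch rule compares their water
    mole fractions (equilibrium wins strictly above the glassy solution).
    """
    if rh == 0.0:
        return IsothermPoint(rh=0.0, temperature=T, ww=0.0, branch="NE", tg=system.tg_dry)
    fwv = vapor_water_fugacity(system, T, rh)
    ln_fwv = math.log(fwv)
    psat, _, _ = system.water_eos.saturation_pressure(T)
    pw = psat * rh

    ww_eq = _solve_ww(lambda ww: system.ln_fw_eq(T, pw, ww) - ln_fwv)
    ww_ne = _solve_ww(lambda ww: system.ln_fw_ne(T, rh, ww) - ln_fwv)
    if ww_eq is None and ww_ne is None:
        raise NoRootError(
            f"no isofugacity root for {system.label()} at RH = {rh:.4f}: "
            f"residual keeps one sign over ww in (1e-8, {WW_MAX})"
        )
    if ww_eq is None or ww_ne is None:
        branch = "EQ" if ww_ne is None else "NE"
        ww = ww_eq if ww_ne is None else ww_ne
    else:
        branch = select_branch(
            system.water_mole_fraction(ww_eq), system.water_mole_fraction(ww_ne)
        )
        ww = ww_eq if branch == "EQ" else ww_ne
    log.debug("%s RH=%.4f -> ww=%.5f (%s)", system.label(), rh, ww, branch)
    return IsothermPoint(rh=rh, temperature=T, ww=ww, branch=branch, tg=system.tg(ww))


def isotherm_curve(
    system: SorptionSystem, T: float, rh_grid: Sequence[float]
) -> List[IsothermPoint]:
    """Pointwise isotherm over an increasing RH grid, with a monotonicity check."""
    rh_grid = list(rh_grid)
    if any(b <= a for a, b in zip(rh_grid, rh_grid[1:])):
        raise ValueError("rh_grid must be strictly increasing")
    points: List[IsothermPoint] = []
    for i, rh in enumerate(rh_grid):
        try:
            points.append(solve_water_uptake(system, T, rh))
        except (NoRootError, RuntimeError) as exc:
            raise type(exc)(f"grid index {i} (RH={rh}): {exc}") from exc
    ww = [p.ww for p in points]
    if any(b < a - 1e-10 for a, b in zip(ww, ww[1:])):
        log.warning(
            "isotherm of %s is not monotone in RH; suspected branch mis-selection",
            system.label(),
        )
    return points


def glassy_limit_rh(
    system: SorptionSystem,
    T: float,
    rh_max: float = 0.95,
    tol: float = 1e-4,
    coarse_step: float = 0.05,
) -> float:
    """RH at which the wet mixture's glass transition equals T.

    Combines the sorption isotherm with the Gordon-Taylor equation and
    bisects Tg(ww(RH)) - T = 0 in RH. Raises GlassyThroughoutRange if the
    system stays glassy over [0, rh_max).
    """
    def h(rh: float) -> float:
        return solve_water_uptake(system, T, rh).tg - T

    if system.tg_dry <= T:
        raise ValueError(f"{system.label()} is rubbery when dry at T = {T} K")
    lo, hi = 0.0, None
    rh = coarse_step
    while rh < rh_max:
        if h(rh) <= 0:
            hi = rh
            break
        lo = rh
        rh += coarse_step
    if hi is None:
        raise GlassyThroughoutRange(
            f"{system.label()} stays glassy over RH in [0, {rh_max})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if h(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
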