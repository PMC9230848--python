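"""Non-equilibrium (glassy) volume model and NET-GP fugacity evaluation.

A glassy film is not at its equilibrium density: its specific volume is
pinned by the glass's history and relaxes only through the empirical
swelling relation

    (v0_NE / v_NE) * (1 - ww) = 1 - kw_NE * RH**2

so the water fugacity in the glass must be evaluated at that imposed volume
(pseudo-equilibrium) rather than at the equilibrium density. The dry ASD
specific volume and swelling coefficient follow mass-weighted and
volume-weighted mixing rules over polymer and API.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .components import MixtureSpec, mass_to_mole_fractions
from .constants import NA
from .eos import PcSaft

__all__ = [
    "DryASDSpec",
    "NEVolumeState",
    "dry_specific_volume",
    "swelling_coefficient",
    "ne_specific_volume",
    "ne_ln_fugacity",
    "select_branch",
    "equilibrium_specific_volume",
]

#: exponent on RH in the swelling relation; 2 reproduces the published form
RH_EXPONENT_DEFAULT = 2.0


class DryASDSpec(BaseModel):
    """Dry amorphous solid dispersion: polymer + API at a given drug load."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    polymer: Optional[str] = None
    api: Optional[str] = None
    drug_load: float = Field(ge=0.0, le=1.0, description="w0a, API mass fraction, dry basis")

    @property
    def polymer_load(self) -> float:
        return 1.0 - self.drug_load

    @property
    def dry_components(self) -> Dict[str, float]:
        """Mass fractions of the dry matrix, zero-weight components dropped."""
        out: Dict[str, float] = {}
        if self.polymer is not None and self.polymer_load > 0:
            out[self.polymer] = self.polymer_load
        if self.api is not None and self.drug_load > 0:
            out[self.api] = self.drug_load
        if not out:
            raise ValueError("dry ASD has no components with positive weight")
        return out


@dataclass(frozen=True)
class NEVolumeState:
    """Resolved non-equilibrium volume state of a wet glassy film."""

    v0_ne: float  # cm^3/g dry
    kw_ne: float  # -
    rh: float  # fraction
    ww: float  # water mass fraction
    v_ne: float  # cm^3/g of the wet mixture


def equilibrium_specific_volume(
    eos: PcSaft, T: float = 298.15, p: float = 1.0e5
) -> float:
    """Equilibrium specific volume (cm^3/g) of the pure component in ``eos``.

    Used for the API, whose glassy specific volume is taken equal to the
    equilibrium (liquid-root) value.
    """
    if eos.mixture.n != 1:
        raise ValueError("equilibrium_specific_volume expects a pure component")
    M = eos.mixture.components[0].molar_mass
    state = eos.solve_density(T, p, np.array([1.0]), "liquid")
    rho_mol_cm3 = state.number_density * 1.0e24 / NA  # mol/cm^3
    return 1.0 / (rho_mol_cm3 * M)


def dry_specific_volume(
    spec: DryASDSpec, v0_ne: Mapping[str, float]
) -> float:
    """Mass-weighted dry NE specific volume: v0 = w0a v0a + w0p v0p (cm^3/g).

    ``v0_ne`` maps component name to its pure glassy specific volume; for the
    API this is the EOS equilibrium value (see equilibrium_specific_volume).
    """
    total = 0.0
    for name, w in spec.dry_components.items():
        if name not in v0_ne:
            raise KeyError(f"missing NE specific volume for {name!r}")
        total += w * v0_ne[name]
    return total


def swelling_coefficient(
    spec: DryASDSpec, v0_ne: Mapping[str, float], kw_ne: Mapping[str, float]
) -> float:
    """Volume-weighted swelling coefficient of the dry ASD by water.

    kw = sum_i w_i (v0_i / v0) kw_i over the dry components.
    """
    v0 = dry_specific_volume(spec, v0_ne)
    total = 0.0
    for name, w in spec.dry_components.items():
        if name not in kw_ne:
            raise KeyError(f"missing swelling coefficient for {name!r}")
        total += w * (v0_ne[name] / v0) * kw_ne[name]
    return total


def ne_specific_volume(
    v0_ne: float,
    kw_ne: float,
    ww: float,
    rh: float,
    rh_exponent: float = RH_EXPONENT_DEFAULT,
) -> NEVolumeState:
    """Wet NE specific volume from the swelling relation.

    v_NE = v0_NE (1 - ww) / (1 - kw_NE RH**n), n = 2 by default.
    """
    if not 0.0 <= ww < 1.0:
        raise ValueError(f"water mass fraction {ww} outside [0, 1)")
    denom = 1.0 - kw_ne * rh**rh_exponent
    if denom <= 0.0:
        raise ValueError(
            f"swelling model out of range: 1 - kw_NE*RH^{rh_exponent:g} = "
            f"{denom:.4f} <= 0 at RH = {rh:.3f}"
        )
    v_ne = v0_ne * (1.0 - ww) / denom
    return NEVolumeState(v0_ne=v0_ne, kw_ne=kw_ne, rh=rh, ww=ww, v_ne=v_ne)


def ne_number_density(
    v_ne: float, mass_fractions: Sequence[float], molar_masses: Sequence[float]
) -> float:
    """Total number density (1/Angstrom^3) at imposed specific volume v_NE (cm^3/g)."""
    w = np.asarray(mass_fractions, dtype=float)
    M = np.asarray(molar_masses, dtype=float)
    mol_per_g = float((w / M).sum())
    return mol_per_g * NA / v_ne * 1.0e-24


def ne_ln_fugacity(
    eos: PcSaft,
    T: float,
    v_ne: float,
    mass_fractions: Sequence[float],
) -> np.ndarray:
    """Component ln fugacities at the imposed non-equilibrium volume.

    The number density is fixed by v_NE; the compressibility factor entering
    the fugacity expression is evaluated at that density, and no pressure
    match is attempted — the NET-GP pseudo-equilibrium contract.
    """
    mix: MixtureSpec = eos.mixture
    M = np.array([c.molar_mass for c in mix.components])
    rho = ne_number_density(v_ne, mass_fractions, M)
    x = mass_to_mole_fractions(np.asarray(mass_fractions, dtype=float), M)
    return eos.ln_fugacity(T, rho, x)


def select_branch(xw_eq: float, xw_ne: float) -> str:
    """EQ/NE transition rule on water *mole* fractions.

    The equilibrium description takes over once it predicts more water than
    the glassy one: EQ iff xw_eq > xw_ne; ties go to NE.
    """
    return "EQ" if xw_eq > xw_ne else "NE"
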