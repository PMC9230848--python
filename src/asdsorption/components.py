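"""Domain types: pure-component parameter records, binary interactions, mixtures.

Parameter conventions follow the usual PC-SAFT practice for polymers: the
segment number is stored as the ratio ``m_seg / M`` (mol/g) so that a polymer
pseudo-component of any molar mass can be described by a single number, and
association sites come in two flavours (electron donors and acceptors) with
integer multiplicities per molecule.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator


class PureComponent(BaseModel):
    """Pure-component PC-SAFT / NET-GP / Gordon-Taylor parameter record.

    Units follow the conventional parameter tables: segment diameter in
    Angstrom, energies divided by the Boltzmann constant in Kelvin, density in
    kg/m^3, glass-transition temperature in Kelvin.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    molar_mass: float = Field(gt=0, description="M, g/mol")
    segment_ratio: float = Field(gt=0, description="m_seg/M, mol/g")
    segment_diameter: float = Field(gt=0, description="sigma, Angstrom")
    dispersion_energy: float = Field(gt=0, description="u/kB, K")
    assoc_energy: float = Field(default=0.0, ge=0, description="eps_AiBi/kB, K")
    assoc_volume: float = Field(default=0.0, ge=0, description="kappa_AiBi, -")
    assoc_sites: Tuple[int, int] = Field(
        default=(0, 0), description="(donor, acceptor) site counts per molecule"
    )
    density: Optional[float] = Field(default=None, gt=0, description="rho_0i, kg/m^3")
    tg: Optional[float] = Field(default=None, gt=0, description="Tg_0i, K")
    gordon_taylor_k: Optional[float] = Field(default=None, gt=0, description="K_i, -")

    @model_validator(mode="after")
    def _check_segments(self) -> "PureComponent":
        if self.m_seg < 1.0:
            raise ValueError(
                f"{self.name}: segment number m_seg = {self.m_seg:.4f} < 1"
            )
        if any(n < 0 for n in self.assoc_sites):
            raise ValueError(f"{self.name}: negative association site count")
        return self

    @property
    def m_seg(self) -> float:
        """Segment number of the (pseudo-)molecule."""
        return self.segment_ratio * self.molar_mass

    @property
    def associating(self) -> bool:
        """Whether the component carries usable association sites.

        A component with sites but eps_AiBi = 0 still participates in *cross*
        association (induced association, e.g. a polymer carbonyl acceptor
        with water); it contributes nothing on its own because
        exp(0) - 1 = 0 in the association strength.
        """
        return self.assoc_volume > 0 and sum(self.assoc_sites) > 0


class BinaryInteraction(BaseModel):
    """Temperature-dependent binary correction to the dispersion energy.

    kij(T) = intercept + slope * T; a constant kij has slope 0.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    pair: Tuple[str, str]
    kij_intercept: float = 0.0
    kij_slope: float = Field(default=0.0, description="1/K")

    def kij(self, temperature: float) -> float:
        value = self.kij_intercept + self.kij_slope * temperature
        if abs(value) >= 1.0:
            raise ValueError(
                f"kij({self.pair[0]},{self.pair[1]}) = {value:.3f} at "
                f"T = {temperature:.2f} K is outside (-1, 1)"
            )
        return value

    def matches(self, a: str, b: str) -> bool:
        return {a, b} == set(self.pair)


class MixtureSpec(BaseModel):
    """Ordered component list plus the full set of binary interactions.

    Cross association parameters are generated by the Wolbach-Sandler
    combining rules inside the equation of state; only dispersion kij values
    are stored here.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    components: Tuple[PureComponent, ...]
    binaries: Tuple[BinaryInteraction, ...] = ()

    @model_validator(mode="after")
    def _check_pairs(self) -> "MixtureSpec":
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names")
        seen = set()
        for b in self.binaries:
            key = frozenset(b.pair)
            if len(key) != 2:
                raise ValueError(f"self-interaction entry {b.pair}; kii is fixed at 0")
            if key in seen:
                raise ValueError(f"duplicate binary entry for {sorted(key)}")
            seen.add(key)
        return self

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def n(self) -> int:
        return len(self.components)

    def kij_matrix(self, temperature: float) -> np.ndarray:
        """Symmetric kij matrix at the given temperature (zeros by default)."""
        n = self.n
        names = self.names
        k = np.zeros((n, n))
        for b in self.binaries:
            try:
                i = names.index(b.pair[0])
                j = names.index(b.pair[1])
            except ValueError:
                continue  # binary refers to a component not in this mixture
            k[i, j] = k[j, i] = b.kij(temperature)
        return k

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, *names: str) -> "MixtureSpec":
        """Sub-mixture restricted to the named components (order as given)."""
        comps = tuple(self.components[self.index(n)] for n in names)
        keep = set(names)
        bins = tuple(b for b in self.binaries if set(b.pair) <= keep)
        return MixtureSpec(components=comps, binaries=bins)


class PhaseState(BaseModel):
    """A homogeneous phase: temperature, number density, composition.

    ``number_density`` is in molecules per cubic Angstrom, the natural unit
    for PC-SAFT where segment diameters are in Angstrom. Pressure and
    compressibility are derived via the equation of state, not stored.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    temperature: float = Field(gt=0, description="T, K")
    number_density: float = Field(gt=0, description="rho~, 1/Angstrom^3")
    mole_fractions: Tuple[float, ...]

    @model_validator(mode="after")
    def _check_composition(self) -> "PhaseState":
        x = np.asarray(self.mole_fractions)
        if np.any(x < 0):
            raise ValueError("negative mole fraction")
        if abs(float(x.sum()) - 1.0) > 1e-8:
            raise ValueError(f"mole fractions sum to {x.sum():.10f}, not 1")
        return self

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.mole_fractions, dtype=float)


def mass_to_mole_fractions(mass_fractions: np.ndarray, molar_masses: np.ndarray) -> np.ndarray:
    """Convert mass fractions to mole fractions.

    Stable for polymer pseudo-components whose molar mass makes their mole
    fraction tiny (~1e-6): the conversion is a ratio of positive terms and
    never differences.
    """
    w = np.asarray(mass_fractions, dtype=float)
    moles = w / np.asarray(molar_masses, dtype=float)
    return moles / moles.sum()


def mole_to_mass_fractions(mole_fractions: np.ndarray, molar_masses: np.ndarray) -> np.ndarray:
    x = np.asarray(mole_fractions, dtype=float)
    mass = x * np.asarray(molar_masses, dtype=float)
    return mass / mass.sum()
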