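"""Parameter registry: load, validate and serialize the packaged parameter set.

The registry bundles the PC-SAFT pure-component records, binary interaction
parameters, NET-GP (glassy) volume parameters, Gordon-Taylor inputs and the
tabulated segmental Maxwell-Stefan diffusivities, each with a provenance
string. Unknown keys are rejected so that typos in user-supplied parameter
files fail loudly.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .components import BinaryInteraction, MixtureSpec, PureComponent

log = logging.getLogger(__name__)

__all__ = ["ParameterRegistry", "load_registry", "NonEquilibriumEntry", "MSDiffusivityTable"]


class _ProvenancedComponent(PureComponent):
    provenance: str = ""


class _ProvenancedBinary(BinaryInteraction):
    provenance: str = ""


class NonEquilibriumEntry(BaseModel):
    """NET-GP parameters of one dry component.

    ``v0_ne`` is the specific volume of the pure glassy component in cm^3/g;
    ``None`` means "take the equilibrium specific volume from the equation of
    state" (used for the API). ``kw_ne`` is the dimensionless swelling
    coefficient by water.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    v0_ne: Optional[float] = Field(default=None, gt=0)
    kw_ne: float = Field(ge=0)
    provenance: str = ""


class MSDiffusivityTable(BaseModel):
    """Nodes (Psi_w, D_seg) of the segmental Maxwell-Stefan diffusivity."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    psi: Tuple[float, ...]
    d_seg: Tuple[float, ...] = Field(description="m^2/s")
    provenance: str = ""

    @model_validator(mode="after")
    def _check_nodes(self) -> "MSDiffusivityTable":
        if len(self.psi) != len(self.d_seg) or len(self.psi) == 0:
            raise ValueError("psi and d_seg must be equal-length, non-empty")
        if np.any(np.diff(self.psi) <= 0):
            raise ValueError("psi nodes must be strictly increasing")
        if any(d <= 0 for d in self.d_seg):
            raise ValueError("diffusivities must be positive")
        return self


class FilmDefaults(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    diameter: float = Field(gt=0, description="m")
    thickness: float = Field(gt=0, description="m")
    provenance: str = ""


class ParameterRegistry(BaseModel):
    """Validated parameter set for the sorption models."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    components: Dict[str, _ProvenancedComponent]
    binaries: Tuple[_ProvenancedBinary, ...]
    ne_params: Dict[str, NonEquilibriumEntry]
    ms_tables: Dict[str, MSDiffusivityTable]
    rh_schedule: Tuple[float, ...]
    film: FilmDefaults

    @model_validator(mode="before")
    @classmethod
    def _inject_names(cls, data):
        comps = data.get("components")
        if isinstance(comps, dict):
            for name, rec in comps.items():
                if isinstance(rec, dict):
                    rec.setdefault("name", name)
        return data

    @model_validator(mode="after")
    def _validate(self) -> "ParameterRegistry":
        names = set(self.components)
        for b in self.binaries:
            if not set(b.pair) <= names:
                raise ValueError(f"binary {b.pair} refers to unknown component")
        for key in list(self.ne_params) + list(self.ms_tables):
            if key not in names:
                raise ValueError(f"parameter entry for unknown component {key!r}")
        if any(not (0 <= rh < 1) for rh in self.rh_schedule):
            raise ValueError("RH schedule entries must be in [0, 1)")
        return self

    # ------------------------------------------------------------------
    def mixture(self, *names: str) -> MixtureSpec:
        """Mixture specification for the named components, in the given order."""
        comps = []
        for n in names:
            if n not in self.components:
                raise KeyError(f"unknown component {n!r}")
            comps.append(PureComponent(**self.components[n].model_dump(exclude={"provenance"})))
        keep = set(names)
        bins = tuple(
            BinaryInteraction(**b.model_dump(exclude={"provenance"}))
            for b in self.binaries
            if set(b.pair) <= keep
        )
        return MixtureSpec(components=tuple(comps), binaries=bins)

    def to_yaml(self) -> str:
        data = self.model_dump(mode="json")
        return yaml.safe_dump(data, sort_keys=True)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_yaml())


def load_registry(path: Optional[Union[str, Path]] = None) -> ParameterRegistry:
    """Load and validate a parameter registry (packaged default if no path).

    Logs the interpretation in use for the temperature-dependent PVP-IND kij,
    whose published rendering is ambiguous (see docs/methods.md).
    """
    if path is None:
        text = resources.files("asdsorption.data").joinpath("parameters.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("parameter file must be a mapping")
    reg = ParameterRegistry(**raw)
    for b in reg.binaries:
        if b.kij_slope != 0.0:
            log.info(
                "kij(%s,%s) = %.4g %+.4g*T -> %.4f at 298.15 K",
                b.pair[0], b.pair[1], b.kij_intercept, b.kij_slope,
                b.kij(298.15),
            )
    return reg
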