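"""Water-sorption kinetics: Crank plane-sheet diffusion, Maxwell-Stefan
machinery, and full RH-step experiment prediction.

The measured mass-uptake curve of a film on an impermeable support follows
the plane-sheet series solution with an apparent Fickian diffusivity D_w.
D_w factorises as

    D_w = omega_0^2 * Gamma_w * D_seg

where omega_0^2 = (L0/L)^2 corrects the mass-fixed reference frame for film
swelling, Gamma_w = dln f_w / dln w_w removes thermodynamic non-idealities,
and D_seg is the segmental Maxwell-Stefan diffusivity of water. D_seg in an
ASD is mixed from the polymer and API values by mass-weighted friction
additivity (a harmonic mean), with both looked up at the ASD's
plasticization factor Psi_w — the free-volume coordinate on which the
water-concentration dependencies of all these systems collapse.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .components import mass_to_mole_fractions
from .glass import gordon_taylor_tg, plasticization_factor, simha_boyer_K
from .isotherm import SorptionSystem, solve_water_uptake
from .registry import MSDiffusivityTable, ParameterRegistry

log = logging.getLogger(__name__)

__all__ = [
    "FilmGeometry",
    "SorptionStep",
    "StepPrediction",
    "crank_profile",
    "crank_fractional_uptake",
    "fickian_from_ms",
    "fit_fickian_d",
    "interp_ms_diffusivity",
    "mix_ms_diffusivity",
    "predict_sorption_experiment",
    "segmental_from_molecular",
    "thermodynamic_factor",
    "system_thermodynamic_factor",
    "thickness_ratio",
    "thickness_correction",
    "gordon_taylor_tg",
    "plasticization_factor",
    "simha_boyer_K",
]

#: number of series terms; the q = 19 term is < 1e-3 of the amplitude at t = 0
CRANK_TERMS = 20

#: intermediate-composition weights for per-step constants (Vrentas rule)
WW_EVAL_START_WEIGHT = 0.3
WW_EVAL_END_WEIGHT = 0.7


@dataclass(frozen=True)
class FilmGeometry:
    """Thin circular film on an impermeable support."""

    dry_thickness: float  # L0, m
    area: float  # m^2
    dry_mass: float  # m0, g
    dry_density: float  # kg/m^3, mass-weighted from pure densities

    @classmethod
    def from_dry_mass(
        cls, dry_mass_g: float, dry_density: float, diameter: float = 14.5e-3
    ) -> "FilmGeometry":
        """Geometry from dry mass, density and circular base diameter."""
        area = math.pi * (diameter / 2.0) ** 2
        thickness = dry_mass_g / 1000.0 / (dry_density * area)
        return cls(
            dry_thickness=thickness, area=area, dry_mass=dry_mass_g, dry_density=dry_density
        )

    @classmethod
    def from_thickness(
        cls, dry_thickness: float, dry_density: float, diameter: float = 14.5e-3
    ) -> "FilmGeometry":
        area = math.pi * (diameter / 2.0) ** 2
        mass_g = dry_thickness * area * dry_density * 1000.0
        return cls(
            dry_thickness=dry_thickness, area=area, dry_mass=mass_g, dry_density=dry_density
        )


@dataclass
class SorptionStep:
    """One RH step of a sorption experiment: trace plus endpoints."""

    rh_start: float
    rh_end: float
    times: np.ndarray  # s, strictly increasing from 0
    water_mass: np.ndarray  # g, same length as times
    film: FilmGeometry
    ww_start: Optional[float] = None
    ww_end: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.water_mass = np.asarray(self.water_mass, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.water_mass):
            raise ValueError("times and water_mass must be equal-length 1-D arrays")
        if len(self.times) and (self.times[0] < 0 or np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must be strictly increasing from 0")


@dataclass(frozen=True)
class FitResult:
    """Fitted Fickian diffusivity with asymptotic uncertainty."""

    d_w: float  # m^2/s
    ci_low: float
    ci_high: float
    residual_rms: float  # relative to the step amplitude
    sigmoidal: bool  # residual pattern suggests anomalous (relaxation) sorption


@dataclass
class StepPrediction:
    """All per-step quantities of a predicted sorption step."""

    rh_start: float
    rh_end: float
    ww_start: float
    ww_end: float
    ww_eval: float
    tg: float  # K at ww_eval
    psi_w: float
    gamma_w: float
    omega0_sq: float
    d_seg_api: Optional[float]  # m^2/s
    d_seg_polymer: Optional[float]
    d_seg: float
    d_fick: float
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    water_mass: np.ndarray = field(default_factory=lambda: np.empty(0))


# ----------------------------------------------------------------------
# Crank plane-sheet kinetics
# ----------------------------------------------------------------------
def crank_fractional_uptake(tau: np.ndarray, n_terms: int = CRANK_TERMS) -> np.ndarray:
    """Fractional uptake M(t)/M_inf at dimensionless time tau = D t / L0^2.

    Plane sheet of thickness L0 with one impermeable face:
    1 - sum_q 8/((2q+1)^2 pi^2) exp(-(2q+1)^2 pi^2 tau / 4).
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    q = np.arange(n_terms)
    k = (2 * q + 1)
    coeff = 8.0 / (k**2 * math.pi**2)
    expo = -(k**2) * math.pi**2 / 4.0
    return 1.0 - (coeff[None, :] * np.exp(expo[None, :] * tau[:, None])).sum(axis=1)


def crank_profile(
    mw0: float,
    mw_inf: float,
    d_w: float,
    L0: float,
    times: Sequence[float],
    n_terms: int = CRANK_TERMS,
) -> np.ndarray:
    """Water-mass trace of one sorption step.

    m_w(t) = m_w0 + (m_w_inf - m_w0) * fractional_uptake(D t / L0^2).
    """
    if d_w <= 0 or L0 <= 0:
        raise ValueError("d_w and L0 must be positive")
    tau = d_w * np.asarray(times, dtype=float) / L0**2
    return mw0 + (mw_inf - mw0) * crank_fractional_uptake(tau, n_terms)


def fit_fickian_d(
    step: SorptionStep,
    n_terms: int = CRANK_TERMS,
    confidence_z: float = 1.96,
) -> FitResult:
    """Least-squares Fickian diffusivity from one measured sorption step.

    D_w is log-parameterised; the initial guess comes from the half-time of
    the plane-sheet solution (fractional uptake 1/2 at D t/L0^2 ~= 0.196).
    The step asymptote m_w_inf is co-fitted (started from the trace end) so
    that truncating a step at the termination criterion does not bias D_w.
    Residual diagnostics flag the sigmoidal pattern typical of
    relaxation-limited (anomalous) sorption, where a single Fickian constant
    cannot reproduce the curve shape.
    """
    t = step.times
    mw = step.water_mass
    if len(t) < 10:
        raise ValueError("need at least 10 time points to fit")
    mw0 = step.water_mass[0] if step.ww_start is None else _ww_to_mw(step.ww_start, step.film)
    mw_inf0 = step.water_mass[-1] if step.ww_end is None else _ww_to_mw(step.ww_end, step.film)
    amplitude = mw_inf0 - mw0
    if abs(amplitude) < 1e-15:
        raise ValueError("step amplitude is zero; nothing to fit")
    L0 = step.film.dry_thickness

    frac = (mw - mw0) / amplitude
    idx = np.searchsorted(frac, 0.5)
    t_half = t[min(max(idx, 1), len(t) - 1)]
    d_guess = 0.196 * L0**2 / max(t_half, t[1])

    def resid(theta: np.ndarray) -> np.ndarray:
        # theta = (log10 D, asymptote as a multiple of the trace amplitude)
        mw_inf = mw0 + theta[1] * amplitude
        model = crank_profile(mw0, mw_inf, 10.0 ** theta[0], L0, t, n_terms)
        return (model - mw) / abs(amplitude)

    sol = least_squares(resid, x0=[math.log10(d_guess), 1.0], method="lm")
    if not sol.success:
        raise RuntimeError(f"diffusivity fit did not converge: {sol.message}")
    logd = float(sol.x[0])
    d_w = 10.0**logd

    dof = max(len(t) - 2, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        sd_logd = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        sd_logd = math.inf
    ci = (10.0 ** (logd - confidence_z * sd_logd), 10.0 ** (logd + confidence_z * sd_logd))

    # sigmoidal-residual flag: early-time systematic overshoot changing sign
    r = sol.fun
    early = r[: max(len(r) // 3, 2)]
    late = r[max(len(r) // 3, 2) : 2 * len(r) // 3]
    sigmoidal = bool(
        len(early) and len(late)
        and abs(early.mean()) > 0.02
        and abs(late.mean()) > 0.005
        and np.sign(early.mean()) != np.sign(late.mean())
    )
    return FitResult(
        d_w=d_w,
        ci_low=ci[0],
        ci_high=ci[1],
        residual_rms=math.sqrt(s2),
        sigmoidal=sigmoidal,
    )


def _ww_to_mw(ww: float, film: FilmGeometry) -> float:
    """Water mass (g) in the film at water mass fraction ww (total basis)."""
    return film.dry_mass * ww / (1.0 - ww)


# ----------------------------------------------------------------------
# Maxwell-Stefan machinery
# ----------------------------------------------------------------------
def interp_ms_diffusivity(table: MSDiffusivityTable, psi: float) -> float:
    """Piecewise-linear D_seg(Psi_w); clamped (with a warning) outside the nodes."""
    psi_nodes = np.asarray(table.psi)
    d_nodes = np.asarray(table.d_seg)
    if psi < psi_nodes[0] or psi > psi_nodes[-1]:
        warnings.warn(
            f"plasticization factor {psi:.4f} outside tabulated range "
            f"[{psi_nodes[0]:.4f}, {psi_nodes[-1]:.4f}]; clamping",
            stacklevel=2,
        )
    return float(np.interp(psi, psi_nodes, d_nodes))


def segmental_from_molecular(
    d_molecular: float, ww: float, m_water: float, m_host: float
) -> float:
    """Molecular -> segmental Maxwell-Stefan diffusivity conversion.

    D_seg = D_mol * (1 - x_w) / (1 - w_w) with x_w from the molar masses.
    """
    if not 0.0 <= ww < 1.0:
        raise ValueError("ww must be in [0, 1)")
    xw = float(
        mass_to_mole_fractions(np.array([ww, 1.0 - ww]), np.array([m_water, m_host]))[0]
    )
    return d_molecular * (1.0 - xw) / (1.0 - ww)


def mix_ms_diffusivity(w0a: float, d_api: float, d_polymer: float) -> float:
    """ASD segmental diffusivity by mass-weighted friction additivity.

    1/D = w0a/D_api + (1 - w0a)/D_polymer; the result lies between the
    inputs for any drug load.
    """
    if d_api <= 0 or d_polymer <= 0:
        raise ValueError("diffusivities must be positive")
    if not 0.0 <= w0a <= 1.0:
        raise ValueError("drug load must be in [0, 1]")
    return 1.0 / (w0a / d_api + (1.0 - w0a) / d_polymer)


def thermodynamic_factor(
    ln_fw: Callable[[float], float], ww: float, rel_step: float = 1e-4
) -> float:
    """Gamma_w = d ln f_w / d ln w_w by central difference on ``ln_fw``.

    ``ln_fw`` maps water mass fraction to the log condensed-phase water
    fugacity. Near the domain edge a one-sided difference is used (warned).
    """
    h = ww * rel_step
    lo, hi = ww - h, ww + h
    if lo <= 0.0 or hi >= 1.0:
        warnings.warn("ww at domain edge; one-sided difference", stacklevel=2)
        if lo <= 0.0:
            lo, hi = ww, ww + h
        else:
            lo, hi = ww - h, ww
    dln_f = ln_fw(hi) - ln_fw(lo)
    dln_w = math.log(hi) - math.log(lo)
    return dln_f / dln_w


def system_thermodynamic_factor(
    system: SorptionSystem,
    T: float,
    ww: float,
    branch: str,
    rh: float,
    rel_step: float = 1e-4,
) -> float:
    """Gamma_w for a water/matrix system on the given EQ/NE branch.

    On the NE branch the imposed glassy volume is evaluated at the step's
    target RH; on the EQ branch the density is re-solved at the water
    partial pressure of that RH.
    """
    if branch == "NE":
        ln_fw = lambda w: system.ln_fw_ne(T, rh, w)
    elif branch == "EQ":
        psat, _, _ = system.water_eos.saturation_pressure(T)
        pw = psat * rh
        ln_fw = lambda w: system.ln_fw_eq(T, pw, w)
    else:
        raise ValueError(f"unknown branch {branch!r}")
    return thermodynamic_factor(ln_fw, ww, rel_step)


def thickness_ratio(dry_density: float, ww: float, water_density: float = 997.0) -> float:
    """Swollen-to-dry thickness ratio L/L0 from volume additivity."""
    if not 0.0 <= ww < 1.0:
        raise ValueError("ww must be in [0, 1)")
    return 1.0 + ww / (1.0 - ww) * dry_density / water_density


def thickness_correction(
    film: FilmGeometry,
    ww: float,
    water_density: float = 997.0,
    flux_reduction: bool = True,
) -> float:
    """Reference-frame factor omega_0^2 = (L0/L)^2 <= 1.

    ``flux_reduction=False`` returns the reciprocal (L/L0)^2 for sensitivity
    checks against the alternative reading of the correction.
    """
    ratio = thickness_ratio(film.dry_density, ww, water_density)
    return ratio**2 if not flux_reduction else ratio**-2


def fickian_from_ms(omega0_sq: float, gamma_w: float, d_seg: float) -> float:
    """Apparent Fickian diffusivity D_w = omega_0^2 * Gamma_w * D_seg."""
    if min(omega0_sq, gamma_w, d_seg) <= 0:
        raise ValueError("all factors must be positive")
    return omega0_sq * gamma_w * d_seg


# ----------------------------------------------------------------------
# full-experiment prediction
# ----------------------------------------------------------------------
def predict_sorption_experiment(
    system: SorptionSystem,
    T: float,
    rh_schedule: Sequence[float],
    film: FilmGeometry,
    registry: Optional[ParameterRegistry] = None,
    step_duration: Optional[Callable[[StepPrediction], float]] = None,
    sampling_interval: float = 60.0,
    flux_reduction: bool = True,
) -> List[StepPrediction]:
    """Predict a complete RH-step sorption experiment from parameters alone.

    Per step: endpoints from the isotherm, per-step constants frozen at the
    intermediate composition ww_eval = 0.3 ww0 + 0.7 ww_inf, segmental
    diffusivities interpolated at the plasticization factor and mixed by
    friction additivity, then the Crank profile with the resulting Fickian
    diffusivity. Step failures are logged and the remaining steps still run.
    """
    registry = registry if registry is not None else system.registry
    spec = system.spec
    predictions: List[StepPrediction] = []
    rh_prev = 0.0
    ww_prev = 0.0
    for i, rh in enumerate(rh_schedule):
        try:
            pred = _predict_step(
                system, T, rh_prev, rh, ww_prev, film, registry, flux_reduction
            )
        except Exception as exc:  # keep going; later steps may still work
            log.error("step %d (RH %.3f -> %.3f) failed: %s", i, rh_prev, rh, exc)
            rh_prev = rh
            continue
        duration = (
            step_duration(pred)
            if step_duration is not None
            else _default_step_duration(pred, film)
        )
        times = np.arange(0.0, duration + sampling_interval, sampling_interval)
        pred.times = times
        pred.water_mass = crank_profile(
            _ww_to_mw(pred.ww_start, film),
            _ww_to_mw(pred.ww_end, film),
            pred.d_fick,
            film.dry_thickness,
            times,
        )
        predictions.append(pred)
        rh_prev, ww_prev = rh, pred.ww_end
    return predictions


def _predict_step(
    system: SorptionSystem,
    T: float,
    rh_start: float,
    rh_end: float,
    ww_start: float,
    film: FilmGeometry,
    registry: ParameterRegistry,
    flux_reduction: bool,
) -> StepPrediction:
    spec = system.spec
    if rh_end == rh_start == 0.0:
        return StepPrediction(
            rh_start=0.0, rh_end=0.0, ww_start=0.0, ww_end=0.0, ww_eval=0.0,
            tg=system.tg_dry, psi_w=0.0, gamma_w=1.0, omega0_sq=1.0,
            d_seg_api=None, d_seg_polymer=None, d_seg=1e-15, d_fick=1e-15,
        )
    point = solve_water_uptake(system, T, rh_end)
    ww_end = point.ww
    ww_eval = WW_EVAL_START_WEIGHT * ww_start + WW_EVAL_END_WEIGHT * ww_end

    tg_wet = system.tg(ww_eval)
    psi = plasticization_factor(system.tg_dry, tg_wet, T)

    d_api = d_pol = None
    if spec.api and spec.drug_load > 0:
        d_api = interp_ms_diffusivity(registry.ms_tables[spec.api], psi)
    if spec.polymer and spec.polymer_load > 0:
        d_pol = interp_ms_diffusivity(registry.ms_tables[spec.polymer], psi)
    if d_api is not None and d_pol is not None:
        d_seg = mix_ms_diffusivity(spec.drug_load, d_api, d_pol)
    else:
        d_seg = d_api if d_api is not None else d_pol

    gamma = system_thermodynamic_factor(system, T, ww_eval, point.branch, rh_end)
    omega0_sq = thickness_correction(film, ww_eval, flux_reduction=flux_reduction)
    d_fick = fickian_from_ms(omega0_sq, gamma, d_seg)
    return StepPrediction(
        rh_start=rh_start, rh_end=rh_end, ww_start=ww_start, ww_end=ww_end,
        ww_eval=ww_eval, tg=tg_wet, psi_w=psi, gamma_w=gamma,
        omega0_sq=omega0_sq, d_seg_api=d_api, d_seg_polymer=d_pol,
        d_seg=d_seg, d_fick=d_fick,
    )


def _default_step_duration(pred: StepPrediction, film: FilmGeometry) -> float:
    """Duration reaching ~99.9% of the step amplitude (tau ~= 2.8)."""
    return 2.8 * film.dry_thickness**2 / pred.d_fick
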