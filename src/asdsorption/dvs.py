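"""DVS trace exchange format and a synthetic sorption-experiment generator.

The canonical CSV dialect has a header row and the comma-separated columns
``time_s, mass_mg, target_RH, measured_RH`` (UTF-8). A trace starts with a
drying segment at near-zero RH from which the dry mass is inferred, followed
by RH steps; each step becomes one :class:`~asdsorption.kinetics.SorptionStep`.

The generator emulates a gravimetric step experiment: Crank kinetics per
step, Gaussian mass noise scaled to the step amplitude (the balance noise of
a microbalance is at the sub-microgram level), and automatic step
termination on a mass-change-rate criterion (default 1e-4 wt%/min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .kinetics import FilmGeometry, SorptionStep, crank_profile

__all__ = [
    "SyntheticExperimentSpec",
    "StepGroundTruth",
    "read_dvs_trace",
    "generate_experiment",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = ["time_s", "mass_mg", "target_RH", "measured_RH"]

#: default termination threshold of the step, wt%/min
TERMINATION_WT_PCT_PER_MIN = 1e-4

#: RH of the drying segment (effectively dry nitrogen)
DRYING_RH = 1e-5

#: points averaged over the end of the drying plateau for the dry mass
DRY_PLATEAU_POINTS = 10


@dataclass(frozen=True)
class StepGroundTruth:
    """Per-step ground truth emitted alongside a synthetic trace."""

    rh_start: float
    rh_end: float
    ww_start: float
    ww_end: float
    d_w: float  # m^2/s


@dataclass
class SyntheticExperimentSpec:
    """Specification of one synthetic RH-step sorption experiment."""

    rh_schedule: Sequence[float]
    film: FilmGeometry
    ww_end: Sequence[float]  # endpoint water mass fraction per step
    d_w: Sequence[float]  # true Fickian diffusivity per step, m^2/s
    noise_sigma: float = 0.0  # Gaussian noise, relative to step amplitude
    seed: Optional[int] = None
    sampling_interval: float = 60.0  # s
    termination_rate: float = TERMINATION_WT_PCT_PER_MIN  # wt%/min
    drying_duration: float = 1800.0  # s
    max_tau: float = 12.0  # hard cap on dimensionless step duration
    n_terms: int = 200  # series terms; generous so the emulated truth is converged

    def __post_init__(self) -> None:
        n = len(self.rh_schedule)
        if len(self.ww_end) != n or len(self.d_w) != n:
            raise ValueError("rh_schedule, ww_end and d_w must be equal length")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.noise_sigma > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise is requested")
        if any(not 0 <= rh < 1 for rh in self.rh_schedule):
            raise ValueError("RH values must be in [0, 1)")
        if any(not 0 <= w < 1 for w in self.ww_end):
            raise ValueError("ww endpoints must be in [0, 1)")
        if any(d <= 0 for d in self.d_w):
            raise ValueError("diffusivities must be positive")


def _ww_to_mw(ww: float, film: FilmGeometry) -> float:
    return film.dry_mass * ww / (1.0 - ww)


def generate_experiment(
    spec: SyntheticExperimentSpec,
    path: Optional[Union[str, Path]] = None,
) -> Tuple[pd.DataFrame, List[StepGroundTruth]]:
    """Stitched multi-step synthetic DVS trace plus its ground truth.

    Each step runs until the smoothed mass-change rate drops below the
    termination threshold (minimum 10 samples, capped at ``max_tau`` in
    dimensionless time); the drying stub preceding the first step sits flat
    at the dry mass so readers can recover it from the plateau.
    """
    rng = np.random.default_rng(spec.seed)
    film = spec.film
    m0 = film.dry_mass  # g
    rows: List[pd.DataFrame] = []
    truths: List[StepGroundTruth] = []

    t_global = 0.0
    n_dry = max(int(spec.drying_duration // spec.sampling_interval) + 1, DRY_PLATEAU_POINTS)
    t_dry = t_global + np.arange(n_dry) * spec.sampling_interval
    dry_mass = np.full(n_dry, m0)
    if spec.noise_sigma > 0:
        dry_mass = dry_mass + spec.noise_sigma * 1e-6 * rng.standard_normal(n_dry)
    rows.append(
        pd.DataFrame(
            {
                "time_s": t_dry,
                "mass_mg": dry_mass * 1000.0,
                "target_RH": DRYING_RH,
                "measured_RH": DRYING_RH,
            }
        )
    )
    t_global = t_dry[-1] + spec.sampling_interval

    ww_prev = 0.0
    rh_prev = DRYING_RH
    for rh, ww_inf, d_w in zip(spec.rh_schedule, spec.ww_end, spec.d_w):
        mw0 = _ww_to_mw(ww_prev, film)
        mw_inf = _ww_to_mw(ww_inf, film)
        times = _terminated_times(spec, film, mw0, mw_inf, d_w)
        mw = crank_profile(mw0, mw_inf, d_w, film.dry_thickness, times, spec.n_terms)
        if spec.noise_sigma > 0:
            mw = mw + spec.noise_sigma * abs(mw_inf - mw0) * rng.standard_normal(len(mw))
        rows.append(
            pd.DataFrame(
                {
                    "time_s": t_global + times,
                    "mass_mg": (m0 + mw) * 1000.0,
                    "target_RH": rh,
                    "measured_RH": rh,
                }
            )
        )
        truths.append(
            StepGroundTruth(
                rh_start=rh_prev, rh_end=rh, ww_start=ww_prev, ww_end=ww_inf, d_w=d_w
            )
        )
        t_global += times[-1] + spec.sampling_interval
        ww_prev, rh_prev = ww_inf, rh

    trace = pd.concat(rows, ignore_index=True)
    if path is not None:
        trace.to_csv(path, index=False, float_format="%.10g")
    return trace, truths


def _terminated_times(
    spec: SyntheticExperimentSpec,
    film: FilmGeometry,
    mw0: float,
    mw_inf: float,
    d_w: float,
) -> np.ndarray:
    """Sample times of one step, cut by the mass-change-rate criterion."""
    L0 = film.dry_thickness
    t_max = spec.max_tau * L0**2 / d_w
    times = np.arange(0.0, t_max + spec.sampling_interval, spec.sampling_interval)
    mw = crank_profile(mw0, mw_inf, d_w, L0, times, spec.n_terms)
    wt_pct = 100.0 * mw / (film.dry_mass + mw)
    # smoothed rate over a 5-sample window, wt% per minute
    window = 5
    for i in range(max(window, 10), len(times)):
        seg_t = times[i - window : i + 1]
        seg_w = wt_pct[i - window : i + 1]
        rate = abs(np.polyfit(seg_t, seg_w, 1)[0]) * 60.0
        if rate < spec.termination_rate:
            return times[: i + 1]
    return times


def read_dvs_trace(
    path: Union[str, Path],
    dry_density: float,
    diameter: float = 14.5e-3,
) -> List[SorptionStep]:
    """Parse a DVS CSV trace into per-step sorption records.

    The dry mass is the mean of the last few points of the drying plateau
    (the leading segment at near-zero target RH); the trace is split at
    every change of the target RH.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace is missing required columns: {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_s must be strictly increasing")

    # contiguous segments of constant target RH
    target = df["target_RH"].to_numpy(dtype=float)
    boundaries = np.flatnonzero(np.diff(target) != 0) + 1
    segments = np.split(np.arange(len(df)), boundaries)

    first = segments[0]
    if target[first[0]] > 1e-3:
        raise ValueError("trace must start with a drying segment at near-zero RH")
    mass_g = df["mass_mg"].to_numpy(dtype=float) / 1000.0
    m0 = float(mass_g[first][-DRY_PLATEAU_POINTS:].mean())
    film = FilmGeometry.from_dry_mass(m0, dry_density, diameter)

    steps: List[SorptionStep] = []
    rh_prev = float(target[first[0]])
    for seg in segments[1:]:
        rh = float(target[seg[0]])
        times = t[seg] - t[seg[0]]
        mw = mass_g[seg] - m0
        ww_end = float(mw[-1] / (m0 + mw[-1]))
        ww_start = float(mw[0] / (m0 + mw[0]))
        steps.append(
            SorptionStep(
                rh_start=rh_prev,
                rh_end=rh,
                times=times,
                water_mass=mw,
                film=film,
                ww_start=ww_start,
                ww_end=ww_end,
            )
        )
        rh_prev = rh
    return steps
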