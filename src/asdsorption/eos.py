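"""PC-SAFT equation of state with association, for polymer/API/water mixtures.

The residual Helmholtz energy a_res = a_hc + a_disp + a_assoc is the standard
perturbed-chain form (hard-chain reference with the Boublik-Mansoori
hard-sphere mixture term, second-order dispersion with the universal model
constants, and a donor/acceptor association term with Wolbach-Sandler
combining rules for the cross parameters).

Analytic first derivatives of a_res with respect to number density and the
(unconstrained) mole fractions are carried alongside the energy itself; the
association contribution uses the stationarity of the Michelsen-Hendriks
Q-function so that site fractions can be held fixed while differentiating.

Internal units: temperature in K, number density in molecules/Angstrom^3,
energies reduced by kB. Pressures at the interface are in Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .components import MixtureSpec, PhaseState
from .constants import ANGSTROM3_TO_M3, KB

__all__ = [
    "PcSaft",
    "HelmholtzResult",
    "reduced_residual_helmholtz",
    "compressibility",
    "ln_fugacity",
    "solve_density",
    "saturation_pressure",
    "EosError",
    "AssociationError",
    "DensityRootError",
]

# Universal dispersion-integral constants a_0i..a_2i, b_0i..b_2i.
_A = np.array(
    [
        [0.9105631445, -0.3084016918, -0.0906148351],
        [0.6361281449, 0.1860531159, 0.4527842806],
        [2.6861347891, -2.5030047259, 0.5962700728],
        [-26.547362491, 21.419793629, -1.7241829131],
        [97.759208784, -65.255885330, -4.1302112531],
        [-159.59154087, 83.318680481, 13.776631870],
        [91.297774084, -33.746922930, -8.6728470368],
    ]
)
_B = np.array(
    [
        [0.7240946941, -0.5755498075, 0.0976883116],
        [2.2382791861, 0.6995095521, -0.2557574982],
        [-4.0025849485, 3.8925673390, -9.1558561530],
        [-21.003576815, -17.215471648, 20.642075974],
        [26.855641363, 192.67226447, -38.804430052],
        [206.55133841, -161.82646165, 93.626774077],
        [-355.60235612, -165.20769346, -29.666905585],
    ]
)

_MAX_PACKING = 0.7405  # close-packing bound on the packing fraction eta


class EosError(RuntimeError):
    """Base class for equation-of-state failures."""


class AssociationError(EosError):
    """The association site-fraction iteration did not converge."""


class DensityRootError(EosError):
    """No density root (or only a trivial one) in the physical bracket."""


@dataclass
class HelmholtzResult:
    """Reduced residual Helmholtz energy with term breakdown and derivatives."""

    ares: float
    hc: float
    disp: float
    assoc: float
    dares_drho: float  # d a_res / d rho~ at constant T, x
    dares_dx: np.ndarray  # unconstrained d a_res / d x_k at constant T, rho~
    site_fractions: Optional[np.ndarray] = None  # (n, 2): acceptor, donor


@dataclass
class _Workspace:
    """Temperature-dependent parameter tables for one mixture."""

    T: float
    m: np.ndarray
    d: np.ndarray  # temperature-dependent segment diameter
    sigma_ij: np.ndarray
    uij_over_T: np.ndarray
    eps_cross: np.ndarray  # eps_AiBj / kB
    kappa_cross: np.ndarray
    n_donor: np.ndarray
    n_acceptor: np.ndarray
    assoc_active: bool = field(default=False)


class PcSaft:
    """PC-SAFT evaluator bound to a mixture specification.

    Workspaces (temperature-dependent parameter tables) are cached per
    temperature; association site fractions are warm-started between calls at
    the same conditions to speed up nested solvers.
    """

    #: successive-substitution settings for the association site fractions
    assoc_tol: float = 1e-12
    assoc_max_iter: int = 500

    def __init__(self, mixture: MixtureSpec):
        self.mixture = mixture
        self._ws_cache: dict[float, _Workspace] = {}
        self._assoc_warm: Optional[tuple[np.ndarray, np.ndarray]] = None
        self._psat_cache: dict[float, tuple[float, float, float]] = {}

    # ------------------------------------------------------------------
    # parameter tables
    # ------------------------------------------------------------------
    def _workspace(self, T: float) -> _Workspace:
        ws = self._ws_cache.get(T)
        if ws is not None:
            return ws
        comps = self.mixture.components
        m = np.array([c.m_seg for c in comps])
        sigma = np.array([c.segment_diameter for c in comps])
        u = np.array([c.dispersion_energy for c in comps])
        eps = np.array([c.assoc_energy for c in comps])
        kap = np.array([c.assoc_volume for c in comps])
        nd = np.array([c.assoc_sites[0] for c in comps], dtype=float)
        na = np.array([c.assoc_sites[1] for c in comps], dtype=float)

        d = sigma * (1.0 - 0.12 * np.exp(-3.0 * u / T))
        sigma_ij = 0.5 * (sigma[:, None] + sigma[None, :])
        kij = self.mixture.kij_matrix(T)
        uij = np.sqrt(u[:, None] * u[None, :]) * (1.0 - kij)

        # Wolbach-Sandler combining rules for the cross association
        eps_cross = 0.5 * (eps[:, None] + eps[None, :])
        kappa_cross = np.sqrt(kap[:, None] * kap[None, :]) * (
            np.sqrt(sigma[:, None] * sigma[None, :]) / sigma_ij
        ) ** 3
        # components without sites or without assoc volume never associate
        has_sites = ((nd + na) > 0) & (kap > 0)
        mask = has_sites[:, None] & has_sites[None, :]
        kappa_cross = np.where(mask, kappa_cross, 0.0)

        ws = _Workspace(
            T=T,
            m=m,
            d=d,
            sigma_ij=sigma_ij,
            uij_over_T=uij / T,
            eps_cross=eps_cross,
            kappa_cross=kappa_cross,
            n_donor=nd,
            n_acceptor=na,
            assoc_active=bool(np.any(kappa_cross * (np.exp(eps_cross / T) - 1.0) > 0)),
        )
        if len(self._ws_cache) > 64:
            self._ws_cache.clear()
        self._ws_cache[T] = ws
        return ws

    # ------------------------------------------------------------------
    # residual Helmholtz energy and derivatives
    # ------------------------------------------------------------------
    def helmholtz(self, T: float, rho: float, x: Sequence[float]) -> HelmholtzResult:
        """a_res(T, rho~, x) with the hc/disp/assoc breakdown and derivatives.

        ``rho`` is the total number density in molecules/Angstrom^3; ``x`` are
        mole fractions (need not sum exactly to one for derivative probes).
        """
        ws = self._workspace(T)
        x = np.asarray(x, dtype=float)
        if rho <= 0:
            raise EosError("number density must be positive")
        m, d = ws.m, ws.d

        # packing fractions zeta_0..zeta_3
        dn = d[None, :] ** np.arange(4)[:, None]  # (4, n)
        zeta = (math.pi / 6.0) * rho * dn @ (x * m)  # (4,)
        eta = zeta[3]
        if eta >= _MAX_PACKING:
            raise EosError(f"packing fraction eta = {eta:.4f} exceeds close packing")
        dzeta_dx = (math.pi / 6.0) * rho * (m[None, :] * dn)  # (4, n)
        dzeta_drho = zeta / rho

        z0, z1, z2, z3 = zeta
        e = 1.0 - z3
        ln_e = math.log(e)

        # --- hard-sphere / hard-chain -----------------------------------
        ahs = (
            3.0 * z1 * z2 / e
            + z2**3 / (z3 * e**2)
            + (z2**3 / z3**2 - z0) * ln_e
        ) / z0
        dahs = np.empty(4)
        dahs[0] = (-ahs - ln_e) / z0
        dahs[1] = 3.0 * z2 / (e * z0)
        dahs[2] = (
            3.0 * z1 / e + 3.0 * z2**2 / (z3 * e**2) + 3.0 * z2**2 / z3**2 * ln_e
        ) / z0
        dahs[3] = (
            3.0 * z1 * z2 / e**2
            + z2**3 * (2.0 / (z3 * e**3) - 1.0 / (z3**2 * e**2))
            - 2.0 * z2**3 / z3**3 * ln_e
            + (z0 - z2**3 / z3**2) / e
        ) / z0

        dd = d[:, None] * d[None, :] / (d[:, None] + d[None, :])  # d_i d_j/(d_i+d_j)
        g = 1.0 / e + dd * 3.0 * z2 / e**2 + dd**2 * 2.0 * z2**2 / e**3
        dg_dz2 = 3.0 * dd / e**2 + 4.0 * dd**2 * z2 / e**3
        dg_dz3 = 1.0 / e**2 + 6.0 * dd * z2 / e**3 + 6.0 * dd**2 * z2**2 / e**4

        mbar = float(x @ m)
        gii = np.diag(g)
        ahc = mbar * ahs - float(x @ ((m - 1.0) * np.log(gii)))

        # chain-term derivative wrt each zeta_n
        dahc_dzeta = mbar * dahs
        wchain = x * (m - 1.0) / gii
        dahc_dzeta[2] -= float(wchain @ np.diag(dg_dz2))
        dahc_dzeta[3] -= float(wchain @ np.diag(dg_dz3))

        dahc_drho = float(dahc_dzeta @ dzeta_drho)
        dahc_dx = (
            m * ahs
            - (m - 1.0) * np.log(gii)
            + dzeta_dx.T @ dahc_dzeta
        )

        # --- dispersion --------------------------------------------------
        powers = eta ** np.arange(7)
        dpowers = np.arange(7) * eta ** np.array([0, 0, 1, 2, 3, 4, 5])
        f1 = (mbar - 1.0) / mbar
        f2 = f1 * (mbar - 2.0) / mbar
        avec = _A[:, 0] + f1 * _A[:, 1] + f2 * _A[:, 2]
        bvec = _B[:, 0] + f1 * _B[:, 1] + f2 * _B[:, 2]
        da_dm = _A[:, 1] / mbar**2 + _A[:, 2] * (3.0 / mbar**2 - 4.0 / mbar**3)
        db_dm = _B[:, 1] / mbar**2 + _B[:, 2] * (3.0 / mbar**2 - 4.0 / mbar**3)
        I1 = float(avec @ powers)
        I2 = float(bvec @ powers)
        I1e = float(avec @ dpowers)  # dI1/deta
        I2e = float(bvec @ dpowers)

        s3 = ws.sigma_ij**3
        E1 = ws.uij_over_T * s3  # (u_ij/kT) sigma_ij^3
        E2 = ws.uij_over_T**2 * s3
        mm = m[:, None] * m[None, :]
        m2es3 = float((x[:, None] * x[None, :] * mm * E1).sum())
        m2e2s3 = float((x[:, None] * x[None, :] * mm * E2).sum())

        h1 = (8.0 * eta - 2.0 * eta**2) / e**4
        h2 = (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4) / (
            (e * (2.0 - eta)) ** 2
        )
        C1 = 1.0 / (1.0 + mbar * h1 + (1.0 - mbar) * h2)
        C2 = -(C1**2) * (
            mbar * (-4.0 * eta**2 + 20.0 * eta + 8.0) / e**5
            + (1.0 - mbar)
            * (2.0 * eta**3 + 12.0 * eta**2 - 48.0 * eta + 40.0)
            / (e * (2.0 - eta)) ** 3
        )

        adisp = -2.0 * math.pi * rho * I1 * m2es3 - math.pi * rho * mbar * C1 * I2 * m2e2s3

        deta_drho = eta / rho
        dadisp_drho = (
            adisp / rho
            - 2.0 * math.pi * rho * I1e * deta_drho * m2es3
            - math.pi * rho * mbar * (C2 * I2 + C1 * I2e) * deta_drho * m2e2s3
        )

        deta_dx = dzeta_dx[3]
        dm2es3_dx = 2.0 * m * ((x * m) @ E1)
        dm2e2s3_dx = 2.0 * m * ((x * m) @ E2)
        sum_da = float(da_dm @ powers)
        sum_db = float(db_dm @ powers)
        dI1_dx = I1e * deta_dx + sum_da * m
        dI2_dx = I2e * deta_dx + sum_db * m
        dC1_dx = C2 * deta_dx - C1**2 * (h1 - h2) * m
        dadisp_dx = (
            -2.0 * math.pi * rho * (dI1_dx * m2es3 + I1 * dm2es3_dx)
            - math.pi
            * rho
            * (m * C1 * I2 + mbar * dC1_dx * I2 + mbar * C1 * dI2_dx)
            * m2e2s3
            - math.pi * rho * mbar * C1 * I2 * dm2e2s3_dx
        )

        # --- association -------------------------------------------------
        if ws.assoc_active:
            strength = ws.kappa_cross * (np.exp(ws.eps_cross / T) - 1.0) * s3
            delta = strength * g  # (n, n) symmetric, Angstrom^3
            XA, XD = self._solve_site_fractions(rho, x, ws, delta)
            na, nd = ws.n_acceptor, ws.n_donor
            aassoc = float(
                x
                @ (
                    na * (np.log(np.where(na > 0, XA, 1.0)) - XA / 2.0 + 0.5)
                    + nd * (np.log(np.where(nd > 0, XD, 1.0)) - XD / 2.0 + 0.5)
                )
            )
            # pairing weights P_ij = nA_i nD_j XA_i XD_j + nD_i nA_j XD_i XA_j
            P = (na * XA)[:, None] * (nd * XD)[None, :] + (nd * XD)[:, None] * (
                na * XA
            )[None, :]
            xx = x[:, None] * x[None, :]
            ddelta_dzeta2 = strength * dg_dz2
            ddelta_dzeta3 = strength * dg_dz3
            ddelta_drho = (
                ddelta_dzeta2 * dzeta_drho[2] + ddelta_dzeta3 * dzeta_drho[3]
            )
            daassoc_drho = -0.5 * float((xx * P * (delta + rho * ddelta_drho)).sum())
            # explicit composition dependence (fixed site fractions)
            lnXA = np.log(np.where(na > 0, XA, 1.0))
            lnXD = np.log(np.where(nd > 0, XD, 1.0))
            own = na * (lnXA - XA + 1.0) + nd * (lnXD - XD + 1.0)
            pair_term = rho * (x[None, :] * P * delta).sum(axis=1)
            S2 = float((xx * P * ddelta_dzeta2).sum())
            S3 = float((xx * P * ddelta_dzeta3).sum())
            g_term = 0.5 * rho * (S2 * dzeta_dx[2] + S3 * dzeta_dx[3])
            daassoc_dx = own - pair_term - g_term
            site_fractions = np.stack([XA, XD], axis=1)
        else:
            aassoc = 0.0
            daassoc_drho = 0.0
            daassoc_dx = np.zeros_like(x)
            site_fractions = None

        ares = ahc + adisp + aassoc
        return HelmholtzResult(
            ares=ares,
            hc=ahc,
            disp=adisp,
            assoc=aassoc,
            dares_drho=dahc_drho + dadisp_drho + daassoc_drho,
            dares_dx=dahc_dx + dadisp_dx + daassoc_dx,
            site_fractions=site_fractions,
        )

    def _solve_site_fractions(
        self, rho: float, x: np.ndarray, ws: _Workspace, delta: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Site fractions by damped successive substitution + Newton polish.

        X_A(i) = 1 / (1 + rho sum_j x_j nD_j X_D(j) Delta_ij) and the mirror
        equation for donors; tolerance 1e-12 on the max update. A short damped
        substitution phase provides a safe starting point (warm-started from
        the previous call when available), then Newton converges the coupled
        system quadratically.
        """
        n = len(x)
        warm = self._assoc_warm
        if warm is not None and warm[0].shape == (n,):
            XA, XD = warm[0].copy(), warm[1].copy()
        else:
            XA = np.full(n, 0.2)
            XD = np.full(n, 0.2)
        nd, na = ws.n_donor, ws.n_acceptor
        wD = rho * delta * (x * nd)[None, :]  # XA_i residual couples to XD_j
        wA = rho * delta * (x * na)[None, :]
        damp = 0.5
        err = math.inf
        for it in range(self.assoc_max_iter):
            XA_new = 1.0 / (1.0 + wD @ XD)
            XD_new = 1.0 / (1.0 + wA @ XA)
            err = max(np.abs(XA_new - XA).max(), np.abs(XD_new - XD).max())
            XA = damp * XA_new + (1.0 - damp) * XA
            XD = damp * XD_new + (1.0 - damp) * XD
            if err < self.assoc_tol:
                self._assoc_warm = (XA.copy(), XD.copy())
                return XA, XD
            if it >= 4 and err < 1e-2:
                sol = self._newton_site_fractions(XA, XD, wA, wD)
                if sol is not None:
                    self._assoc_warm = (sol[0].copy(), sol[1].copy())
                    return sol
        raise AssociationError(
            f"association site fractions not converged to {self.assoc_tol:g} "
            f"in {self.assoc_max_iter} iterations (last update {err:.2e})"
        )

    def _newton_site_fractions(self, XA, XD, wA, wD):
        """Newton iteration on G_A = XA*(1 + wD@XD) - 1, G_D mirrored."""
        n = len(XA)
        for _ in range(30):
            gA = XA * (1.0 + wD @ XD) - 1.0
            gD = XD * (1.0 + wA @ XA) - 1.0
            J = np.zeros((2 * n, 2 * n))
            J[:n, :n] = np.diag(1.0 + wD @ XD)
            J[:n, n:] = XA[:, None] * wD
            J[n:, n:] = np.diag(1.0 + wA @ XA)
            J[n:, :n] = XD[:, None] * wA
            try:
                step = np.linalg.solve(J, np.concatenate([gA, gD]))
            except np.linalg.LinAlgError:
                return None
            XA_new = np.clip(XA - step[:n], 1e-14, 1.0)
            XD_new = np.clip(XD - step[n:], 1e-14, 1.0)
            err = max(np.abs(XA_new - XA).max(), np.abs(XD_new - XD).max())
            XA, XD = XA_new, XD_new
            if err < self.assoc_tol:
                return XA, XD
        return None

    # ------------------------------------------------------------------
    # derived thermodynamic quantities
    # ------------------------------------------------------------------
    def compressibility(self, T: float, rho: float, x: Sequence[float]) -> float:
        """Z = 1 + rho~ * d a_res/d rho~ at constant T, x."""
        res = self.helmholtz(T, rho, x)
        return 1.0 + rho * res.dares_drho

    def pressure(self, T: float, rho: float, x: Sequence[float]) -> float:
        """p = Z rho~ kB T in Pa (rho~ in 1/Angstrom^3)."""
        Z = self.compressibility(T, rho, x)
        return Z * rho * ANGSTROM3_TO_M3 * KB * T

    def ln_fugacity(self, T: float, rho: float, x: Sequence[float]) -> np.ndarray:
        """Component ln f_i with f_i in Pa.

        ln f_i = a_res + da/dx_i - sum_j x_j da/dx_j + (Z - 1)
                 + ln(rho~ x_i kB T); components with x_i = 0 get -inf.
        """
        x = np.asarray(x, dtype=float)
        res = self.helmholtz(T, rho, x)
        Z = 1.0 + rho * res.dares_drho
        mu_res = res.ares + res.dares_dx - float(x @ res.dares_dx) + (Z - 1.0)
        with np.errstate(divide="ignore"):
            ideal = np.log(rho * ANGSTROM3_TO_M3 * x * KB * T)
        return mu_res + ideal

    # ------------------------------------------------------------------
    # solvers
    # ------------------------------------------------------------------
    def _eta_to_rho(self, T: float, x: np.ndarray, eta: float) -> float:
        ws = self._workspace(T)
        md3 = float((x * ws.m) @ ws.d**3)
        return 6.0 * eta / (math.pi * md3)

    def solve_density(
        self,
        T: float,
        p: float,
        x: Sequence[float],
        phase_hint: Optional[str] = None,
        n_scan: int = 160,
    ) -> PhaseState:
        """Density root of p(rho~) = p, selected by phase hint or Gibbs energy.

        The pressure curve is scanned on a log grid of packing fractions in
        (1e-12, 0.74); each bracketed sign change is refined with Brent's
        method to 1e-10 relative in rho~.
        """
        if p <= 0:
            raise ValueError("pressure must be positive")
        if phase_hint not in (None, "liquid", "vapor"):
            raise ValueError(f"unknown phase hint {phase_hint!r}")
        x = np.asarray(x, dtype=float)
        etas = np.logspace(-12, math.log10(0.74), n_scan)
        rhos = self._eta_to_rho(T, x, etas)

        def f(rho: float) -> float:
            return self.pressure(T, rho, x) - p

        def refine(i: int, vi: float, vj: float) -> float:
            if vi == 0.0:
                return rhos[i]
            return brentq(f, rhos[i], rhos[i + 1], xtol=1e-300, rtol=1e-15)

        roots: list[float] = []
        if phase_hint == "vapor":
            # walk up in density; the first crossing is the vapor root
            vi = f(rhos[0])
            for i in range(len(rhos) - 1):
                vj = f(rhos[i + 1])
                if vi == 0.0 or vi * vj < 0:
                    roots.append(refine(i, vi, vj))
                    break
                vi = vj
        elif phase_hint == "liquid":
            # walk down in density; the first crossing is the liquid root
            vj = f(rhos[-1])
            for i in range(len(rhos) - 2, -1, -1):
                vi = f(rhos[i])
                if vj == 0.0 or vi * vj < 0:
                    roots.append(refine(i, vi, vj))
                    break
                vj = vi
        else:
            vals = np.array([f(r) for r in rhos])
            for i in range(len(rhos) - 1):
                if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
                    roots.append(refine(i, vals[i], vals[i + 1]))
        if not roots:
            raise DensityRootError(
                f"no density root at T={T} K, p={p:.6g} Pa for phase "
                f"{phase_hint or 'any'} in the packing-fraction bracket"
            )
        roots = sorted(roots)
        if phase_hint == "vapor":
            rho = roots[0]
        elif phase_hint == "liquid":
            rho = roots[-1]
        else:
            # lower molar Gibbs energy wins: g/RT = sum x_i ln f_i
            def gibbs(r: float) -> float:
                lnf = self.ln_fugacity(T, r, x)
                mask = x > 0
                return float((x[mask] * lnf[mask]).sum())

            rho = min(roots, key=gibbs)
        return PhaseState(
            temperature=T, number_density=rho, mole_fractions=tuple(x)
        )

    def saturation_pressure(
        self, T: float, component: Optional[str] = None
    ) -> tuple[float, float, float]:
        """Pure-component vapor-liquid saturation at T.

        Returns (p_sat in Pa, liquid rho~, vapor rho~). Isofugacity between
        the coexisting phases is satisfied to |Delta ln f| < 1e-10.
        """
        if component is None:
            if self.mixture.n != 1:
                raise ValueError("component name required for a mixture")
            mix = self.mixture
            eos = self
        else:
            mix = self.mixture.subset(component)
            eos = PcSaft(mix)
        cached = eos._psat_cache.get(T)
        if cached is not None:
            return cached
        x = np.array([1.0])

        def dlnf(p: float) -> float:
            liq = eos.solve_density(T, p, x, "liquid")
            vap = eos.solve_density(T, p, x, "vapor")
            if abs(liq.number_density / vap.number_density - 1.0) < 1e-6:
                raise DensityRootError(
                    f"liquid and vapor roots collapsed at p = {p:.4g} Pa"
                )
            fl = eos.ln_fugacity(T, liq.number_density, x)[0]
            fv = eos.ln_fugacity(T, vap.number_density, x)[0]
            return fl - fv

        # successive substitution on the fugacity ratio: at a trial pressure
        # the liquid/vapor fugacity imbalance directly rescales the pressure
        p = 1000.0
        resid = math.inf
        for _ in range(100):
            try:
                r = dlnf(p)
            except DensityRootError as exc:
                raise EosError(
                    f"no vapor-liquid coexistence found at T = {T} K ({exc})"
                ) from exc
            p_new = p * math.exp(max(min(r, 5.0), -5.0))
            resid = abs(r)
            if resid < 1e-12:
                break
            p = p_new
        psat = p
        liq = eos.solve_density(T, psat, x, "liquid")
        vap = eos.solve_density(T, psat, x, "vapor")
        resid = abs(
            eos.ln_fugacity(T, liq.number_density, x)[0]
            - eos.ln_fugacity(T, vap.number_density, x)[0]
        )
        if resid > 1e-10:
            raise EosError(f"saturation solver residual {resid:.2e} > 1e-10")
        out = (psat, liq.number_density, vap.number_density)
        eos._psat_cache[T] = out
        return out


# ----------------------------------------------------------------------
# module-level functional interface
# ----------------------------------------------------------------------
def reduced_residual_helmholtz(mix: MixtureSpec, state: PhaseState) -> HelmholtzResult:
    """a_res and its hc/disp/assoc breakdown at the given state."""
    return PcSaft(mix).helmholtz(state.temperature, state.number_density, state.x)


def compressibility(mix: MixtureSpec, state: PhaseState) -> float:
    return PcSaft(mix).compressibility(state.temperature, state.number_density, state.x)


def ln_fugacity(mix: MixtureSpec, state: PhaseState) -> np.ndarray:
    return PcSaft(mix).ln_fugacity(state.temperature, state.number_density, state.x)


def solve_density(
    mix: MixtureSpec,
    T: float,
    p: float,
    x: Sequence[float],
    phase_hint: Optional[str] = None,
) -> PhaseState:
    return PcSaft(mix).solve_density(T, p, x, phase_hint)


def saturation_pressure(mix: MixtureSpec, T: float, component: Optional[str] = None):
    return PcSaft(mix).saturation_pressure(T, component)
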