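"""Independent brute-force transcription of the PC-SAFT terms.

Written as a literal, loop-based rendering of the published term expressions
(hard chain, dispersion, donor/acceptor association with Wolbach-Sandler
cross parameters), kept deliberately separate from the package's optimized
implementation so it can serve as a term-by-term oracle in tests. Only the
energy itself is computed here — no derivatives.
"""

import math

import numpy as np

A0 = [0.9105631445, 0.6361281449, 2.6861347891, -26.547362491,
      97.759208784, -159.59154087, 91.297774084]
A1 = [-0.3084016918, 0.1860531159, -2.5030047259, 21.419793629,
      -65.255885330, 83.318680481, -33.746922930]
A2 = [-0.0906148351, 0.4527842806, 0.5962700728, -1.7241829131,
      -4.1302112531, 13.776631870, -8.6728470368]
B0 = [0.7240946941, 2.2382791861, -4.0025849485, -21.003576815,
      26.855641363, 206.55133841, -355.60235612]
B1 = [-0.5755498075, 0.6995095521, 3.8925673390, -17.215471648,
      192.67226447, -161.82646165, -165.20769346]
B2 = [0.0976883116, -0.2557574982, -9.1558561530, 20.642075974,
      -38.804430052, 93.626774077, -29.666905585]


def oracle_ares(T, rho, x, m, sigma, u, kij, eps_assoc, kappa_assoc, n_donor, n_acceptor):
    """(a_hc, a_disp, a_assoc) for a mixture at (T, rho~ in 1/A^3, x)."""
    n = len(x)
    d = [sigma[i] * (1.0 - 0.12 * math.exp(-3.0 * u[i] / T)) for i in range(n)]

    zeta = [0.0] * 4
    for k in range(4):
        for i in range(n):
            zeta[k] += math.pi / 6.0 * rho * x[i] * m[i] * d[i] ** k
    z0, z1, z2, z3 = zeta

    # hard-sphere mixture term (Boublik-Mansoori)
    ahs = (
        3.0 * z1 * z2 / (1.0 - z3)
        + z2 ** 3 / (z3 * (1.0 - z3) ** 2)
        + (z2 ** 3 / z3 ** 2 - z0) * math.log(1.0 - z3)
    ) / z0

    def g_contact(i, j):
        dij = d[i] * d[j] / (d[i] + d[j])
        return (
            1.0 / (1.0 - z3)
            + dij * 3.0 * z2 / (1.0 - z3) ** 2
            + dij ** 2 * 2.0 * z2 ** 2 / (1.0 - z3) ** 3
        )

    mbar = sum(x[i] * m[i] for i in range(n))
    ahc = mbar * ahs
    for i in range(n):
        ahc -= x[i] * (m[i] - 1.0) * math.log(g_contact(i, i))

    # dispersion
    eta = z3
    I1 = I2 = 0.0
    for k in range(7):
        ak = A0[k] + (mbar - 1.0) / mbar * A1[k] + (mbar - 1.0) / mbar * (mbar - 2.0) / mbar * A2[k]
        bk = B0[k] + (mbar - 1.0) / mbar * B1[k] + (mbar - 1.0) / mbar * (mbar - 2.0) / mbar * B2[k]
        I1 += ak * eta ** k
        I2 += bk * eta ** k
    m2es3 = m2e2s3 = 0.0
    for i in range(n):
        for j in range(n):
            sij = 0.5 * (sigma[i] + sigma[j])
            uij = math.sqrt(u[i] * u[j]) * (1.0 - kij[i][j])
            m2es3 += x[i] * x[j] * m[i] * m[j] * (uij / T) * sij ** 3
            m2e2s3 += x[i] * x[j] * m[i] * m[j] * (uij / T) ** 2 * sij ** 3
    C1 = 1.0 / (
        1.0
        + mbar * (8.0 * eta - 2.0 * eta ** 2) / (1.0 - eta) ** 4
        + (1.0 - mbar)
        * (20.0 * eta - 27.0 * eta ** 2 + 12.0 * eta ** 3 - 2.0 * eta ** 4)
        / ((1.0 - eta) * (2.0 - eta)) ** 2
    )
    adisp = -2.0 * math.pi * rho * I1 * m2es3 - math.pi * rho * mbar * C1 * I2 * m2e2s3

    # association: donor/acceptor site types with integer multiplicities
    delta = [[0.0] * n for _ in range(n)]
    associating = [
        kappa_assoc[i] > 0 and (n_donor[i] + n_acceptor[i]) > 0 for i in range(n)
    ]
    for i in range(n):
        for j in range(n):
            if not (associating[i] and associating[j]):
                continue
            sij = 0.5 * (sigma[i] + sigma[j])
            eps_ij = 0.5 * (eps_assoc[i] + eps_assoc[j])
            kap_ij = math.sqrt(kappa_assoc[i] * kappa_assoc[j]) * (
                math.sqrt(sigma[i] * sigma[j]) / sij
            ) ** 3
            delta[i][j] = sij ** 3 * g_contact(i, j) * kap_ij * (
                math.exp(eps_ij / T) - 1.0
            )

    XA = [1.0] * n
    XD = [1.0] * n
    if any(delta[i][j] > 0 for i in range(n) for j in range(n)):
        for _ in range(20000):
            XA_new, XD_new = [], []
            for i in range(n):
                sa = sum(x[j] * n_donor[j] * XD[j] * delta[i][j] for j in range(n))
                sd = sum(x[j] * n_acceptor[j] * XA[j] * delta[i][j] for j in range(n))
                XA_new.append(1.0 / (1.0 + rho * sa))
                XD_new.append(1.0 / (1.0 + rho * sd))
            err = max(
                max(abs(a - b) for a, b in zip(XA_new, XA)),
                max(abs(a - b) for a, b in zip(XD_new, XD)),
            )
            XA = [0.5 * (a + b) for a, b in zip(XA_new, XA)]
            XD = [0.5 * (a + b) for a, b in zip(XD_new, XD)]
            if err < 1e-14:
                break

    aassoc = 0.0
    for i in range(n):
        if not associating[i]:
            continue
        aassoc += x[i] * (
            n_acceptor[i] * (math.log(XA[i]) - XA[i] / 2.0 + 0.5)
            + n_donor[i] * (math.log(XD[i]) - XD[i] / 2.0 + 0.5)
        )
    return ahc, adisp, aassoc


def oracle_from_mixture(mix, T, rho, x):
    """Run the oracle on a MixtureSpec from the package."""
    comps = mix.components
    kij_mat = mix.kij_matrix(T)
    return oracle_ares(
        T,
        rho,
        list(x),
        [c.m_seg for c in comps],
        [c.segment_diameter for c in comps],
        [c.dispersion_energy for c in comps],
        [[kij_mat[i][j] for j in range(len(comps))] for i in range(len(comps))],
        [c.assoc_energy for c in comps],
        [c.assoc_volume for c in comps],
        [c.assoc_sites[0] for c in comps],
        [c.assoc_sites[1] for c in comps],
    )


def pde_fractional_uptake(taus, nx=400, dt=2e-5):
    """Crank-Nicolson solution of plane-sheet sorption, as a kinetics oracle.

    Dimensionless diffusion on x in [0, 1] with c(x, 0) = 0, c(1, t) = 1 and
    a zero-flux base at x = 0; returns the fractional uptake at the given
    dimensionless times tau = D t / L0^2.
    """
    from scipy.linalg import solve_banded

    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    dx = 1.0 / (nx - 1)
    r = dt / (2.0 * dx ** 2)
    nu = nx - 1  # unknown nodes 0..nx-2; node nx-1 is the fixed surface (c = 1)

    # (I - r A) v_new = v + r A v + boundary, A = Laplacian with mirror at 0
    ab = np.zeros((3, nu))
    ab[0, 1:] = -r
    ab[1, :] = 1.0 + 2.0 * r
    ab[2, :-1] = -r
    ab[0, 1] = -2.0 * r  # zero-flux mirror: c[-1] = c[1]

    def apply_A(v):
        av = np.empty(nu)
        av[0] = 2.0 * (v[1] - v[0])
        av[1:-1] = v[:-2] - 2.0 * v[1:-1] + v[2:]
        av[-1] = v[-2] - 2.0 * v[-1] + 1.0
        return av

    v = np.zeros(nu)
    out = np.empty(len(taus))
    order = np.argsort(taus)
    t = 0.0
    for idx in order:
        target = taus[idx]
        while t < target - 1e-12:
            rhs = v + r * apply_A(v)
            rhs[-1] += r  # implicit-side boundary term moved to the rhs
            v = solve_banded((1, 1), ab, rhs)
            t += dt
        c = np.concatenate([v, [1.0]])
        out[idx] = np.trapezoid(c, dx=dx)
    return out
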