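"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np

from latticeimplant import fe_solver


def oc_reference_design(
    mesh,
    surrogate,
    volume_fraction: float = 0.4,
    rho_bounds: tuple[float, float] = (0.2, 0.7),
    iters: int = 40,
    move: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Optimality-criteria compliance minimization (gradient-based reference).

    Uses the same FE solver and material law as the package but a classical
    OC update on the continuous densities, providing an independent
    near-optimal compliance for the same volume constraint.
    """
    lo, hi = rho_bounds
    rho = np.full(mesh.n_elements, volume_fraction)
    a2, a1, _ = surrogate.e_coeffs
    c = np.inf
    for _ in range(iters):
        asm = fe_solver.assemble(mesh, rho, surrogate)
        state = fe_solver.solve(mesh, asm)
        c = state.c
        # dc/drho_e = -(dE/drho / E) * dc_e  (nu dependence neglected)
        E = surrogate.modulus(rho)
        dE = (2.0 * a2 * rho + a1) * surrogate.Es
        sens = -state.element_energy * dE / E  # negative: adding density helps
        # OC bisection on the volume multiplier
        l1, l2 = 1e-12, 1e12
        while (l2 - l1) / (l1 + l2) > 1e-6:
            lmid = 0.5 * (l1 + l2)
            factor = np.sqrt(np.maximum(-sens / lmid, 1e-30))
            rho_new = np.clip(
                np.clip(rho * factor, rho - move, rho + move), lo, hi
            )
            if rho_new.mean() > volume_fraction:
                l1 = lmid
            else:
                l2 = lmid
        rho = rho_new
    asm = fe_solver.assemble(mesh, rho, surrogate)
    state = fe_solver.solve(mesh, asm)
    return rho, state.c


def numeric_centroid_strain(coords: np.ndarray, ue: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Centroid engineering strain of one hex by numeric differentiation.

    Independent of the analytic B-matrix: differentiates the trilinear
    interpolation of the displacement field with central differences in the
    reference coordinates, then maps through the numeric Jacobian.
    """

    def interp(xi):
        w = np.array(
            [
                0.125 * (1 + sx * xi[0]) * (1 + sy * xi[1]) * (1 + sz * xi[2])
                for sx, sy, sz in [
                    (-1, -1, -1),
                    (1, -1, -1),
                    (1, 1, -1),
                    (-1, 1, -1),
                    (-1, -1, 1),
                    (1, -1, 1),
                    (1, 1, 1),
                    (-1, 1, 1),
                ]
            ]
        )
        return w @ ue.reshape(8, 3), w @ coords

    grad_u = np.zeros((3, 3))
    jac = np.zeros((3, 3))
    for d in range(3):
        xi_p = np.zeros(3)
        xi_p[d] = eps
        up, xp = interp(xi_p)
        um, xm = interp(-xi_p)
        grad_u[:, d] = (up - um) / (2 * eps)
        jac[:, d] = (xp - xm) / (2 * eps)
    grad_x = grad_u @ np.linalg.inv(jac)  # du_i/dx_j
    e = 0.5 * (grad_x + grad_x.T)
    return np.array(
        [e[0, 0], e[1, 1], e[2, 2], 2 * e[0, 1], 2 * e[0, 2], 2 * e[1, 2]]
    )


def laminate_stiffness(E_layers, nu_layers, fractions) -> np.ndarray:
    """Exact effective stiffness of an isotropic laminate layered along z.

    Semi-analytic oracle: for each unit macroscopic strain, per-layer strains
    satisfy continuity of in-plane strain components (11, 22, 12) and of the
    out-of-plane stress components (33, 13, 23); the resulting small linear
    system is solved exactly.  Voigt order (11, 22, 33, 12, 13, 23).
    """
    from latticeimplant._hex8 import isotropic_stiffness

    Cs = [isotropic_stiffness(E, nu) for E, nu in zip(E_layers, nu_layers)]
    f = np.asarray(fractions, dtype=float)
    f = f / f.sum()
    n = len(Cs)
    in_plane = [0, 1, 3]
    out_plane = [2, 4, 5]
    C_eff = np.zeros((6, 6))
    for m in range(6):
        e0 = np.zeros(6)
        e0[m] = 1.0
        # unknowns: per-layer strains (6 each); equations:
        # in-plane strains equal e0's in-plane components (per layer);
        # out-of-plane stress equal across layers (continuity);
        # volume average of out-of-plane strains equals e0's.
        A = np.zeros((6 * n, 6 * n))
        b = np.zeros(6 * n)
        row = 0
        for k in range(n):
            for comp in in_plane:
                A[row, 6 * k + comp] = 1.0
                b[row] = e0[comp]
                row += 1
        for comp in out_plane:  # sigma_comp layer k == layer 0
            for k in range(1, n):
                A[row, 6 * k : 6 * k + 6] = Cs[k][comp]
                A[row, 0:6] -= Cs[0][comp]
                row += 1
        for comp in out_plane:
            for k in range(n):
                A[row, 6 * k + comp] = f[k]
            b[row] = e0[comp]
            row += 1
        eps = np.linalg.solve(A, b).reshape(n, 6)
        sigma = sum(f[k] * (Cs[k] @ eps[k]) for k in range(n))
        C_eff[:, m] = sigma
    return 0.5 * (C_eff + C_eff.T)


def mc_union_fraction(cell, l: float, n_samples: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo union solid fraction of a periodic strut cell."""
    rng = np.random.default_rng(seed)
    P = rng.uniform(0.0, l, size=(n_samples, 3))
    hit = np.zeros(n_samples, dtype=bool)
    t2 = cell.t**2
    A = cell.nodes[cell.struts[:, 0]]
    B = cell.nodes[cell.struts[:, 1]]
    for sx in (-l, 0.0, l):
        for sy in (-l, 0.0, l):
            for sz in (-l, 0.0, l):
                off = np.array([sx, sy, sz])
                for a, b in zip(A + off, B + off):
                    u = b - a
                    uu = float(u @ u)
                    d = P - a
                    if uu < 1e-30:
                        dist2 = np.einsum("ij,ij->i", d, d)
                    else:
                        s = np.clip((d @ u) / uu, 0.0, 1.0)
                        dist2 = np.einsum(
                            "ij,ij->i", d - s[:, None] * u, d - s[:, None] * u
                        )
                    hit |= dist2 <= t2
    return float(hit.mean())
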