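"""Steady-state finite-volume solver for the 1-D diagenetic model.

Discretisation: vertex-centred finite volumes on the :class:`~sedpower.grid.Grid`
nodes.  Solutes carry molecular diffusion (tortuosity-corrected, harmonic-mean
interface coefficients), porewater burial advection (upwind) and reaction
sources; solids carry burial advection (upwind), optional biodiffusion and
reactions.  Boundary conditions: fixed solute concentrations and prescribed
solid deposition fluxes at the sediment-water interface; zero diffusive
gradient plus advective burial export at the base.

The nonlinear system is solved by damped Newton iteration with a sparse
finite-difference Jacobian (3-node x 9-variable colouring); when plain Newton
stalls, pseudo-transient continuation (implicit Euler with a geometrically
growing step) carries the state into Newton's basin of attraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import Grid
from .kinetics import ProfileSet, RateProfiles, reaction_rates, source_terms
from .parameters import SOLUTES, SOLIDS, KineticParameters, SiteConfig

_NVAR = len(SOLUTES) + len(SOLIDS)  # 9 state variables per node
_EPS_FD = np.sqrt(np.finfo(float).eps)


class SolverError(RuntimeError):
    """Raised when the steady-state iteration fails to converge."""


@dataclass
class _Discretisation:
    """Precomputed geometry and transport coefficients."""

    grid: Grid
    phi: np.ndarray  # porosity at nodes
    phi_ds: dict  # species -> phi*Ds at interfaces (harmonic mean)
    adv_sol: np.ndarray  # w * phi at interfaces (porewater advection)
    w: float
    d_b: np.ndarray  # biodiffusion coefficient at interfaces
    top_conc: np.ndarray  # Dirichlet values for solutes
    top_flux: np.ndarray  # deposition fluxes for solids
    scales: np.ndarray  # per-variable magnitude scales


def _build_discretisation(site: SiteConfig, p: KineticParameters, grid: Grid) -> _Discretisation:
    z = grid.node_depths
    phi = site.porosity_profile(z)
    dz = grid.cell_widths
    phi_ds = {}
    for s in SOLUTES:
        d0 = p.diffusivity(s, site.temperature)
        theta2 = 1.0 - 2.0 * np.log(phi)
        nodal = phi * d0 / theta2
        phi_ds[s] = 2.0 * nodal[:-1] * nodal[1:] / (nodal[:-1] + nodal[1:])
    phi_mid = 0.5 * (phi[:-1] + phi[1:])
    w = site.sedimentation_rate
    f1, f2, f3 = site.g_fractions
    top_flux = np.array(
        [site.organic_flux * f1, site.organic_flux * f2, site.organic_flux * f3, site.mno2_flux]
    )
    scales = np.empty(_NVAR)
    for j, s in enumerate(SOLUTES):
        scales[j] = max(site.top_concentrations[s], 1e-6)
    if w > 0:
        solid_scale = max(top_flux.max() / w, 1e-6)
    else:
        solid_scale = 1.0
    scales[len(SOLUTES):] = solid_scale
    return _Discretisation(
        grid=grid,
        phi=phi,
        phi_ds=phi_ds,
        adv_sol=w * phi_mid,
        w=w,
        d_b=np.full(grid.n_nodes - 1, p.D_b),
        top_conc=np.array([site.top_concentrations[s] for s in SOLUTES]),
        top_flux=top_flux,
        scales=scales,
    )


def _state_from_matrix(x: np.ndarray, grid: Grid) -> ProfileSet:
    sol = {s: x[:, j] for j, s in enumerate(SOLUTES)}
    solid = {s: x[:, len(SOLUTES) + j] for j, s in enumerate(SOLIDS)}
    return ProfileSet(grid=grid, solutes=sol, solids=solid)


def _residual(
    x: np.ndarray,
    disc: _Discretisation,
    site: SiteConfig,
    p: KineticParameters,
    lam: np.ndarray | None = None,
):
    """Steady-state residual, shape (n_nodes, 9), units mol m-3 bulk yr-1.

    The top solute rows carry the Dirichlet mismatch scaled by a transport
    rate so all rows share comparable magnitudes.  ``lam`` (yr-1, per
    variable) is a stiff restoring penalty on negative concentrations:
    rate laws see clipped values, so without it the discrete system admits
    spurious roots with small negative tails below oxidant depletion.
    """
    grid = disc.grid
    n = grid.n_nodes
    cv = grid.control_volumes
    dz = grid.cell_widths
    state = _state_from_matrix(x, grid)
    rates = reaction_rates(state, p, site)
    src = source_terms(rates, site)

    out = np.empty_like(x)
    for j, s in enumerate(SOLUTES):
        c = x[:, j]
        diff = -disc.phi_ds[s] * (c[1:] - c[:-1]) / dz  # flux at interfaces i+1/2
        adv = disc.adv_sol * c[:-1]  # upwind, w >= 0 (downward)
        flux = diff + adv  # mol m-2 bulk yr-1
        r = np.empty(n)
        r[1:-1] = (flux[:-1] - flux[1:]) / cv[1:-1] + src[s][1:-1]
        # bottom half-cell: no diffusive export, advective burial export
        r[-1] = (flux[-1] - disc.w * disc.phi[-1] * c[-1]) / cv[-1] + src[s][-1]
        # Dirichlet at the interface, scaled to a volumetric-rate magnitude
        r[0] = (disc.top_conc[j] - c[0]) * disc.phi_ds[s][0] / (dz[0] * cv[0])
        out[:, j] = r
    for j, s in enumerate(SOLIDS):
        col = len(SOLUTES) + j
        q = x[:, col]
        if disc.w == 0.0 and p.D_b == 0.0:
            # no solid transport: steady state forces the pools to zero
            out[:, col] = -q + src[s] * 0.0
            continue
        adv = disc.w * q[:-1]
        diff = -disc.d_b * (q[1:] - q[:-1]) / dz
        flux = adv + diff
        r = np.empty(n)
        r[0] = (disc.top_flux[j] - flux[0]) / cv[0] + src[s][0]
        r[1:-1] = (flux[:-1] - flux[1:]) / cv[1:-1] + src[s][1:-1]
        r[-1] = (flux[-1] - disc.w * q[-1]) / cv[-1] + src[s][-1]
        out[:, col] = r
    if lam is not None:
        out -= lam[None, :] * np.minimum(x, 0.0)
    return out


class _Jacobian:
    """Finite-difference sparse Jacobian using a 3-node colouring.

    A perturbation of node j only affects residuals at nodes j-1, j, j+1,
    so columns {j : j mod 3 = c} of one variable can be perturbed together:
    27 residual evaluations per Jacobian.
    """

    def __init__(self, n_nodes: int):
        self.n = n_nodes
        self.pattern = []  # per (c, var): rows, cols arrays
        for c in range(3):
            js = np.arange(c, n_nodes, 3)
            offs = np.array([-1, 0, 1])
            nodes = js[:, None] + offs[None, :]  # (nj, 3)
            valid = (nodes >= 0) & (nodes < n_nodes)
            self.pattern.append((js, nodes, valid))

    def build(self, func, x: np.ndarray, f0: np.ndarray, scales: np.ndarray) -> sp.csc_matrix:
        n = self.n
        rows_all, cols_all, data_all = [], [], []
        var_idx = np.arange(_NVAR)
        for var in range(_NVAR):
            h_col = _EPS_FD * np.maximum(np.abs(x[:, var]), scales[var])
            for c in range(3):
                js, nodes, valid = self.pattern[c]
                xp = x.copy()
                xp[js, var] += h_col[js]
                df = func(xp) - f0  # (n, 9)
                safe = np.clip(nodes, 0, n - 1)  # (nj, 3)
                data = df[safe, :] / h_col[js][:, None, None]  # (nj, 3, 9)
                rows = safe[:, :, None] * _NVAR + var_idx[None, None, :]
                cols = np.broadcast_to(
                    (js * _NVAR + var)[:, None, None], rows.shape
                )
                m = np.broadcast_to(valid[:, :, None], rows.shape)
                rows_all.append(rows[m])
                cols_all.append(cols[m])
                data_all.append(data[m])
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        data = np.concatenate(data_all)
        return sp.coo_matrix((data, (rows, cols)), shape=(n * _NVAR, n * _NVAR)).tocsc()


def _scaled_norm(f: np.ndarray, denom: np.ndarray) -> float:
    return float(np.max(np.abs(f) / denom[None, :]))


def _newton(func, x0, jac, scales, denom, tol, max_iter, mass=None, dt=None, x_prev=None):
    """Damped Newton on func(x) (optionally with an implicit-Euler mass term)."""
    x = x0.copy()

    def full_res(xx):
        f = func(xx)
        if dt is not None:
            f = f - mass * (xx - x_prev) / dt
        return f

    f = full_res(x)
    norm = _scaled_norm(f, denom)
    for _ in range(max_iter):
        if norm < tol:
            return x, norm, True
        J = jac.build(full_res, x, f, scales)
        try:
            lu = spla.splu(J)
        except RuntimeError:
            return x, norm, False
        dx = lu.solve(-f.ravel()).reshape(x.shape)
        alpha, accepted = 1.0, False
        for _ in range(12):
            x_try = x + alpha * dx
            f_try = full_res(x_try)
            norm_try = _scaled_norm(f_try, denom)
            if norm_try < norm * (1.0 - 1e-4 * alpha) or norm_try < tol:
                x, f, norm, accepted = x_try, f_try, norm_try, True
                break
            alpha *= 0.5
        if not accepted:
            return x, norm, False
    return x, norm, norm < tol


def solve_steady_state(
    site: SiteConfig,
    p: KineticParameters,
    grid: Grid,
    *,
    tol: float = 1e-8,
    max_newton: int = 200,
    initial: ProfileSet | None = None,
) -> tuple[ProfileSet, RateProfiles]:
    """Solve the coupled steady-state profiles for one core.

    Returns the converged concentration profiles (negatives below the
    positivity tolerance are clipped to zero) and the reaction rates
    evaluated on them.  Raises :class:`SolverError` with the residual norm
    if neither Newton nor pseudo-transient continuation converges.
    """
    disc = _build_discretisation(site, p, grid)
    n = grid.n_nodes

    # cold start: uniform solutes at their top values, solids at the
    # no-reaction advective balance F/w
    x_cold = np.empty((n, _NVAR))
    x_cold[:, : len(SOLUTES)] = disc.top_conc[None, :]
    if disc.w > 0:
        x_cold[:, len(SOLUTES):] = (disc.top_flux / disc.w)[None, :]
    else:
        x_cold[:, len(SOLUTES):] = 0.0

    # per-column residual denominators: the larger of the cold-start
    # residual and a characteristic transport rate, so columns whose
    # cold-start residual is pure round-off do not block convergence
    f_cold = _residual(x_cold, disc, site, p)
    L = grid.length
    char = np.empty(_NVAR)
    for j, s in enumerate(SOLUTES):
        d_char = float(np.max(disc.phi_ds[s]))
        char[j] = disc.scales[j] * (d_char / L**2 + disc.w / L)
    solid_rate = disc.w / L + p.D_b / L**2
    if solid_rate == 0.0:
        solid_rate = 1.0  # solids are pinned algebraically in this case
    char[len(SOLUTES):] = disc.scales[len(SOLUTES):] * solid_rate
    denom = np.maximum(np.max(np.abs(f_cold), axis=0), np.maximum(char, 1e-30))

    # restoring penalty stiff enough to hold negative tails below
    # ~1e-11 of each variable's scale at the residual tolerance
    lam = 1e3 * denom / disc.scales

    def func(xx):
        return _residual(xx, disc, site, p, lam=lam)

    x0 = x_cold
    if initial is not None:
        x0 = np.column_stack(
            [initial.solutes[s] for s in SOLUTES] + [initial.solids[s] for s in SOLIDS]
        )

    jac = _Jacobian(n)
    x, norm, ok = _newton(func, x0, jac, disc.scales, denom, tol, max_newton)

    if not ok:
        # pseudo-transient continuation: implicit Euler with the step
        # adapted to the remaining steady residual (switched evolution
        # relaxation), finished off by plain Newton
        mass = np.empty((n, _NVAR))
        mass[:, : len(SOLUTES)] = disc.phi[:, None]
        mass[:, len(SOLUTES):] = 1.0
        x = x_cold.copy()
        steady0 = _scaled_norm(func(x), denom)
        dt, last_finish = 1e-2, 0.0
        for step in range(300):
            x_new, norm_s, ok_s = _newton(
                func, x, jac, disc.scales, denom, 1e-6, 30,
                mass=mass, dt=dt, x_prev=x,
            )
            if ok_s:
                x = x_new
                steady = _scaled_norm(func(x), denom)
                if steady < tol:
                    break
                retry = steady < 1e2 and (last_finish == 0.0 or steady < 0.3 * last_finish)
                if retry:
                    x_try, _, ok_try = _newton(func, x, jac, disc.scales, denom, tol, 25)
                    if ok_try:
                        x = x_try
                        break
                    last_finish = steady
                dt = min(dt * 4.0, max(1e-2 * steady0 / max(steady, 1e-30), dt))
                if dt > 1e13:
                    break
            else:
                dt /= 4.0
                if dt < 1e-9:
                    break
        x, norm, ok = _newton(func, x, jac, disc.scales, denom, tol, max_newton)
        if not ok:
            raise SolverError(
                f"steady state not reached for site {site.name!r}: "
                f"scaled residual norm {norm:.3e} (tol {tol:.1e})"
            )

    # positivity audit, then clip round-off negatives
    neg_tol = 1e-9 * np.maximum(disc.scales, np.max(np.abs(x), axis=0))
    if np.any(x < -neg_tol[None, :]):
        worst = float(np.min(x / neg_tol[None, :]))
        raise SolverError(
            f"negative steady-state concentration beyond tolerance (worst {worst:.2f}x)"
        )
    x = np.maximum(x, 0.0)
    state = _state_from_matrix(x, grid)
    return state, reaction_rates(state, p, site)
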