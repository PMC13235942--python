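"""Implicit finite-volume steppers for the PNP and pure-diffusion models.

Discretization
--------------
Cell-centered finite volumes on the rectilinear mesh.  Face diffusivities
and permittivities are distance-weighted harmonic means (exact for the
discontinuous membrane coefficients); the drift term uses central
differencing of phi with arithmetic-mean face concentrations by default (an
upwind donor-cell option is available for steep-gradient robustness).

Time stepping is backward Euler.  The pure-diffusion model is linear and
each species decouples, so one sparse factorization per species is reused
for the whole run; the receptor interface fluxes add a small per-species
damped Newton iteration because the Nernst potentials are logarithmic in
the local concentrations.  The PNP system (all species + potential) is
advanced monolithically: a damped Newton iteration on the coupled residual.
Residual rows are scaled to concentration units (transport rows by dt/V,
Poisson rows by 1/(F V)) so a single tolerance applies to the whole system.
The Newton updates are solved directly (sparse LU) for small systems and
with preconditioned GMRES for large ones; the preconditioner is an
approximate block LU whose potential block is the Debye-screened Poisson
operator (Schur complement with diagonal transport inverses).

Operator splitting applies to the receptor gating ODEs: the open
probability is integrated with glutamate frozen at the start-of-step value,
while the resulting Na+/K+ fluxes are internal boundary conditions of the
implicit transport solve itself, evaluated at end-of-step fields.

Vesicle release needs no source terms: the opening cells simply couple the
vesicle interior to the cleft with restricted diffusion from t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .boundary import BoundaryArrays, BoundarySpec
from .constants import IonSpecies, PhysicalConstants
from .mesh import Mesh
from .receptors import AmpaCoupler, CurrentTrace
from .state import FieldState

__all__ = [
    "SolverSettings",
    "ConvergenceError",
    "solve_poisson",
    "PnpStepper",
    "DiffusionStepper",
    "pnp_step",
    "diffusion_step",
    "run_simulation",
    "run_to_steady_state",
    "SimulationResult",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(f"{message} (residual history: {history})")
        self.history = history


@dataclass(frozen=True)
class SolverSettings:
    """Time-stepping and nonlinear-solver settings.

    ``advection`` selects the face-concentration scheme for the drift term;
    ``negative_tol`` is the concentration undershoot (mM) beyond which a
    step is retried with a halved dt.
    """

    dt: float = 0.02
    newton_tol: float = 1e-8
    newton_max_iter: int = 25
    advection: str = "central"  # or "upwind"
    negative_tol: float = 1e-10
    max_dt_halvings: int = 12
    vesicle_open: bool = True
    linear_solver: str = "auto"  # "auto" | "direct" | "gmres"
    linear_rtol: float = 1e-4    # inexact-Newton forcing for the Krylov path
    direct_threshold: int = 12000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")
        if self.advection not in ("central", "upwind"):
            raise ValueError("advection must be 'central' or 'upwind'")
        if self.linear_solver not in ("auto", "direct", "gmres"):
            raise ValueError("linear_solver must be 'auto', 'direct' or 'gmres'")


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------

class _Discretization:
    """Static (state-independent) operators for one mesh/BC/species set."""

    def __init__(self, mesh: Mesh, species: list[IonSpecies],
                 bc: BoundarySpec, constants: PhysicalConstants,
                 vesicle_open: bool = True):
        self.mesh = mesh
        self.species = species
        self.constants = constants
        self.n = mesh.n_cells
        self.fg = mesh.faces
        self.bcs: BoundaryArrays = bc.build(mesh, species)
        self.vol = mesh.volumes.ravel()
        fg = self.fg

        # per-species face conductances g = D_f * A / d  (nm^3/ms)
        self.g = []
        self.ge = []
        self.gb = []
        self.gb_e = []
        beta = constants.beta
        for sp_k in species:
            Dcell = mesh.cell_diffusivity(sp_k)
            Df = fg.harmonic(Dcell)
            if not vesicle_open:
                from .mesh import Region
                touches = ((fg.region_lo == Region.VESICLE_OPENING)
                           | (fg.region_hi == Region.VESICLE_OPENING))
                Df = np.where(touches, 0.0, Df)
            g = Df * fg.area / fg.dist
            self.g.append(g)
            self.ge.append(sp_k.z * beta * g)
            gbk = Dcell[fg.b_cell] * fg.b_area / fg.b_dist
            self.gb.append(gbk)
            self.gb_e.append(sp_k.z * beta * gbk)

        # Dirichlet masks
        self.bm_phi = np.isfinite(self.bcs.phi)
        self.bm_c = np.isfinite(self.bcs.conc)  # (nk, nb)
        # drift across a boundary face needs both Dirichlet c and phi
        self.bm_drift = self.bm_c & self.bm_phi[None, :]

        # static transport matrices: M_k = V/dt I - (A_diff + bdry diag)
        # assembled without the 1/dt part (added per step)
        self.A_diff = []
        self.b_diff = []
        for k in range(len(species)):
            g = self.g[k]
            rows = np.concatenate([fg.lo, fg.lo, fg.hi, fg.hi])
            cols = np.concatenate([fg.lo, fg.hi, fg.hi, fg.lo])
            data = np.concatenate([-g, g, -g, g])
            m = self.bm_c[k]
            if m.any():
                cells = fg.b_cell[m]
                gb = self.gb[k][m]
                rows = np.concatenate([rows, cells])
                cols = np.concatenate([cols, cells])
                data = np.concatenate([data, -gb])
            A = sp.coo_matrix((data, (rows, cols)), shape=(self.n, self.n)).tocsr()
            b = np.zeros(self.n)
            if m.any():
                np.add.at(b, fg.b_cell[m], self.gb[k][m] * self.bcs.conc[k, m])
            self.A_diff.append(A)
            self.b_diff.append(b)

        # Poisson operator
        eps_cell = mesh.cell_permittivity(constants)
        eps_f = fg.harmonic(eps_cell, zero_blocked=False)
        gP = eps_f * fg.area / fg.dist
        rows = np.concatenate([fg.lo, fg.lo, fg.hi, fg.hi])
        cols = np.concatenate([fg.lo, fg.hi, fg.hi, fg.lo])
        data = np.concatenate([-gP, gP, -gP, gP])
        bP = np.zeros(self.n)
        if self.bm_phi.any():
            cells = fg.b_cell[self.bm_phi]
            gPb = eps_cell[fg.b_cell[self.bm_phi]] * fg.b_area[self.bm_phi] \
                / fg.b_dist[self.bm_phi]
            rows = np.concatenate([rows, cells])
            cols = np.concatenate([cols, cells])
            data = np.concatenate([data, -gPb])
            np.add.at(bP, cells, gPb * self.bcs.phi[self.bm_phi])
        self.L_P = sp.coo_matrix((data, (rows, cols)), shape=(self.n, self.n)).tocsr()
        self.b_P = bP
        self.has_phi_dirichlet = bool(self.bm_phi.any())

    # -- drift terms (state dependent) -------------------------------------
    def drift_net(self, k: int, c: np.ndarray, phi: np.ndarray,
                  scheme: str) -> np.ndarray:
        """Net electrical-drift inflow per cell for species k."""
        fg = self.fg
        adv = self.ge[k] * (phi[fg.hi] - phi[fg.lo])
        if scheme == "central":
            cf = 0.5 * (c[fg.lo] + c[fg.hi])
        else:
            cf = np.where(adv < 0, c[fg.lo], c[fg.hi])
        net = np.zeros(self.n)
        np.add.at(net, fg.lo, adv * cf)
        np.add.at(net, fg.hi, -adv * cf)
        m = self.bm_drift[k]
        if m.any():
            cells = fg.b_cell[m]
            adv_b = self.gb_e[k][m] * (self.bcs.phi[m] - phi[cells])
            cbc = self.bcs.conc[k, m]
            if scheme == "central":
                cfb = 0.5 * (c[cells] + cbc)
            else:
                cfb = np.where(adv_b < 0, c[cells], cbc)
            np.add.at(net, cells, adv_b * cfb)
        return net

    def drift_jacobian_parts(self, k: int, c: np.ndarray, phi: np.ndarray,
                             scheme: str):
        """COO pieces of d(net)/dc and d(net)/dphi for species k."""
        fg = self.fg
        dphi = phi[fg.hi] - phi[fg.lo]
        adv = self.ge[k] * dphi
        if scheme == "central":
            cf = 0.5 * (c[fg.lo] + c[fg.hi])
            dc_lo = 0.5 * adv
            dc_hi = 0.5 * adv
        else:
            donor_lo = adv < 0
            cf = np.where(donor_lo, c[fg.lo], c[fg.hi])
            dc_lo = np.where(donor_lo, adv, 0.0)
            dc_hi = np.where(donor_lo, 0.0, adv)
        gec = self.ge[k] * cf
        # rows/cols/data for d(net)/dc
        rows_c = np.concatenate([fg.lo, fg.lo, fg.hi, fg.hi])
        cols_c = np.concatenate([fg.lo, fg.hi, fg.lo, fg.hi])
        data_c = np.concatenate([dc_lo, dc_hi, -dc_lo, -dc_hi])
        # d(net)/dphi: net_lo = ge*cf*(phi_hi - phi_lo)
        rows_p = np.concatenate([fg.lo, fg.lo, fg.hi, fg.hi])
        cols_p = np.concatenate([fg.lo, fg.hi, fg.lo, fg.hi])
        data_p = np.concatenate([-gec, gec, gec, -gec])
        m = self.bm_drift[k]
        if m.any():
            cells = fg.b_cell[m]
            adv_b = self.gb_e[k][m] * (self.bcs.phi[m] - phi[cells])
            cbc = self.bcs.conc[k, m]
            if scheme == "central":
                cfb = 0.5 * (c[cells] + cbc)
                dcb = 0.5 * adv_b
            else:
                donor_cell = adv_b < 0
                cfb = np.where(donor_cell, c[cells], cbc)
                dcb = np.where(donor_cell, adv_b, 0.0)
            rows_c = np.concatenate([rows_c, cells])
            cols_c = np.concatenate([cols_c, cells])
            data_c = np.concatenate([data_c, dcb])
            rows_p = np.concatenate([rows_p, cells])
            cols_p = np.concatenate([cols_p, cells])
            data_p = np.concatenate([data_p, -self.gb_e[k][m] * cfb])
        return (rows_c, cols_c, data_c), (rows_p, cols_p, data_p)


# ---------------------------------------------------------------------------
# Poisson solve
# ---------------------------------------------------------------------------

def solve_poisson(mesh: Mesh, charge_density: np.ndarray, bc: BoundarySpec,
                  constants: PhysicalConstants | None = None,
                  species: list[IonSpecies] | None = None,
                  disc: "_Discretization | None" = None) -> np.ndarray:
    """Solve div(eps_r eps0 grad phi) = -rho on the mesh.

    ``charge_density`` is the nodal rho field in C/m^3 (shape of the mesh).
    Returns phi (mV) with the same shape.  Raises if no Dirichlet patch
    anchors the potential.
    """
    constants = constants or PhysicalConstants()
    if disc is None:
        from .constants import default_species
        species = species or default_species()
        disc = _Discretization(mesh, species, bc, constants)
    if not disc.has_phi_dirichlet:
        raise ValueError("Poisson problem is singular: no Dirichlet patch for phi")
    rhs = -disc.b_P - charge_density.ravel() * disc.vol
    phi = spla.splu(disc.L_P.tocsc()).solve(rhs)
    return phi.reshape(mesh.shape)


# ---------------------------------------------------------------------------
# steppers
# ---------------------------------------------------------------------------

class DiffusionStepper:
    """Backward-Euler stepper for the pure-diffusion model.

    Linear and species-decoupled; one LU factorization per species per dt
    is cached and reused.
    """

    def __init__(self, mesh: Mesh, species: list[IonSpecies], bc: BoundarySpec,
                 constants: PhysicalConstants | None = None,
                 settings: SolverSettings | None = None):
        self.constants = constants or PhysicalConstants()
        self.settings = settings or SolverSettings()
        self.mesh = mesh
        self.species = species
        self.disc = _Discretization(mesh, species, bc, self.constants,
                                    vesicle_open=self.settings.vesicle_open)
        self._lu: dict[tuple[int, float], spla.SuperLU] = {}

    def _factor(self, k: int, dt: float) -> spla.SuperLU:
        key = (k, dt)
        if key not in self._lu:
            n = self.disc.n
            M = sp.diags(self.disc.vol / dt) - self.disc.A_diff[k]
            self._lu[key] = spla.splu(M.tocsc())
        return self._lu[key]

    def step(self, state: FieldState, dt: float | None = None,
             sources: np.ndarray | None = None,
             ampa: tuple | None = None) -> FieldState:
        """One implicit Euler step.

        ``sources`` are fixed per-cell molar source rates (mM*nm^3/ms);
        ``ampa=(coupler, o, skip_masks)`` adds the receptor interface
        fluxes evaluated implicitly at the end-of-step concentrations (a
        small per-species damped Newton iteration, since the Nernst
        potentials are logarithmic in the local concentrations).
        """
        dt = dt if dt is not None else self.settings.dt
        nk = len(self.species)
        conc = state.conc.reshape(nk, -1)
        new = state.copy()
        new_c = new.conc.reshape(nk, -1)
        for k in range(nk):
            rhs = self.disc.vol / dt * conc[k] + self.disc.b_diff[k]
            if sources is not None:
                rhs = rhs + sources[k]
            new_c[k] = self._factor(k, dt).solve(rhs)
        if ampa is not None:
            coupler, o, skip = ampa
            self._implicit_flux_correction(new_c, conc, coupler, o, skip, dt)
        new.t = state.t + dt
        new.phi = None
        return new

    def _implicit_flux_correction(self, c: np.ndarray, c_old: np.ndarray,
                                  coupler, o: np.ndarray,
                                  skip: dict, dt: float) -> None:
        """Newton iteration for the conducted species (Na+, K+) with the
        receptor flux as an implicit internal boundary condition."""
        d = self.disc
        tol = self.settings.newton_tol * max(1.0, float(np.abs(c_old).max()))

        def residuals(cc):
            fe = coupler.flux_eval(cc, None, o, skip)
            S = coupler.sources(fe, d.n)
            out = {}
            norm = 0.0
            for name, k in coupler.idx.items():
                R = ((cc[k] - c_old[k]) * d.vol / dt
                     - (d.A_diff[k] @ cc[k] + d.b_diff[k]) - S[k])
                out[k] = (name, R)
                norm = max(norm, float(np.abs(R * dt / d.vol).max()))
            return fe, out, norm

        fe, res, norm = residuals(c)
        history = [norm]
        for _ in range(self.settings.newton_max_iter):
            if norm <= tol:
                return
            ext, intr = coupler.ext_cells, coupler.int_cells
            a = coupler.areas
            deltas = {}
            for k, (name, R) in res.items():
                rows = np.concatenate([ext, ext, intr, intr])
                cols = np.concatenate([ext, intr, ext, intr])
                data = np.concatenate([
                    -a * fe.dJ_dce[name], -a * fe.dJ_dci[name],
                    a * fe.dJ_dce[name], a * fe.dJ_dci[name]])
                dS = sp.coo_matrix((data, (rows, cols)), shape=(d.n, d.n))
                Jk = (sp.diags(d.vol / dt) - d.A_diff[k] + dS).tocsc()
                deltas[k] = spla.splu(Jk).solve(-R)
            lam = 1.0
            for _ in range(20):
                c_try = c.copy()
                for k, dk in deltas.items():
                    c_try[k] = c[k] + lam * dk
                fe_try, res_try, norm_try = residuals(c_try)
                if norm_try < norm or norm_try <= tol:
                    break
                lam *= 0.5
            c[...] = c_try
            fe, res, norm = fe_try, res_try, norm_try
            history.append(norm)
        if norm <= tol:
            return
        raise ConvergenceError(
            "implicit receptor-flux iteration did not converge", history)


class PnpStepper:
    """Monolithic backward-Euler stepper for the coupled PNP system.

    One damped Newton iteration per step on the full residual
    (all species + Poisson), sparse direct linear solves.
    """

    def __init__(self, mesh: Mesh, species: list[IonSpecies], bc: BoundarySpec,
                 constants: PhysicalConstants | None = None,
                 settings: SolverSettings | None = None):
        self.constants = constants or PhysicalConstants()
        self.settings = settings or SolverSettings()
        self.mesh = mesh
        self.species = species
        self.disc = _Discretization(mesh, species, bc, self.constants,
                                    vesicle_open=self.settings.vesicle_open)
        if not self.disc.has_phi_dirichlet:
            raise ValueError("PNP needs at least one Dirichlet patch for phi")
        self.nk = len(species)
        self.n = self.disc.n
        # row scaling -> concentration units
        self._z = np.array([s.z for s in species], dtype=float)
        n_unknowns = (self.nk + 1) * self.n
        if self.settings.linear_solver == "auto":
            self._direct = n_unknowns <= self.settings.direct_threshold
        else:
            self._direct = self.settings.linear_solver == "direct"
        self._prec = None        # cached block preconditioner (Krylov path)
        self._prec_age = 0       # linear solves since the last rebuild
        self._static = None      # cached state-independent Jacobian entries
        self._static_dt = None

    def initial_potential(self, state: FieldState) -> np.ndarray:
        rho = state.charge_density(self.constants)
        return solve_poisson(self.mesh, rho, bc=None, constants=self.constants,
                             disc=self.disc)

    # -- residual and Jacobian ---------------------------------------------
    def _residual(self, c: np.ndarray, phi: np.ndarray, c_old: np.ndarray,
                  dt: float, sources: np.ndarray | None,
                  ampa: tuple | None = None) -> np.ndarray:
        d = self.disc
        scheme = self.settings.advection
        F = self.constants.F
        flux_sources = None
        if ampa is not None:
            coupler, o, skip = ampa
            fe = coupler.flux_eval(c, phi, o, skip)
            flux_sources = coupler.sources(fe, d.n)
        parts = []
        s_c = dt / d.vol
        for k in range(self.nk):
            net = d.A_diff[k] @ c[k] + d.b_diff[k] + d.drift_net(k, c[k], phi, scheme)
            if sources is not None:
                net = net + sources[k]
            if flux_sources is not None:
                net = net + flux_sources[k]
            parts.append(((c[k] - c_old[k]) * d.vol / dt - net) * s_c)
        rho_v = F * (self._z @ c) * d.vol
        r_phi = (d.L_P @ phi + d.b_P + rho_v) / (F * d.vol)
        parts.append(r_phi)
        return np.concatenate(parts)

    def _ampa_jacobian_entries(self, c: np.ndarray, phi: np.ndarray,
                               ampa: tuple, s_c: np.ndarray):
        """Row-scaled COO entries of -d(flux sources)/d(c, phi)."""
        coupler, o, skip = ampa
        fe = coupler.flux_eval(c, phi, o, skip)
        ext, intr = coupler.ext_cells, coupler.int_cells
        a = coupler.areas
        n, nk = self.n, self.nk
        rows, cols, data = [], [], []
        for name, k in coupler.idx.items():
            off = k * n
            re, ri = off + ext, off + intr
            # concentration couplings
            rows.extend([re, re, ri, ri])
            cols.extend([off + ext, off + intr, off + ext, off + intr])
            data.extend([
                -a * fe.dJ_dce[name] * s_c[ext],
                -a * fe.dJ_dci[name] * s_c[ext],
                a * fe.dJ_dce[name] * s_c[intr],
                a * fe.dJ_dci[name] * s_c[intr]])
            if coupler.model == "pnp":
                # v = phi_int - phi_ext
                pe, pi = nk * n + ext, nk * n + intr
                rows.extend([re, re, ri, ri])
                cols.extend([pi, pe, pi, pe])
                data.extend([
                    -a * fe.dJ_dv[name] * s_c[ext],
                    a * fe.dJ_dv[name] * s_c[ext],
                    a * fe.dJ_dv[name] * s_c[intr],
                    -a * fe.dJ_dv[name] * s_c[intr]])
        return (np.concatenate(rows), np.concatenate(cols),
                np.concatenate(data))

    def _static_entries(self, dt: float):
        """State-independent Jacobian entries (cached per dt)."""
        if self._static is not None and self._static_dt == dt:
            return self._static
        d = self.disc
        n, nk = self.n, self.nk
        F = self.constants.F
        s_c = dt / d.vol
        s_p = 1.0 / (F * d.vol)
        rows, cols, data = [], [], []
        idx = np.arange(n)
        for k in range(nk):
            off = k * n
            # dR_k/dc_k, static part: (V/dt I - A_diff) * s_c
            A = d.A_diff[k].tocoo()
            rows.append(off + A.row)
            cols.append(off + A.col)
            data.append(-A.data * s_c[A.row])
            rows.append(off + idx)
            cols.append(off + idx)
            data.append(np.ones(n))  # (V/dt)*s_c == 1
            # dR_phi/dc_k = F z_k V * s_p == z_k
            rows.append(nk * n + idx)
            cols.append(off + idx)
            data.append(np.full(n, self._z[k]))
        LP = d.L_P.tocoo()
        rows.append(nk * n + LP.row)
        cols.append(nk * n + LP.col)
        data.append(LP.data * s_p[LP.row])
        self._static = (np.concatenate(rows), np.concatenate(cols),
                        np.concatenate(data))
        self._static_dt = dt
        return self._static

    def _jacobian(self, c: np.ndarray, phi: np.ndarray, dt: float,
                  ampa: tuple | None = None) -> sp.csc_matrix:
        d = self.disc
        n, nk = self.n, self.nk
        scheme = self.settings.advection
        s_c = dt / d.vol
        srows, scols, sdata = self._static_entries(dt)
        rows, cols, data = [srows], [scols], [sdata]
        for k in range(nk):
            off = k * n
            (rc, cc, dc), (rp, cp, dp) = d.drift_jacobian_parts(k, c[k], phi, scheme)
            rows.append(off + rc)
            cols.append(off + cc)
            data.append(-dc * s_c[rc])
            rows.append(off + rp)
            cols.append(nk * n + cp)
            data.append(-dp * s_c[rp])
        if ampa is not None:
            ar, ac, ad = self._ampa_jacobian_entries(c, phi, ampa, s_c)
            rows.append(ar)
            cols.append(ac)
            data.append(ad)
        J = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=((nk + 1) * n, (nk + 1) * n),
        )
        return J.tocsc()

    # -- linear solver ------------------------------------------------------
    def _build_preconditioner(self, J: sp.csr_matrix):
        """Approximate block-LU of the coupled Jacobian.

        The species diagonal blocks T_k and the potential block are scalar
        7-point operators; the potential Schur complement is approximated
        with diag(T_k)^-1, which yields the screened ("Debye") Poisson
        operator.  All six factorizations are scalar-sized and cheap.
        """
        n, nk = self.n, self.nk
        J = J.tocsr()
        T_lu, P_blocks = [], []
        S = J[nk * n:, nk * n:].copy()
        for k in range(nk):
            Tk = J[k * n:(k + 1) * n, k * n:(k + 1) * n]
            Pk = J[k * n:(k + 1) * n, nk * n:].tocsr()
            T_lu.append(spla.splu(Tk.tocsc()))
            P_blocks.append(Pk)
            S = S - self._z[k] * sp.diags(1.0 / Tk.diagonal()) @ Pk
        S_lu = spla.splu(S.tocsc())

        def apply(y: np.ndarray) -> np.ndarray:
            y = np.asarray(y, dtype=float)
            x = np.empty_like(y)
            cs = [T_lu[k].solve(y[k * n:(k + 1) * n]) for k in range(nk)]
            rhs = y[nk * n:].copy()
            for k in range(nk):
                rhs -= self._z[k] * cs[k]
            xphi = S_lu.solve(rhs)
            x[nk * n:] = xphi
            for k in range(nk):
                x[k * n:(k + 1) * n] = cs[k] - T_lu[k].solve(P_blocks[k] @ xphi)
            return x

        return spla.LinearOperator(J.shape, apply, dtype=float)

    #: GMRES iteration count above which the cached preconditioner is
    #: considered stale and rebuilt from the current Jacobian
    _PREC_MAX_ITERS = 140

    def _solve_linear(self, J, R: np.ndarray, fresh_prec: bool) -> np.ndarray:
        if self._direct:
            return spla.splu(J.tocsc()).solve(-R)
        if self._prec is None:
            self._prec = self._build_preconditioner(J)
            self._prec_age = 0
        rtol = self.settings.linear_rtol
        count = [0]

        def cb(_):
            count[0] += 1

        delta, info = spla.gmres(J, -R, M=self._prec, rtol=rtol, atol=0.0,
                                 maxiter=400, restart=150, callback=cb,
                                 callback_type="pr_norm")
        if info != 0 or count[0] > self._PREC_MAX_ITERS:
            # stale preconditioner; rebuild from the current Jacobian
            self._prec = self._build_preconditioner(J)
            self._prec_age = 0
            if info != 0:
                delta, info = spla.gmres(J, -R, M=self._prec, rtol=rtol,
                                         atol=0.0, maxiter=400, restart=150)
        else:
            self._prec_age += 1
        if info != 0:
            raise ConvergenceError(
                "preconditioned GMRES failed on the Newton update", [float(info)])
        return delta

    def step(self, state: FieldState, dt: float | None = None,
             sources: np.ndarray | None = None,
             ampa: tuple | None = None) -> FieldState:
        """One backward-Euler step of the coupled system.

        ``sources`` are fixed molar source rates;
        ``ampa=(coupler, o, skip_masks)`` adds the receptor interface
        fluxes, evaluated implicitly at the end-of-step fields inside the
        same Newton iteration.
        """
        dt = dt if dt is not None else self.settings.dt
        tol = self.settings.newton_tol
        c_old = state.conc.reshape(self.nk, -1)
        c = c_old.copy()
        phi = (state.phi.ravel().copy() if state.phi is not None
               else self.initial_potential(state).ravel())
        ref = max(1.0, float(np.abs(c_old).max()))
        atol = tol * ref

        R = self._residual(c, phi, c_old, dt, sources, ampa)
        norm = float(np.abs(R).max())
        history = [norm]
        it = 0
        while norm > atol:
            if it >= self.settings.newton_max_iter:
                raise ConvergenceError("Newton iteration did not converge", history)
            J = self._jacobian(c, phi, dt, ampa)
            delta = self._solve_linear(J, R, fresh_prec=(it == 0))
            dc = delta[: self.nk * self.n].reshape(self.nk, self.n)
            dphi = delta[self.nk * self.n:]
            lam = 1.0
            for _ in range(12):
                c_try = c + lam * dc
                phi_try = phi + lam * dphi
                R_try = self._residual(c_try, phi_try, c_old, dt, sources, ampa)
                norm_try = float(np.abs(R_try).max())
                if norm_try < norm or norm_try <= atol:
                    break
                lam *= 0.5
            c, phi, R, norm = c_try, phi_try, R_try, norm_try
            history.append(norm)
            it += 1
        new = state.copy()
        new.conc = c.reshape(state.conc.shape)
        new.phi = phi.reshape(self.mesh.shape)
        new.t = state.t + dt
        new.newton_iterations = it  # type: ignore[attr-defined]
        return new


def pnp_step(state: FieldState, mesh: Mesh, bc: BoundarySpec,
             settings: SolverSettings | None = None,
             constants: PhysicalConstants | None = None,
             sources: np.ndarray | None = None) -> FieldState:
    """One backward-Euler step of the coupled PNP system (convenience)."""
    stepper = PnpStepper(mesh, state.species, bc, constants, settings)
    return stepper.step(state, sources=sources)


def diffusion_step(state: FieldState, mesh: Mesh, bc: BoundarySpec,
                   settings: SolverSettings | None = None,
                   constants: PhysicalConstants | None = None,
                   sources: np.ndarray | None = None) -> FieldState:
    """One backward-Euler step of the pure-diffusion model (convenience)."""
    stepper = DiffusionStepper(mesh, state.species, bc, constants, settings)
    return stepper.step(state, sources=sources)


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Output of :func:`run_simulation`.

    ``snapshots`` maps requested times to field states; ``probes`` is a
    long-format table (t_ms, probe, quantity, value); ``current`` is the
    integrated AMPA trace (empty if no receptor coupling).
    """

    model: str
    times: np.ndarray
    snapshots: dict[float, FieldState]
    final_state: FieldState
    current: CurrentTrace
    probes: pd.DataFrame
    newton_iterations: list[int] = field(default_factory=list)
    mesh: Mesh | None = None


def _probe_rows(state: FieldState, mesh: Mesh, probes, rows: list) -> None:
    for name, (i, j, k) in probes:
        for ks, sp_k in enumerate(state.species):
            rows.append((state.t, name, sp_k.name, float(state.conc[ks, i, j, k])))
        if state.phi is not None:
            rows.append((state.t, name, "phi", float(state.phi[i, j, k])))


def run_simulation(
    initial: FieldState,
    mesh: Mesh,
    bc: BoundarySpec,
    settings: SolverSettings | None = None,
    duration: float = 0.5,
    model: str = "pnp",
    constants: PhysicalConstants | None = None,
    coupler: AmpaCoupler | None = None,
    snapshot_times: tuple[float, ...] = (),
    probes: list[tuple[str, tuple[int, int, int]]] | None = None,
    progress: Callable[[int, int], None] | None = None,
) -> SimulationResult:
    """Advance one model for ``duration`` ms with operator-split receptors.

    ``duration`` must be a multiple of the time step.  A step that drives
    any concentration below ``-negative_tol`` is retried as two half steps
    (recursively, up to ``max_dt_halvings`` levels); the nominal dt is
    restored afterwards.
    """
    settings = settings or SolverSettings()
    constants = constants or PhysicalConstants()
    if model not in ("pnp", "d"):
        raise ValueError("model must be 'pnp' or 'd'")
    dt = settings.dt
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ValueError("duration must be a multiple of dt")

    if model == "pnp":
        stepper = PnpStepper(mesh, initial.species, bc, constants, settings)
    else:
        stepper = DiffusionStepper(mesh, initial.species, bc, constants, settings)

    state = initial.copy()
    if model == "pnp":
        state.phi = solve_poisson(mesh, state.charge_density(constants), None,
                                  constants, disc=stepper.disc)
    else:
        state.phi = None

    probes = probes or []
    rows: list = []
    _probe_rows(state, mesh, probes, rows)
    snapshots: dict[float, FieldState] = {}
    want = sorted(set(float(t) for t in snapshot_times))
    if want and 0.0 == want[0]:
        snapshots[0.0] = state.copy()
        want = want[1:]
    times = [0.0]
    currents = [0.0 if coupler is not None else np.nan]
    newton_iters: list[int] = []

    def advance(st: FieldState, h: float, depth: int) -> tuple[FieldState, float]:
        if coupler is not None:
            markov_new, o = coupler.advance_markov(st, h)
            skip = coupler.skip_masks(st.conc.reshape(len(st.species), -1))
            ampa = (coupler, o, skip)
        else:
            markov_new, o, skip, ampa = st.markov, None, None, None
        new = stepper.step(st, h, ampa=ampa)
        cmin = float(new.conc.min())
        if cmin < -settings.negative_tol:
            if depth >= settings.max_dt_halvings:
                raise ConvergenceError(
                    f"negative concentration {cmin:g} mM persists at minimum dt",
                    [cmin])
            half, _ = advance(st, h / 2.0, depth + 1)
            return advance(half, h / 2.0, depth + 1)
        new.markov = markov_new
        if coupler is not None:
            # current carried by the step's implicit end-of-step fluxes
            fe = coupler.flux_eval(
                new.conc.reshape(len(new.species), -1),
                None if new.phi is None else new.phi.ravel(), o, skip)
            I = coupler.current(fe)
        else:
            I = np.nan
        if hasattr(new, "newton_iterations"):
            newton_iters.append(new.newton_iterations)
        return new, I

    for step_i in range(n_steps):
        state, I = advance(state, dt, 0)
        state.t = (step_i + 1) * dt  # avoid drift from halved steps
        times.append(state.t)
        currents.append(I)
        _probe_rows(state, mesh, probes, rows)
        while want and state.t >= want[0] - 1e-9:
            snapshots[want[0]] = state.copy()
            want = want[1:]
        if progress is not None:
            progress(step_i + 1, n_steps)

    trace = CurrentTrace(t=np.asarray(times), I=np.asarray(currents, dtype=float))
    probe_df = pd.DataFrame(rows, columns=["t_ms", "probe", "quantity", "value"])
    return SimulationResult(
        model=model, times=np.asarray(times), snapshots=snapshots,
        final_state=state, current=trace, probes=probe_df,
        newton_iterations=newton_iters, mesh=mesh,
    )


def run_to_steady_state(
    initial: FieldState,
    mesh: Mesh,
    bc: BoundarySpec,
    settings: SolverSettings | None = None,
    model: str = "pnp",
    constants: PhysicalConstants | None = None,
    rate_tol: float = 1e-8,
    max_steps: int = 2000,
) -> FieldState:
    """Step until max |dc/dt| falls below ``rate_tol`` (mM/ms)."""
    settings = settings or SolverSettings()
    constants = constants or PhysicalConstants()
    if model == "pnp":
        stepper = PnpStepper(mesh, initial.species, bc, constants, settings)
    else:
        stepper = DiffusionStepper(mesh, initial.species, bc, constants, settings)
    state = initial.copy()
    if model == "pnp":
        state.phi = solve_poisson(mesh, state.charge_density(constants), None,
                                  constants, disc=stepper.disc)
    for _ in range(max_steps):
        new = stepper.step(state, settings.dt)
        rate = float(np.abs(new.conc - state.conc).max()) / settings.dt
        state = new
        if rate < rate_tol:
            return state
    raise ConvergenceError("steady state not reached", [rate])
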