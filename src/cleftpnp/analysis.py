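"""Flux decomposition, model-comparison metrics, and equilibrium oracles.

The transport of each species splits into a diffusional flux J_d = -D grad c
and an electrical (drift) flux J_e = -D z e/(kB T) c grad phi; the PNP model
evolves concentrations by -div(J_d + J_e), the pure-diffusion model by
-div J_d alone.  This module computes the two flux fields with the same
discrete operators as the solvers, verifies the discrete balance, compares
paired PNP/D runs, and provides an independent Poisson-Boltzmann solver for
one-dimensional equilibrium checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .boundary import BoundarySpec
from .constants import AVOGADRO, IonSpecies, PhysicalConstants, species_index
from .mesh import Mesh
from .state import FieldState

__all__ = [
    "FluxField",
    "flux_decomposition",
    "divergence_check",
    "PoissonBoltzmannSolution",
    "poisson_boltzmann_oracle",
    "molecule_count",
    "electroneutral_complete",
    "ComparisonReport",
    "compare_runs",
]


# ---------------------------------------------------------------------------
# flux decomposition
# ---------------------------------------------------------------------------

@dataclass
class FluxField:
    """Face-centered diffusional and electrical flux densities (mM*nm/ms).

    Values are signed along the +axis direction of each face and aligned
    with ``mesh.faces``.  ``j_e`` is None for pure-diffusion states.
    """

    species: str
    mesh: Mesh
    j_d: np.ndarray
    j_e: np.ndarray | None

    def x_component_line(self, j: int, k: int):
        """x-axis fluxes along the x line through cell row (j, k).

        Returns (x_face_positions, J_d_x, J_e_x or None).
        """
        nx, ny, nz = self.mesh.shape
        if nx < 2:
            raise ValueError("mesh has no x faces")
        i = np.arange(nx - 1)
        idx = (i * ny + j) * nz + k  # axis-0 faces come first, C-order
        x = self.mesh.ex[1:-1]
        je = None if self.j_e is None else self.j_e[idx]
        return x, self.j_d[idx], je


def flux_decomposition(state: FieldState, mesh: Mesh, species: IonSpecies | str,
                       constants: PhysicalConstants | None = None,
                       require_potential: bool = True) -> FluxField:
    """Compute J_d and J_e for one species on the mesh faces.

    Uses the same harmonic-mean face diffusivities and two-point gradients
    as the transport stepper.  Requesting the electrical flux from a state
    without a potential raises.
    """
    cns = constants or PhysicalConstants()
    if isinstance(species, str):
        sp_k = state.species[species_index(state.species, species)]
    else:
        sp_k = species
    k = species_index(state.species, sp_k.name)
    if require_potential and state.phi is None:
        raise ValueError(
            "state carries no potential (pure-diffusion output); "
            "the electrical flux is undefined")
    fg = mesh.faces
    Df = fg.harmonic(mesh.cell_diffusivity(sp_k))
    c = state.conc[k].ravel()
    j_d = -Df * (c[fg.hi] - c[fg.lo]) / fg.dist
    j_e = None
    if state.phi is not None:
        phi = state.phi.ravel()
        cbar = 0.5 * (c[fg.lo] + c[fg.hi])
        j_e = -Df * sp_k.z * cns.beta * cbar * (phi[fg.hi] - phi[fg.lo]) / fg.dist
    return FluxField(species=sp_k.name, mesh=mesh, j_d=j_d, j_e=j_e)


def divergence_check(old: FieldState, new: FieldState, mesh: Mesh,
                     bc: BoundarySpec, model: str = "pnp",
                     constants: PhysicalConstants | None = None,
                     settings=None,
                     sources: np.ndarray | None = None) -> np.ndarray:
    """Discrete balance residual of one accepted step, in mM.

    Verifies (c_new - c_old)/dt = -div(J_d + J_e) (PNP) or -div J_d (D)
    cell by cell, using the stepper's own operators; the result is scaled
    by dt/V so entries are concentration-sized.  Cells receiving interface
    sources are balanced against ``sources`` if given.
    """
    from .solvers import SolverSettings, _Discretization

    if old.conc.shape != new.conc.shape or old.conc.shape[1:] != mesh.shape:
        raise ValueError("states and mesh do not match")
    cns = constants or PhysicalConstants()
    settings = settings or SolverSettings()
    dt = new.t - old.t
    if dt <= 0:
        raise ValueError("states must be consecutive (new.t > old.t)")
    disc = _Discretization(mesh, new.species, bc, cns,
                           vesicle_open=settings.vesicle_open)
    nk = len(new.species)
    c_new = new.conc.reshape(nk, -1)
    c_old = old.conc.reshape(nk, -1)
    res = np.zeros_like(c_new)
    phi = None if new.phi is None else new.phi.ravel()
    for k in range(nk):
        net = disc.A_diff[k] @ c_new[k] + disc.b_diff[k]
        if model == "pnp":
            if phi is None:
                raise ValueError("PNP-form residual requires a potential")
            net = net + disc.drift_net(k, c_new[k], phi, settings.advection)
        if sources is not None:
            net = net + sources[k]
        res[k] = ((c_new[k] - c_old[k]) * disc.vol / dt - net) * dt / disc.vol
    return res.reshape(new.conc.shape)


# ---------------------------------------------------------------------------
# 1D Poisson-Boltzmann equilibrium oracle
# ---------------------------------------------------------------------------

@dataclass
class PoissonBoltzmannSolution:
    """Equilibrium profiles on (0, L): c_k(x) = A_k exp(-z_k e phi / kB T)."""

    x: np.ndarray
    phi: np.ndarray
    conc: np.ndarray          # (n_species, n)
    A: np.ndarray             # Boltzmann prefactors, mM
    z: np.ndarray
    beta: float

    def boltzmann_residual(self) -> float:
        """Max relative deviation from the Boltzmann relation."""
        res = 0.0
        for k in range(len(self.A)):
            model = self.A[k] * np.exp(-self.z[k] * self.beta * self.phi)
            res = max(res, float(np.abs(self.conc[k] - model).max()
                                 / max(self.A[k], 1e-300)))
        return res

    def deviation_from_uniformity(self) -> float:
        """L2 norm (over x) of the concentration deviations from their means."""
        dx = self.x[1] - self.x[0]
        dev = self.conc - self.conc.mean(axis=1, keepdims=True)
        return float(np.sqrt((dev ** 2).sum() * dx))


def poisson_boltzmann_oracle(
    mixture: dict[str, float] | list[tuple[int, float]],
    phi0: float,
    length: float = 10.0,
    constants: PhysicalConstants | None = None,
    species: list[IonSpecies] | None = None,
    n: int = 2001,
    tol: float = 1e-12,
    max_outer: int = 2000,
    damping: float = 1.0,
) -> PoissonBoltzmannSolution:
    """Stationary 1D solution with Dirichlet phi(0)=0, phi(L)=phi0 and
    zero-flux (content-conserving) concentrations.

    At equilibrium every species follows a Boltzmann distribution whose
    prefactor A_k is fixed by conservation of its initial content.  Solved
    by an outer damped fixed point on the A_k and an inner Newton iteration
    on the nonlinear Poisson equation, on its own uniform node grid
    (independent of the finite-volume transport discretization).
    """
    cns = constants or PhysicalConstants()
    if isinstance(mixture, dict):
        if species is None:
            raise ValueError("species list required with a named mixture")
        zs = np.array([sp.z for sp in species], dtype=float)
        c0 = np.array([mixture.get(sp.name, 0.0) for sp in species])
    else:
        zs = np.array([z for z, _ in mixture], dtype=float)
        c0 = np.array([c for _, c in mixture])
    if (c0 < 0).any():
        raise ValueError("initial concentrations must be nonnegative")
    if abs(float(zs @ c0)) > 1e-9:
        raise ValueError("initial mixture must be electroneutral")

    beta = cns.beta
    eps = cns.eps_bulk * cns.eps0
    x = np.linspace(0.0, length, n)
    h = x[1] - x[0]
    phi = np.linspace(0.0, phi0, n)
    A = c0.copy()

    def charge(phi_vec):
        boltz = np.exp(-np.outer(zs * beta, phi_vec))     # (nk, n)
        rho = cns.F * (zs * A) @ boltz
        drho = -cns.F * beta * ((zs ** 2) * A) @ boltz
        return boltz, rho, drho

    for _ in range(max_outer):
        # inner Newton for phi with fixed A
        for _ in range(80):
            boltz, rho, drho = charge(phi)
            r = np.zeros(n)
            r[1:-1] = eps * (phi[:-2] - 2 * phi[1:-1] + phi[2:]) / h ** 2 \
                + rho[1:-1]
            if np.abs(r).max() < 1e-10 * max(1.0, cns.F * float(c0.sum())):
                break
            ab = np.zeros((3, n - 2))
            ab[0, 1:] = eps / h ** 2
            ab[1] = -2 * eps / h ** 2 + drho[1:-1]
            ab[2, :-1] = eps / h ** 2
            dphi = sla.solve_banded((1, 1), ab, -r[1:-1])
            phi[1:-1] += dphi
        # update prefactors from content conservation
        boltz = np.exp(-np.outer(zs * beta, phi))
        integrals = np.trapezoid(boltz, x, axis=1)
        A_new = np.where(integrals > 0, c0 * length / integrals, 0.0)
        change = np.abs(A_new - A).max() / max(float(c0.max()), 1e-300)
        A = (1.0 - damping) * A + damping * A_new
        if change < tol:
            break
    else:
        raise RuntimeError("Poisson-Boltzmann fixed point did not converge")

    conc = A[:, None] * np.exp(-np.outer(zs * beta, phi))
    return PoissonBoltzmannSolution(x=x, phi=phi, conc=conc, A=A, z=zs, beta=beta)


# ---------------------------------------------------------------------------
# scalar utilities
# ---------------------------------------------------------------------------

def molecule_count(concentration: float, volume: float) -> float:
    """Number of molecules at ``concentration`` mM in ``volume`` nm^3."""
    if concentration < 0 or volume < 0:
        raise ValueError("concentration and volume must be nonnegative")
    return concentration * volume * 1e-27 * AVOGADRO


def electroneutral_complete(mixture: dict[str, float],
                            species: list[IonSpecies],
                            solve_for: str = "Cl-") -> dict[str, float]:
    """Fill in the one missing species so that sum z_k [k] = 0.

    Returns a new mixture including ``solve_for``; raises if the required
    concentration would be negative.
    """
    target = species[species_index(species, solve_for)]
    net = 0.0
    for sp_k in species:
        if sp_k.name == solve_for:
            continue
        net += sp_k.z * mixture.get(sp_k.name, 0.0)
    value = -net / target.z
    if value < 0:
        raise ValueError(
            f"electroneutrality would require negative [{solve_for}] = {value:g} mM")
    out = dict(mixture)
    out[solve_for] = value
    return out


# ---------------------------------------------------------------------------
# PNP vs D comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Paired comparison of two runs sharing mesh, ICs and schedule.

    Conventions (first run = A, second = B; canonically A = PNP, B = D):
    ``conc_ratio`` holds c_B/c_A at the reference probe and time,
    ``conc_diff`` holds c_A - c_B, and ``peak_current_ratio`` is
    min_A/min_B of the signed I_AMPA minima.  Swapping the inputs inverts
    every ratio and negates every difference.
    """

    t_eval: float
    probe: str
    probe_cell: tuple[int, int, int]
    conc_ratio: dict[str, float]
    conc_diff: dict[str, float]
    peak_current_a: float
    peak_current_b: float
    profiles: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    probe_series: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def peak_current_ratio(self) -> float:
        return self.peak_current_a / self.peak_current_b

    @property
    def peak_excess_percent(self) -> float:
        """How much more negative A's peak current is than B's, percent."""
        return (abs(self.peak_current_a) / abs(self.peak_current_b) - 1.0) * 100.0

    def excess_percent(self, species: str) -> float:
        """Relative excess of B over A at the probe, percent of A."""
        return (self.conc_ratio[species] - 1.0) * 100.0

    def summary(self) -> dict:
        d = {
            "t_eval_ms": self.t_eval,
            "probe": self.probe,
            "peak_current_a_nA": self.peak_current_a,
            "peak_current_b_nA": self.peak_current_b,
            "peak_excess_percent": self.peak_excess_percent,
        }
        for name, r in self.conc_ratio.items():
            d[f"ratio_{name}"] = r
        return d


def compare_runs(run_a, run_b, probe: str = "cleft_center",
                 probe_cell: tuple[int, int, int] | None = None,
                 t_eval: float = 0.5) -> ComparisonReport:
    """Compare two :class:`~cleftpnp.solvers.SimulationResult` objects.

    Both runs must share the mesh and snapshot/probe schedule and differ
    only in the transport model.  Canonical usage is
    ``compare_runs(pnp_run, d_run)``.
    """
    if run_a.final_state.conc.shape != run_b.final_state.conc.shape:
        raise ValueError("runs use different meshes")
    if len(run_a.times) != len(run_b.times) or not np.allclose(
            run_a.times, run_b.times):
        raise ValueError("runs use different schedules")
    mesh = run_a.mesh
    species = run_a.final_state.species

    def state_at(run, t):
        for ts, st in run.snapshots.items():
            if abs(ts - t) < 1e-9:
                return st
        if abs(run.final_state.t - t) < 1e-9:
            return run.final_state
        raise ValueError(f"no snapshot at t = {t} ms in run")

    sa = state_at(run_a, t_eval)
    sb = state_at(run_b, t_eval)
    if probe_cell is None:
        df = run_a.probes
        if not df.empty and probe in set(df["probe"]):
            probe_cell = None  # resolved through the probe table below
        else:
            raise ValueError("probe_cell required when runs carry no probe table")

    if probe_cell is None:
        # read probe values from the recorded tables
        def probe_value(run, name_q):
            df = run.probes
            sel = df[(df["probe"] == probe) & (df["quantity"] == name_q)
                     & (np.abs(df["t_ms"] - t_eval) < 1e-9)]
            return float(sel["value"].iloc[0])

        ca = {sp.name: probe_value(run_a, sp.name) for sp in species}
        cb = {sp.name: probe_value(run_b, sp.name) for sp in species}
        cell = (-1, -1, -1)
    else:
        i, j, k = probe_cell
        ca = {sp.name: float(sa.conc[ks, i, j, k])
              for ks, sp in enumerate(species)}
        cb = {sp.name: float(sb.conc[ks, i, j, k])
              for ks, sp in enumerate(species)}
        cell = probe_cell

    tiny = 1e-300
    conc_ratio = {n: cb[n] / max(ca[n], tiny) if ca[n] > 0 else np.nan
                  for n in ca}
    conc_diff = {n: ca[n] - cb[n] for n in ca}

    # center-line profiles along x at the cleft center
    rows = []
    if mesh is not None and mesh.geometry is not None:
        y_mid = 0.5 * sum(mesh.geometry.y_cleft)
        _, j, k = mesh.find_cell(0.0, y_mid, 0.0)
        for label, st in (("a", sa), ("b", sb)):
            for ks, sp in enumerate(species):
                for i, xc in enumerate(mesh.cx):
                    rows.append((label, sp.name, float(xc),
                                 float(st.conc[ks, i, j, k])))
            if st.phi is not None:
                for i, xc in enumerate(mesh.cx):
                    rows.append((label, "phi", float(xc),
                                 float(st.phi[i, j, k])))
    profiles = pd.DataFrame(rows, columns=["run", "quantity", "x_nm", "value"])

    pa = float(np.nanmin(run_a.current.I)) if len(run_a.current.I) else np.nan
    pb = float(np.nanmin(run_b.current.I)) if len(run_b.current.I) else np.nan

    series = pd.concat(
        [run_a.probes.assign(run="a"), run_b.probes.assign(run="b")],
        ignore_index=True) if not run_a.probes.empty else pd.DataFrame()

    return ComparisonReport(
        t_eval=t_eval, probe=probe, probe_cell=cell,
        conc_ratio=conc_ratio, conc_diff=conc_diff,
        peak_current_a=pa, peak_current_b=pb,
        profiles=profiles, probe_series=series,
    )
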