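"""AMPA receptor gating, transmembrane fluxes, and the vesicle interface.

The receptor is a seven-state Markov chain (closed states C0..C5 plus the
conducting state O) gated by the local glutamate concentration; the open
probability is o = [O] = 1 - sum(C0..C5).  Open receptors pass Na+ and K+
with fixed single-channel conductances; the flux densities are evaluated
locally on each mesh element of the AMPA area of the postsynaptic membrane
and applied as paired interface sources so that what leaves the cleft
enters the postsynaptic cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import (
    AMPA_FLUX_SCALE,
    CURRENT_TO_NA,
    IonSpecies,
    PhysicalConstants,
    species_index,
)
from .mesh import Mesh, Region

__all__ = [
    "MarkovParams",
    "MarkovState",
    "AmpaParams",
    "MembraneFlux",
    "CurrentTrace",
    "markov_rhs",
    "markov_rate_matrix",
    "markov_step",
    "markov_steady_state",
    "nernst_potential",
    "ampa_flux",
    "integrate_current",
    "AmpaCoupler",
    "apply_vesicle_release",
    "VesicleInterface",
]


@dataclass(frozen=True)
class MarkovParams:
    """Rate constants of the 7-state AMPA gating scheme.

    Association rates (k1p, k2p, k3p) are in mM^-1 ms^-1; all other rates
    in ms^-1.
    """

    k1p: float = 4.59
    k1m: float = 4.26
    k2p: float = 28.4
    k2m: float = 3.26
    k3p: float = 1.27
    k3m: float = 0.0457
    alpha: float = 4.24
    beta: float = 0.9
    alpha1: float = 2.89
    beta1: float = 0.0392
    alpha2: float = 0.172
    beta2: float = 7.27e-4
    alpha3: float = 0.0177
    beta3: float = 4.0e-3
    alpha4: float = 0.0168
    beta4: float = 0.1904

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"Markov rate {name!r} must be nonnegative")


@dataclass
class MarkovState:
    """Receptor state: closed-state probabilities C0..C5 (last axis).

    The conducting-state probability is the complement
    o = 1 - (C0 + ... + C5), so the seven probabilities always sum to one
    by construction.
    """

    C: np.ndarray

    @classmethod
    def resting(cls, n: int = 1) -> "MarkovState":
        C = np.zeros((n, 6))
        C[:, 0] = 1.0
        return cls(C)

    @property
    def o(self) -> np.ndarray:
        return 1.0 - self.C.sum(axis=-1)

    def validate(self, tol: float = 1e-12) -> None:
        probs = np.concatenate([self.C, self.o[..., None]], axis=-1)
        if (probs < -tol).any() or (probs > 1 + tol).any():
            raise ValueError("Markov probabilities out of [0, 1]")


def markov_rhs(C: np.ndarray, glu: float | np.ndarray,
               params: MarkovParams | None = None) -> np.ndarray:
    """Time derivatives of the closed-state probabilities C0..C5.

    ``C`` has shape (..., 6); ``glu`` is the local glutamate concentration
    in mM (scalar or broadcastable).  The open state enters through its
    complement value, and the derivative of the sum of all seven states is
    identically zero.
    """
    p = params or MarkovParams()
    glu = np.asarray(glu, dtype=float)
    if (glu < 0).any():
        raise ValueError("glutamate concentration must be nonnegative")
    C = np.asarray(C, dtype=float)
    C0, C1, C2, C3, C4, C5 = (C[..., i] for i in range(6))
    O = 1.0 - C.sum(axis=-1)
    d = np.empty_like(C)
    d[..., 0] = -p.k1p * glu * C0 + p.k1m * C1
    d[..., 1] = (p.k1p * glu * C0 - (p.k1m + p.k2p * glu + p.alpha1) * C1
                 + p.k2m * C2 + p.beta1 * C3)
    d[..., 2] = (p.k2p * glu * C1 - (p.k2m + p.alpha + p.alpha2) * C2
                 + p.beta * O + p.beta2 * C4)
    d[..., 3] = p.alpha1 * C1 - (p.beta1 + p.k3p * glu) * C3 + p.k3m * C4
    d[..., 4] = (p.k3p * glu * C3 + p.alpha2 * C2
                 - (p.k3m + p.beta2 + p.alpha4) * C4 + p.beta4 * C5)
    d[..., 5] = p.alpha3 * O + p.alpha4 * C4 - (p.beta3 + p.beta4) * C5
    return d


def markov_rate_matrix(glu: float, params: MarkovParams | None = None) -> np.ndarray:
    """Generator matrix Q of the full 7-state chain, dp/dt = Q p.

    State order: [C0, C1, C2, C3, C4, C5, O].  Used for steady-state
    (null-space) computations.
    """
    p = params or MarkovParams()
    if glu < 0:
        raise ValueError("glutamate concentration must be nonnegative")
    Q = np.zeros((7, 7))
    transitions = [
        (0, 1, p.k1p * glu), (1, 0, p.k1m),
        (1, 2, p.k2p * glu), (2, 1, p.k2m),
        (1, 3, p.alpha1), (3, 1, p.beta1),
        (2, 6, p.alpha), (6, 2, p.beta),
        (2, 4, p.alpha2), (4, 2, p.beta2),
        (3, 4, p.k3p * glu), (4, 3, p.k3m),
        (4, 5, p.alpha4), (5, 4, p.beta4),
        (6, 5, p.alpha3), (5, 6, p.beta3),
    ]
    for i, j, rate in transitions:
        Q[j, i] += rate
        Q[i, i] -= rate
    return Q


def markov_steady_state(glu: float, params: MarkovParams | None = None) -> np.ndarray:
    """Stationary distribution of the chain at fixed glutamate (7-vector)."""
    Q = markov_rate_matrix(glu, params)
    A = np.vstack([Q, np.ones(7)])
    b = np.zeros(8)
    b[-1] = 1.0
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol


def markov_step(C: np.ndarray, glu: float | np.ndarray, dt: float,
                substep: float = 0.001,
                params: MarkovParams | None = None) -> np.ndarray:
    """Integrate the gating ODEs over ``dt`` with glutamate held fixed.

    Classical RK4 with a local substep (default 0.001 ms).  ``dt`` must be
    a multiple of the substep.
    """
    if substep <= 0:
        raise ValueError("substep must be positive")
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    C = np.asarray(C, dtype=float).copy()
    if dt == 0:
        return C
    n = int(round(dt / substep))
    if abs(n * substep - dt) > 1e-12 * max(1.0, dt) or n < 1:
        raise ValueError("dt must be a positive multiple of the substep")
    h = dt / n
    for _ in range(n):
        k1 = markov_rhs(C, glu, params)
        k2 = markov_rhs(C + 0.5 * h * k1, glu, params)
        k3 = markov_rhs(C + 0.5 * h * k2, glu, params)
        k4 = markov_rhs(C + h * k3, glu, params)
        C += (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    # guard against harmless roundoff excursions
    np.clip(C, 0.0, 1.0, out=C)
    return C


def nernst_potential(z: int, c_ext: float | np.ndarray, c_int: float | np.ndarray,
                     constants: PhysicalConstants | None = None) -> float | np.ndarray:
    """Nernst (reversal) potential (kB*T)/(z*e) * ln(c_ext/c_int), in mV."""
    cns = constants or PhysicalConstants()
    c_ext = np.asarray(c_ext, dtype=float)
    c_int = np.asarray(c_int, dtype=float)
    if (c_ext <= 0).any() or (c_int <= 0).any():
        raise ValueError("Nernst potential requires strictly positive concentrations")
    out = (cns.thermal_voltage / z) * np.log(c_ext / c_int)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AmpaParams:
    """AMPA receptor population parameters.

    N_AMPA receptors are spread evenly over the w_a x w_a receptor area;
    g_Na and g_K are single-channel conductances in pS.
    """

    N_AMPA: float = 200.0
    g_Na: float = 25.0
    g_K: float = 15.0
    w_a: float = 140.0

    def __post_init__(self) -> None:
        if self.N_AMPA < 0 or self.g_Na < 0 or self.g_K < 0 or self.w_a <= 0:
            raise ValueError("invalid AMPA parameters")


@dataclass
class MembraneFlux:
    """Per-AMPA-face molar flux densities, mM*nm/ms.

    Sign convention: the flux formula g*o*(v - v0) gives a (negative)
    inward current for the resting driving force on Na+; a negative J for a
    cation means that species moves from the cleft into the postsynaptic
    cell.
    """

    J_Na: np.ndarray
    J_K: np.ndarray
    v: np.ndarray
    v0_Na: np.ndarray
    v0_K: np.ndarray


def ampa_flux(o: np.ndarray, v: np.ndarray, v0_Na: np.ndarray, v0_K: np.ndarray,
              params: AmpaParams | None = None,
              constants: PhysicalConstants | None = None) -> MembraneFlux:
    """Na+ and K+ flux densities through the AMPA receptors.

    J_k = N_AMPA/(F w_a^2) * g_k * o * (v - v0_k), converted to the
    internal mM*nm/ms flux unit.  ``o`` must lie in [0, 1].
    """
    p = params or AmpaParams()
    cns = constants or PhysicalConstants()
    o = np.asarray(o, dtype=float)
    if (o < -1e-12).any() or (o > 1 + 1e-12).any():
        raise ValueError("open probability must lie in [0, 1]")
    v = np.asarray(v, dtype=float)
    pref = AMPA_FLUX_SCALE * p.N_AMPA / (cns.F * p.w_a ** 2)
    J_Na = pref * p.g_Na * o * (v - np.asarray(v0_Na))
    J_K = pref * p.g_K * o * (v - np.asarray(v0_K))
    return MembraneFlux(J_Na=J_Na, J_K=J_K, v=v,
                        v0_Na=np.broadcast_to(np.asarray(v0_Na, float), J_Na.shape).copy(),
                        v0_K=np.broadcast_to(np.asarray(v0_K, float), J_K.shape).copy())


def integrate_current(flux: MembraneFlux, mesh: Mesh,
                      constants: PhysicalConstants | None = None) -> float:
    """Total AMPA receptor current, nA: surface integral of F*(J_Na+J_K)."""
    cns = constants or PhysicalConstants()
    if len(mesh.ampa_ix) == 0:
        raise ValueError("mesh has no AMPA zone")
    areas = mesh.wx[mesh.ampa_ix] * mesh.wz[mesh.ampa_iz]
    total = np.sum((flux.J_Na + flux.J_K) * areas)
    return float(CURRENT_TO_NA * cns.F * total)


@dataclass
class CurrentTrace:
    """AMPA current time series (times in ms, current in nA)."""

    t: np.ndarray
    I: np.ndarray

    @property
    def peak(self) -> float:
        """Signed minimum of the trace (peak inward current)."""
        return float(self.I.min())


@dataclass
class VesicleInterface:
    """Vesicle release interface summary.

    ``open=True`` couples the vesicle to the cleft through the opening
    cells (restricted diffusion, like the cleft); when blocked, the vesicle
    is a closed subdomain and its content is conserved.
    """

    open: bool
    n_opening_cells: int
    opening_cross_section: float  # nm^2


def apply_vesicle_release(mesh: Mesh, open: bool = True) -> VesicleInterface:
    """Describe (and validate) the vesicle release pathway on a mesh."""
    opening = mesh.region == Region.VESICLE_OPENING
    n = int(opening.sum())
    if n == 0:
        raise ValueError("mesh has no vesicle opening")
    ii, jj, kk = np.nonzero(opening)
    area = float(np.sum(mesh.wx[np.unique(ii)]) * np.sum(mesh.wz[np.unique(kk)]))
    return VesicleInterface(open=open, n_opening_cells=n, opening_cross_section=area)


@dataclass
class FluxEval:
    """One evaluation of the AMPA interface fluxes and their sensitivities.

    Per AMPA face and per conducted species (Na+, K+): the molar flux
    density J (mM*nm/ms), its derivatives with respect to the local
    extracellular and intracellular concentrations and the membrane
    potential, and the local v / Nernst potentials.  Used by the implicit
    steppers, which treat the flux as an internal boundary condition
    evaluated at the end-of-step fields.
    """

    o: np.ndarray
    v: np.ndarray
    J: dict[str, np.ndarray]
    dJ_dce: dict[str, np.ndarray]
    dJ_dci: dict[str, np.ndarray]
    dJ_dv: dict[str, np.ndarray]
    v0: dict[str, np.ndarray]


class AmpaCoupler:
    """Receptor coupling for the PDE steppers.

    Operator splitting applies to the gating only: each transport step
    first integrates the Markov chains with the local glutamate sampled at
    the cleft cell adjacent to each AMPA membrane face (frozen over the
    step), yielding the open probability o.  The Na+/K+ fluxes themselves
    are then internal boundary conditions of the implicit transport solve,
    evaluated at the end-of-step concentrations and potential — an explicit
    flux at this receptor density would overdraw the thin cleft within one
    0.02 ms step.

    Fluxes are paired: the cleft cell below the postsynaptic membrane loses
    exactly what the intracellular cell above it gains, so transmembrane
    transport conserves mass globally.  For the pure-diffusion model the
    membrane potential is fixed at the holding potential; the Nernst
    potentials always use the local (diffusing) concentrations.
    """

    #: Nernst arguments are clamped below this concentration (mM) so the
    #: implicit flux stays finite and smooth while remaining strongly
    #: restoring as a local concentration approaches zero
    c_clamp: float = 1e-6

    def __init__(self, mesh: Mesh, species: list[IonSpecies],
                 ampa: AmpaParams | None = None,
                 markov: MarkovParams | None = None,
                 constants: PhysicalConstants | None = None,
                 model: str = "pnp", holding_potential: float = -70.0,
                 substep: float = 0.001):
        if len(mesh.ampa_ix) == 0:
            raise ValueError("mesh has no AMPA zone")
        self.mesh = mesh
        self.species = species
        self.ampa = ampa or AmpaParams()
        self.markov = markov or MarkovParams()
        self.constants = constants or PhysicalConstants()
        self.model = model
        self.holding_potential = holding_potential
        self.substep = substep
        self.i_na = species_index(species, "Na+")
        self.i_k = species_index(species, "K+")
        self.i_glu = species_index(species, "Glu-")
        self.idx = {"Na+": self.i_na, "K+": self.i_k}
        self.g = {"Na+": self.ampa.g_Na, "K+": self.ampa.g_K}
        ix, iz = mesh.ampa_ix, mesh.ampa_iz
        self.ext_cells = mesh.flat(ix, mesh.j_cleft_top, iz)
        self.int_cells = mesh.flat(ix, mesh.j_intra_post, iz)
        self.areas = mesh.wx[ix] * mesh.wz[iz]
        self._pref = (AMPA_FLUX_SCALE * self.ampa.N_AMPA
                      / (self.constants.F * self.ampa.w_a ** 2))

    def advance_markov(self, state, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Integrate the gating ODEs over dt; returns (markov_new, o)."""
        conc = state.conc.reshape(len(self.species), -1)
        glu = np.maximum(conc[self.i_glu, self.ext_cells], 0.0)
        markov_new = markov_step(state.markov, glu, dt, self.substep, self.markov)
        return markov_new, 1.0 - markov_new.sum(axis=1)

    def skip_masks(self, c_flat: np.ndarray) -> dict[str, np.ndarray]:
        """Faces whose flux is skipped this step (nonpositive start value)."""
        masks = {}
        for name, k in self.idx.items():
            ce = c_flat[k, self.ext_cells]
            ci = c_flat[k, self.int_cells]
            skip = (ce <= 0.0) | (ci <= 0.0)
            if skip.any():
                warnings.warn(
                    f"nonpositive local [{name}] at {int(skip.sum())} AMPA "
                    "face(s); their flux is skipped for this step",
                    RuntimeWarning)
            masks[name] = skip
        return masks

    def flux_eval(self, c_flat: np.ndarray, phi_flat: np.ndarray | None,
                  o: np.ndarray,
                  skip: dict[str, np.ndarray] | None = None) -> FluxEval:
        """Fluxes and sensitivities at given fields (implicit evaluation)."""
        if self.model == "pnp":
            if phi_flat is None:
                raise ValueError("PNP coupling requires a potential field")
            v = phi_flat[self.int_cells] - phi_flat[self.ext_cells]
        else:
            v = np.full(len(self.ext_cells), float(self.holding_potential))
        T = self.constants.thermal_voltage  # z = +1 for both Na+ and K+
        J, dce, dci, dv, v0s = {}, {}, {}, {}, {}
        for name, k in self.idx.items():
            ce = np.maximum(c_flat[k, self.ext_cells], self.c_clamp)
            ci = np.maximum(c_flat[k, self.int_cells], self.c_clamp)
            live = ~skip[name] if skip is not None else np.ones(len(ce), bool)
            v0 = T * np.log(ce / ci)
            gP = self._pref * self.g[name] * o
            J[name] = np.where(live, gP * (v - v0), 0.0)
            # derivatives vanish where the clamp is active (or face skipped)
            de = (ce > self.c_clamp) & live
            di = (ci > self.c_clamp) & live
            dce[name] = np.where(de, -gP * T / ce, 0.0)
            dci[name] = np.where(di, gP * T / ci, 0.0)
            dv[name] = np.where(live, gP, 0.0)
            v0s[name] = np.where(live, v0, np.nan)
        return FluxEval(o=o, v=v, J=J, dJ_dce=dce, dJ_dci=dci, dJ_dv=dv, v0=v0s)

    def sources(self, fe: FluxEval, n_cells: int) -> np.ndarray:
        """Molar source rates (n_species, n_cells) in mM*nm^3/ms.

        J < 0 means the species enters the postsynaptic cell, so the cleft
        cell gains +J*A and the intracellular cell gains -J*A.
        """
        out = np.zeros((len(self.species), n_cells))
        for name, k in self.idx.items():
            np.add.at(out[k], self.ext_cells, fe.J[name] * self.areas)
            np.add.at(out[k], self.int_cells, -fe.J[name] * self.areas)
        return out

    def membrane_flux(self, fe: FluxEval) -> MembraneFlux:
        return MembraneFlux(J_Na=fe.J["Na+"], J_K=fe.J["K+"], v=fe.v,
                            v0_Na=fe.v0["Na+"], v0_K=fe.v0["K+"])

    def current(self, fe: FluxEval) -> float:
        """Total AMPA current of one flux evaluation, nA."""
        return integrate_current(self.membrane_flux(fe), self.mesh,
                                 self.constants)
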