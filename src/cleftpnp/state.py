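"""Simulation state: concentration fields, potential, receptor states."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import IonSpecies, PhysicalConstants, default_species
from .mesh import Mesh, Region

__all__ = ["InitialConditions", "FieldState", "initialize_state"]

_ELECTRONEUTRAL_TOL = 1e-9


@dataclass(frozen=True)
class InitialConditions:
    """Per-region initial concentration mixtures, mM.

    Each mixture maps species name -> concentration and must be
    electroneutral (sum of z_k [k] = 0) for the given species list.
    The defaults are physiological: extracellular Na-rich, intracellular
    K-rich, and a vesicle loaded with glutamate balanced by Na+ and K+.
    """

    extracellular: dict[str, float] = field(default_factory=lambda: {
        "Na+": 100.0, "K+": 4.0, "Ca2+": 1.4, "Cl-": 106.8, "Glu-": 0.0,
    })
    intracellular: dict[str, float] = field(default_factory=lambda: {
        "Na+": 12.0, "K+": 125.0, "Ca2+": 0.0001, "Cl-": 137.0002, "Glu-": 0.0,
    })
    vesicle: dict[str, float] = field(default_factory=lambda: {
        "Na+": 145.0, "K+": 5.0, "Ca2+": 0.0, "Cl-": 0.0, "Glu-": 150.0,
    })

    def mixture(self, region_kind: str) -> dict[str, float]:
        return getattr(self, region_kind)

    def validate(self, species: list[IonSpecies]) -> None:
        for kind in ("extracellular", "intracellular", "vesicle"):
            mix = self.mixture(kind)
            net = 0.0
            for sp in species:
                c = mix.get(sp.name, 0.0)
                if c < 0:
                    raise ValueError(f"negative concentration for {sp.name} in {kind}")
                net += sp.z * c
            if abs(net) > _ELECTRONEUTRAL_TOL:
                raise ValueError(
                    f"{kind} mixture is not electroneutral: sum z_k [k] = {net:g} mM"
                )

    def as_vector(self, kind: str, species: list[IonSpecies]) -> np.ndarray:
        mix = self.mixture(kind)
        return np.array([mix.get(sp.name, 0.0) for sp in species])


@dataclass
class FieldState:
    """Fields at one time point.

    ``conc`` has shape (n_species, nx, ny, nz) in mM; ``phi`` has shape
    (nx, ny, nz) in mV (None for pure-diffusion states); ``markov`` holds
    the closed-state probabilities C0..C5 per AMPA face, shape
    (n_faces, 6), with the open probability defined as the complement.
    """

    t: float
    conc: np.ndarray
    phi: np.ndarray | None
    markov: np.ndarray | None = None
    species: list[IonSpecies] = field(default_factory=default_species)

    def copy(self) -> "FieldState":
        return FieldState(
            t=self.t,
            conc=self.conc.copy(),
            phi=None if self.phi is None else self.phi.copy(),
            markov=None if self.markov is None else self.markov.copy(),
            species=self.species,
        )

    def charge_density(self, constants: PhysicalConstants) -> np.ndarray:
        """rho = F * sum_k z_k [k], C/m^3, shape (nx, ny, nz)."""
        z = np.array([sp.z for sp in self.species])
        return constants.F * np.einsum("k,kxyz->xyz", z, self.conc)

    def open_probability(self) -> np.ndarray:
        """Per-AMPA-face open probability o = 1 - sum(C0..C5)."""
        if self.markov is None:
            return np.empty(0)
        return 1.0 - self.markov.sum(axis=1)

    def total_moles(self, mesh: Mesh) -> np.ndarray:
        """Per-species total content, mM*nm^3 (1e-27 mol)."""
        return np.einsum("kxyz,xyz->k", self.conc, mesh.volumes)


def initialize_state(
    mesh: Mesh,
    ics: InitialConditions,
    holding_potential: float = -70.0,
    species: list[IonSpecies] | None = None,
    constants: PhysicalConstants | None = None,
    with_phi: bool = True,
) -> FieldState:
    """Initial fields from per-region mixtures.

    Concentrations are set by region (vesicle and its opening get the
    vesicle mixture; cleft and extracellular cells get the extracellular
    mixture; intracellular cells the intracellular mixture; membrane cells
    carry no mobile ions).  The potential starts at 0 mV extracellularly and
    at the holding potential in the cells (it is recomputed from Poisson
    before the first step of a PNP run).  All receptors start in the fully
    unbound closed state C0.
    """
    species = species if species is not None else default_species()
    ics.validate(species)
    nx, ny, nz = mesh.shape
    conc = np.zeros((len(species), nx, ny, nz))
    phi = np.zeros((nx, ny, nz))
    r = mesh.region

    vec_e = ics.as_vector("extracellular", species)
    vec_i = ics.as_vector("intracellular", species)
    vec_v = ics.as_vector("vesicle", species)
    masks = {
        "e": (r == Region.EXTRACELLULAR) | (r == Region.CLEFT),
        "i": (r == Region.INTRA_PRE) | (r == Region.INTRA_POST),
        "v": (r == Region.VESICLE) | (r == Region.VESICLE_OPENING),
    }
    for k in range(len(species)):
        conc[k][masks["e"]] = vec_e[k]
        conc[k][masks["i"]] = vec_i[k]
        conc[k][masks["v"]] = vec_v[k]
    # membrane cells keep 0 (no mobile ions in the lipid; frozen by D = 0)

    phi[masks["i"] | (r == Region.VESICLE)] = holding_potential
    phi[np.isin(r, Region.MEMBRANES)] = 0.5 * holding_potential

    n_faces = len(mesh.ampa_ix)
    markov = None
    if n_faces:
        markov = np.zeros((n_faces, 6))
        markov[:, 0] = 1.0  # C0 = 1
    return FieldState(t=0.0, conc=conc, phi=phi if with_phi else None,
                      markov=markov, species=species)
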