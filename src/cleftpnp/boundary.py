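"""Boundary conditions on the outer domain boundary.

Internal walls (membranes, vesicle wall) are handled by zero face
diffusivities, not by this module.  A :class:`BoundarySpec` maps each outer
boundary face to either a Dirichlet value or a homogeneous Neumann
condition, independently for the potential and the concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .constants import IonSpecies
from .mesh import Mesh, Region
from .state import InitialConditions

__all__ = ["BoundarySpec", "BoundaryArrays"]

# side ids in FaceGeometry: 0..5 = x-, x+, y-, y+, z-, z+


@dataclass
class BoundaryArrays:
    """Per-boundary-face condition arrays (NaN marks homogeneous Neumann)."""

    phi: np.ndarray           # (n_bfaces,)
    conc: np.ndarray          # (n_species, n_bfaces)

    @property
    def has_phi_dirichlet(self) -> bool:
        return bool(np.isfinite(self.phi).any())


@dataclass
class BoundarySpec:
    """Outer boundary conditions.

    ``kind='synapse'`` (default): Dirichlet for both the potential and the
    concentrations on the whole outer boundary; faces adjacent to
    extracellular cells carry 0 mV and the extracellular mixture, faces
    adjacent to intracellular cells carry the holding potential and the
    intracellular mixture.

    ``kind='closed'``: homogeneous Neumann everywhere (isolated box).

    ``kind='phi_ends'``: Dirichlet potential ``phi_left``/``phi_right`` on
    the two x-faces only, homogeneous Neumann for everything else (the 1D
    equilibrium setup).
    """

    kind: Literal["synapse", "closed", "phi_ends"] = "synapse"
    ics: InitialConditions | None = None
    phi_extracellular: float = 0.0
    phi_intracellular: float = -70.0
    phi_left: float = 0.0
    phi_right: float = 0.0

    @classmethod
    def synapse_default(cls, ics: InitialConditions,
                        holding_potential: float = -70.0) -> "BoundarySpec":
        return cls(kind="synapse", ics=ics, phi_intracellular=holding_potential)

    @classmethod
    def closed(cls) -> "BoundarySpec":
        return cls(kind="closed")

    @classmethod
    def phi_ends(cls, phi_left: float, phi_right: float) -> "BoundarySpec":
        return cls(kind="phi_ends", phi_left=phi_left, phi_right=phi_right)

    def build(self, mesh: Mesh, species: list[IonSpecies]) -> BoundaryArrays:
        fg = mesh.faces
        nb = len(fg.b_cell)
        nk = len(species)
        phi = np.full(nb, np.nan)
        conc = np.full((nk, nb), np.nan)
        if self.kind == "closed":
            return BoundaryArrays(phi=phi, conc=conc)
        if self.kind == "phi_ends":
            phi[fg.b_side == 0] = self.phi_left
            phi[fg.b_side == 1] = self.phi_right
            return BoundaryArrays(phi=phi, conc=conc)
        if self.kind == "synapse":
            if self.ics is None:
                raise ValueError("synapse boundary conditions require initial mixtures")
            extra = np.isin(fg.b_region, (Region.EXTRACELLULAR, Region.CLEFT))
            intra = np.isin(
                fg.b_region,
                (Region.INTRA_PRE, Region.INTRA_POST, Region.VESICLE),
            )
            phi[extra] = self.phi_extracellular
            phi[intra] = self.phi_intracellular
            ce = self.ics.as_vector("extracellular", species)
            ci = self.ics.as_vector("intracellular", species)
            for k in range(nk):
                conc[k, extra] = ce[k]
                conc[k, intra] = ci[k]
            # membrane cells never touch the outer boundary in valid
            # geometries; if they do, leave them Neumann (no transport there)
            return BoundaryArrays(phi=phi, conc=conc)
        raise ValueError(f"unknown boundary kind {self.kind!r}")
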