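"""Physical constants and ion species in the nm-ms-mM-mV unit system.

All quantities in this package live in a single consistent unit system:
lengths in nm, times in ms, concentrations in mM, potentials in mV.  The
convenient coincidences that make this work without conversion factors:

* 1 mM = 1 mol/m^3, so ``F * z * c`` (F in C/mol, c in mM) is a charge
  density in C/m^3.
* With the vacuum permittivity expressed in fF/m (8854), the Poisson
  equation ``div(eps_r eps0 grad phi) = -rho`` holds numerically when
  gradients are taken per nm, phi is in mV and rho is in C/m^3.
* With the Boltzmann constant in mJ/K and the elementary charge in C,
  ``e * phi / (kB * T)`` is dimensionless for phi in mV, and the thermal
  voltage ``kB * T / e`` comes out in mV (~26.7 mV at 310 K).

Molar amounts are carried as mM * nm^3 (1e-27 mol); the conversion of the
single-channel flux formula (pS, mV, C/mol, nm^2) into a molar flux density
in mM*nm/ms is the factor ``AMPA_FLUX_SCALE`` = 1e9, and a current assembled
as ``F * J * area`` (J in mM*nm/ms, area in nm^2) is in units of 1e-24 A,
i.e. ``CURRENT_TO_NA`` = 1e-15 converts it to nA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "PhysicalConstants",
    "IonSpecies",
    "default_species",
    "species_index",
    "AMPA_FLUX_SCALE",
    "CURRENT_TO_NA",
    "AVOGADRO",
]

#: Avogadro's number (1/mol).
AVOGADRO = 6.02214076e23

#: Converts N_AMPA*g*o*(v-v0)/(F*w_a^2) evaluated in (pS, mV, C/mol, nm^2)
#: into a molar flux density in mM*nm/ms.
AMPA_FLUX_SCALE = 1e9

#: Converts F * J * A (C/mol * mM*nm/ms * nm^2) into nA.
CURRENT_TO_NA = 1e-15


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants in the nm-ms-mM-mV system.

    Attributes
    ----------
    F : Faraday constant, C/mol.
    e : elementary charge, C.
    kB : Boltzmann constant, mJ/K (so that kB*T/e is in mV).
    T : absolute temperature, K.
    eps0 : vacuum permittivity, fF/m (numerically consistent with the
        nm-mV Poisson equation and charge densities in C/m^3).
    eps_bulk : relative permittivity of the aqueous domains.
    eps_mem : relative permittivity of the lipid membrane.
    """

    F: float = 96485.3365
    e: float = 1.60217662e-19
    kB: float = 1.380649e-20
    T: float = 310.0
    eps0: float = 8854.0
    eps_bulk: float = 80.0
    eps_mem: float = 2.0

    def __post_init__(self) -> None:
        for name in ("F", "e", "kB", "T", "eps0", "eps_bulk", "eps_mem"):
            if getattr(self, name) <= 0:
                raise ValueError(f"physical constant {name!r} must be positive")

    @property
    def beta(self) -> float:
        """e/(kB*T): inverse thermal voltage, 1/mV."""
        return self.e / (self.kB * self.T)

    @property
    def thermal_voltage(self) -> float:
        """kB*T/e in mV (~26.71 mV at 310 K)."""
        return self.kB * self.T / self.e


@dataclass(frozen=True)
class IonSpecies:
    """One tracked ionic species.

    Attributes
    ----------
    name : species label (Na+, K+, Ca2+, Cl-, Glu-).
    z : integer valence.
    D_bulk : diffusion coefficient in the unrestricted aqueous domains,
        nm^2/ms.
    cleft_factor : divisor kappa applied to D_bulk inside the synaptic
        cleft and the vesicle opening (restricted diffusion).
    D_membrane : diffusion coefficient in the lipid membrane (always 0).
    """

    name: str
    z: int
    D_bulk: float
    cleft_factor: float = 2.56
    D_membrane: float = field(default=0.0)

    def __post_init__(self) -> None:
        # physiological species carry -1, +1 or +2; z = 0 is admitted so a
        # chargeless variant can verify that drift vanishes identically
        if self.z not in (-2, -1, 0, 1, 2):
            raise ValueError(f"unsupported valence z={self.z} for {self.name}")
        if self.D_bulk <= 0:
            raise ValueError("D_bulk must be positive")
        if self.cleft_factor <= 0:
            raise ValueError("cleft reduction factor kappa must be positive")
        if self.D_membrane != 0.0:
            raise ValueError("membrane diffusion coefficient is fixed at zero")

    @property
    def D_cleft(self) -> float:
        """Effective diffusion coefficient in the cleft / vesicle opening."""
        return self.D_bulk / self.cleft_factor

    def with_kappa(self, kappa: float) -> "IonSpecies":
        return replace(self, cleft_factor=kappa)


def default_species(kappa: float = 2.56) -> list[IonSpecies]:
    """The five tracked species with their default diffusion coefficients.

    D values are free-solution coefficients in nm^2/ms; ``kappa`` is the
    common reduction factor for the cleft and vesicle opening.
    """
    return [
        IonSpecies("Na+", 1, 1.33e6, kappa),
        IonSpecies("K+", 1, 1.96e6, kappa),
        IonSpecies("Ca2+", 2, 0.71e6, kappa),
        IonSpecies("Cl-", -1, 2.03e6, kappa),
        IonSpecies("Glu-", -1, 0.86e6, kappa),
    ]


def species_index(species: list[IonSpecies], name: str) -> int:
    for i, sp in enumerate(species):
        if sp.name == name:
            return i
    raise KeyError(f"no species named {name!r}")
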