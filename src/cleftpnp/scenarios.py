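"""Scenario configuration, default parameter packs, sweeps and fixtures.

A :class:`ScenarioConfig` bundles everything one simulation needs: the
geometry, physical constants, species, initial mixtures, receptor
parameters, solver settings, mesh grading, snapshot schedule and probe
positions.  The defaults reproduce the reference parameter pack (cleft
height 15 nm, 200 AMPA receptors, 150 mM vesicle glutamate, kappa 2.56,
dt 0.02 ms).  Configs round-trip through YAML/JSON; an empty file yields
the full default pack.

The whole pipeline is deterministic — there is no random number generation
anywhere in the model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .boundary import BoundarySpec
from .constants import IonSpecies, PhysicalConstants
from .geometry import Geometry
from .mesh import Mesh, MeshResolution, build_interval_mesh, build_mesh
from .receptors import AmpaCoupler, AmpaParams, MarkovParams, markov_step
from .solvers import SimulationResult, SolverSettings, run_simulation, run_to_steady_state
from .state import FieldState, InitialConditions, initialize_state

__all__ = [
    "ScenarioConfig",
    "SweepSpec",
    "Demo1DConfig",
    "MarkovPulseFixture",
    "load_config",
    "dump_defaults",
    "make_demo_1d",
    "make_demo_1d_suite",
    "run_scenario",
    "run_comparison",
    "run_sweep",
    "generate_fixture",
    "config_hash",
]

#: display times of the reference runs; the active schedule keeps those
#: that are multiples of dt and not beyond the simulated duration
_DISPLAY_TIMES = (0.001, 0.05, 0.1, 0.2, 0.3, 0.5)

_DEFAULT_DIFFUSION = {
    "Na+": 1.33e6, "K+": 1.96e6, "Ca2+": 0.71e6, "Cl-": 2.03e6, "Glu-": 0.86e6,
}
_VALENCES = {"Na+": 1, "K+": 1, "Ca2+": 2, "Cl-": -1, "Glu-": -1}


@dataclass
class ScenarioConfig:
    """One complete, self-validating simulation scenario."""

    model: str = "pnp"
    duration: float = 0.5
    geometry: Geometry = field(default_factory=Geometry)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    kappa: float = 2.56
    diffusion: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DIFFUSION))
    ics: InitialConditions = field(default_factory=InitialConditions)
    ampa: AmpaParams = field(default_factory=AmpaParams)
    markov: MarkovParams = field(default_factory=MarkovParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    resolution: MeshResolution = field(default_factory=MeshResolution.coarse)
    holding_potential: float = -70.0
    markov_substep: float = 0.001
    snapshot_times: tuple[float, ...] | None = None
    probes: dict[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.model not in ("pnp", "d"):
            raise ValueError("model must be 'pnp' or 'd'")
        if self.duration < 0:
            raise ValueError("duration must be nonnegative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for name, d in self.diffusion.items():
            if name not in _VALENCES:
                raise ValueError(f"unknown species {name!r}")
            if d <= 0:
                raise ValueError(f"diffusion coefficient for {name} must be positive")
        self.ics.validate(self.species())
        # AMPA area width follows the geometry
        if self.ampa.w_a != self.geometry.w_a:
            self.ampa = replace(self.ampa, w_a=self.geometry.w_a)

    # -- derived pieces ----------------------------------------------------
    def species(self) -> list[IonSpecies]:
        return [IonSpecies(name, _VALENCES[name], D, self.kappa)
                for name, D in self.diffusion.items()]

    def active_snapshot_times(self) -> tuple[float, ...]:
        if self.snapshot_times is not None:
            times = tuple(self.snapshot_times)
        else:
            dt = self.solver.dt
            times = tuple(
                t for t in _DISPLAY_TIMES
                if t <= self.duration + 1e-12
                and abs(round(t / dt) * dt - t) < 1e-9)
        if self.duration > 0 and self.duration not in times:
            times = times + (self.duration,)
        return times

    def default_probes(self) -> dict[str, tuple[float, float, float]]:
        g = self.geometry
        y0, y1 = g.y_cleft
        y_mid = 0.5 * (y0 + y1)
        return {
            "cleft_center": (0.0, y_mid, 0.0),
            "near_post": (0.0, y1 - 0.25 * g.h / self.resolution.n_cleft, 0.0),
            "left_60": (-60.0, y_mid, 0.0),
        }

    # -- builders ----------------------------------------------------------
    def build_mesh(self) -> Mesh:
        return build_mesh(self.geometry, self.resolution)

    def build_state(self, mesh: Mesh) -> FieldState:
        return initialize_state(mesh, self.ics, self.holding_potential,
                                self.species(), self.constants)

    def build_bc(self) -> BoundarySpec:
        return BoundarySpec.synapse_default(self.ics, self.holding_potential)

    def build_coupler(self, mesh: Mesh, model: str | None = None) -> AmpaCoupler:
        return AmpaCoupler(mesh, self.species(), self.ampa, self.markov,
                           self.constants, model or self.model,
                           self.holding_potential, self.markov_substep)

    def probe_cells(self, mesh: Mesh) -> list[tuple[str, tuple[int, int, int]]]:
        probes = self.probes or self.default_probes()
        return [(name, mesh.find_cell(*pos)) for name, pos in probes.items()]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "duration_ms": self.duration,
            "geometry": dataclasses.asdict(self.geometry),
            "constants": dataclasses.asdict(self.constants),
            "kappa": self.kappa,
            "diffusion_nm2_per_ms": dict(self.diffusion),
            "initial_conditions_mM": {
                "extracellular": dict(self.ics.extracellular),
                "intracellular": dict(self.ics.intracellular),
                "vesicle": dict(self.ics.vesicle),
            },
            "ampa": {"N_AMPA": self.ampa.N_AMPA, "g_Na_pS": self.ampa.g_Na,
                     "g_K_pS": self.ampa.g_K},
            "markov": dataclasses.asdict(self.markov),
            "solver": {
                "dt_ms": self.solver.dt,
                "newton_tol": self.solver.newton_tol,
                "newton_max_iter": self.solver.newton_max_iter,
                "advection": self.solver.advection,
                "vesicle_open": self.solver.vesicle_open,
            },
            "resolution": dataclasses.asdict(self.resolution),
            "holding_potential_mV": self.holding_potential,
            "markov_substep_ms": self.markov_substep,
            "snapshot_times_ms": (None if self.snapshot_times is None
                                  else list(self.snapshot_times)),
            "probes_nm": (None if self.probes is None
                          else {k: list(v) for k, v in self.probes.items()}),
            "units": {"length": "nm", "time": "ms", "concentration": "mM",
                      "potential": "mV", "current": "nA",
                      "conductance": "pS"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d or {})
        d.pop("units", None)
        known = {
            "model", "duration_ms", "geometry", "constants", "kappa",
            "diffusion_nm2_per_ms", "initial_conditions_mM", "ampa", "markov",
            "solver", "resolution", "holding_potential_mV",
            "markov_substep_ms", "snapshot_times_ms", "probes_nm",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

        def sub(name, cls_, key_map=None):
            raw = dict(d.get(name) or {})
            if key_map:
                raw = {key_map.get(k, k): v for k, v in raw.items()}
            fields = {f.name for f in dataclasses.fields(cls_)}
            bad = set(raw) - fields
            if bad:
                raise ValueError(f"unknown keys in {name!r}: {sorted(bad)}")
            return cls_(**raw)

        ics_raw = d.get("initial_conditions_mM") or {}
        bad = set(ics_raw) - {"extracellular", "intracellular", "vesicle"}
        if bad:
            raise ValueError(f"unknown keys in initial conditions: {sorted(bad)}")
        base_ics = InitialConditions()
        ics = InitialConditions(
            extracellular={**base_ics.extracellular,
                           **(ics_raw.get("extracellular") or {})},
            intracellular={**base_ics.intracellular,
                           **(ics_raw.get("intracellular") or {})},
            vesicle={**base_ics.vesicle, **(ics_raw.get("vesicle") or {})},
        )
        snapshot = d.get("snapshot_times_ms")
        probes = d.get("probes_nm")
        return cls(
            model=d.get("model", "pnp"),
            duration=d.get("duration_ms", 0.5),
            geometry=sub("geometry", Geometry),
            constants=sub("constants", PhysicalConstants),
            kappa=d.get("kappa", 2.56),
            diffusion={**_DEFAULT_DIFFUSION, **(d.get("diffusion_nm2_per_ms") or {})},
            ics=ics,
            ampa=sub("ampa", AmpaParams,
                     key_map={"g_Na_pS": "g_Na", "g_K_pS": "g_K"}),
            markov=sub("markov", MarkovParams),
            solver=sub("solver", SolverSettings, key_map={"dt_ms": "dt"}),
            resolution=(sub("resolution", MeshResolution)
                        if d.get("resolution") else MeshResolution.coarse()),
            holding_potential=d.get("holding_potential_mV", -70.0),
            markov_substep=d.get("markov_substep_ms", 0.001),
            snapshot_times=None if snapshot is None else tuple(snapshot),
            probes=None if probes is None else
                {k: tuple(v) for k, v in probes.items()},
        )


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a YAML or JSON scenario file; an empty file gives the defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    return ScenarioConfig.from_dict(data or {})


def dump_defaults() -> str:
    """The full default parameter pack as a YAML document."""
    return yaml.safe_dump(ScenarioConfig().to_dict(), sort_keys=False)


def config_hash(config: ScenarioConfig) -> str:
    """Stable hash of a scenario (for rerun manifests)."""
    blob = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# running scenarios
# ---------------------------------------------------------------------------

def run_scenario(config: ScenarioConfig, model: str | None = None,
                 mesh: Mesh | None = None,
                 progress=None) -> SimulationResult:
    """Build everything from a config and advance the chosen model."""
    model = model or config.model
    mesh = mesh if mesh is not None else config.build_mesh()
    state = config.build_state(mesh)
    bc = config.build_bc()
    coupler = config.build_coupler(mesh, model)
    return run_simulation(
        state, mesh, bc, config.solver, config.duration, model,
        config.constants, coupler,
        snapshot_times=config.active_snapshot_times(),
        probes=config.probe_cells(mesh),
        progress=progress,
    )


def run_comparison(config: ScenarioConfig, t_eval: float | None = None,
                   mesh: Mesh | None = None, progress=None):
    """Run the PNP and D models on one scenario and compare them.

    Returns ``(pnp_result, d_result, report)``; the report's A side is the
    PNP run, its B side the D run, so ``report.excess_percent('Glu-')`` is
    the relative glutamate excess of the D model over the PNP model at the
    cleft-center probe.
    """
    from .analysis import compare_runs

    mesh = mesh if mesh is not None else config.build_mesh()
    pnp = run_scenario(config, "pnp", mesh, progress=progress)
    d = run_scenario(config, "d", mesh, progress=progress)
    t_eval = t_eval if t_eval is not None else min(0.5, config.duration)
    report = compare_runs(pnp, d, probe="cleft_center", t_eval=t_eval)
    return pnp, d, report


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

_SWEEP_AXES = ("N_AMPA", "vesicle_glu", "cleft_height", "kappa")


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep.

    When the vesicle glutamate load is varied, the vesicle counter-ions
    (Na+, K+) are scaled by the same factor so the vesicle mixture stays
    electroneutral.
    """

    axis: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.axis not in _SWEEP_AXES:
            raise ValueError(f"sweep axis must be one of {_SWEEP_AXES}")
        if not self.values:
            raise ValueError("sweep needs at least one value")

    def apply(self, base: ScenarioConfig, value: float) -> ScenarioConfig:
        if self.axis == "N_AMPA":
            return replace(base, ampa=replace(base.ampa, N_AMPA=value))
        if self.axis == "cleft_height":
            return replace(base, geometry=replace(base.geometry, h=value))
        if self.axis == "kappa":
            return replace(base, kappa=value)
        # vesicle_glu: scale the whole vesicle mixture by value / base glu
        base_glu = base.ics.vesicle.get("Glu-", 0.0)
        if base_glu <= 0:
            raise ValueError("base scenario has no vesicle glutamate to scale")
        f = value / base_glu
        vesicle = {name: c * f for name, c in base.ics.vesicle.items()}
        ics = InitialConditions(
            extracellular=dict(base.ics.extracellular),
            intracellular=dict(base.ics.intracellular),
            vesicle=vesicle,
        )
        return replace(base, ics=ics)


def run_sweep(base: ScenarioConfig, sweep: SweepSpec,
              t_eval: float | None = None, progress=None) -> dict:
    """Run the PNP/D pair for every sweep value; returns value -> report."""
    out = {}
    for v in sweep.values:
        cfg = sweep.apply(base, v)
        _, _, report = run_comparison(cfg, t_eval=t_eval, progress=progress)
        out[v] = report
    return out


# ---------------------------------------------------------------------------
# 1D demonstration problem
# ---------------------------------------------------------------------------

def _species_1d() -> list[IonSpecies]:
    return [IonSpecies("Na+", 1, 1.33e6), IonSpecies("Cl-", -1, 2.03e6),
            IonSpecies("Glu-", -1, 0.86e6)]


@dataclass
class Demo1DConfig:
    """The 1D interval problem: electroneutral Na+/Cl-/Glu- mixture on
    (0, L) nm, zero-flux concentrations, Dirichlet phi(0)=0, phi(L)=phi0.

    The pure-diffusion solution stays uniform; the PNP solution develops
    boundary (Debye) layers whose size grows with \\|phi0\\|.
    """

    phi0: float = -10.0
    length: float = 10.0
    n_cells: int = 200
    mixture: dict[str, float] = field(default_factory=lambda: {
        "Na+": 100.0, "Cl-": 99.0, "Glu-": 1.0})
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        net = sum(_VALENCES[n] * c for n, c in self.mixture.items())
        if abs(net) > 1e-9:
            raise ValueError("1D mixture must be electroneutral")

    def species(self) -> list[IonSpecies]:
        return [sp for sp in _species_1d() if sp.name in self.mixture]

    def build(self):
        mesh = build_interval_mesh(self.length, self.n_cells)
        species = self.species()
        nx = self.n_cells
        conc = np.zeros((len(species), nx, 1, 1))
        for k, sp in enumerate(species):
            conc[k] = self.mixture[sp.name]
        phi = np.zeros((nx, 1, 1))
        state = FieldState(t=0.0, conc=conc, phi=phi, markov=None, species=species)
        bc = BoundarySpec.phi_ends(0.0, self.phi0)
        return mesh, state, bc

    def run_stationary(self, dt: float = 2e-5, rate_tol: float = 1e-6,
                       max_steps: int = 4000) -> FieldState:
        """March the PNP model to its stationary solution."""
        mesh, state, bc = self.build()
        settings = SolverSettings(dt=dt)
        return run_to_steady_state(state, mesh, bc, settings, model="pnp",
                                   constants=self.constants,
                                   rate_tol=rate_tol, max_steps=max_steps)

    def oracle(self, n: int = 2001):
        from .analysis import poisson_boltzmann_oracle
        return poisson_boltzmann_oracle(
            self.mixture, self.phi0, self.length, self.constants,
            species=self.species(), n=n)


def make_demo_1d(phi0: float = -10.0, n_cells: int = 200) -> Demo1DConfig:
    """The 1D interval scenario at one boundary potential."""
    return Demo1DConfig(phi0=phi0, n_cells=n_cells)


def make_demo_1d_suite(phi0s: tuple[float, ...] = (-5.0, -10.0, -15.0),
                       n_cells: int = 200) -> list[Demo1DConfig]:
    """The three boundary-potential variants of the 1D problem."""
    return [Demo1DConfig(phi0=p, n_cells=n_cells) for p in phi0s]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass
class MarkovPulseFixture:
    """A prescribed glutamate transient driving the gating model standalone.

    ``glu(t) = peak * exp(-t / tau)`` sampled at the transport step; the
    receptor ODEs are integrated with the standard substep between samples.
    """

    dt: float = 0.02
    duration: float = 1.0
    peak: float = 1.0
    tau: float = 0.2
    substep: float = 0.001
    params: MarkovParams = field(default_factory=MarkovParams)

    def glu(self, t: np.ndarray) -> np.ndarray:
        return self.peak * np.exp(-np.asarray(t) / self.tau)

    def run(self):
        n = int(round(self.duration / self.dt))
        t = np.arange(n + 1) * self.dt
        glu = self.glu(t)
        C = np.zeros((1, 6))
        C[0, 0] = 1.0
        o = [0.0]
        for i in range(n):
            C = markov_step(C, glu[i], self.dt, self.substep, self.params)
            o.append(float(1.0 - C.sum()))
        return t, glu, np.asarray(o)


def generate_fixture(kind: str):
    """Deterministic small-scale inputs for tests and demos.

    ``coarse3d``: the default scenario at the reduced desk-scale mesh;
    ``demo1d``: the 1D interval problem; ``markov_pulse``: a prescribed
    glutamate transient for the gating model alone.
    """
    if kind == "coarse3d":
        # 1 ms covers the AMPA current peak (~0.7 ms at this resolution)
        return ScenarioConfig(resolution=MeshResolution.coarse(), duration=1.0)
    if kind == "demo1d":
        return make_demo_1d()
    if kind == "markov_pulse":
        return MarkovPulseFixture()
    raise ValueError(f"unknown fixture kind {kind!r}")
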