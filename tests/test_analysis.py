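"""Flux decomposition, balance residuals, equilibrium oracle, comparisons."""

import numpy as np
import pandas as pd
import pytest

import cleftpnp as cp
from cleftpnp.analysis import (
    compare_runs,
    divergence_check,
    electroneutral_complete,
    flux_decomposition,
    molecule_count,
    poisson_boltzmann_oracle,
)
from cleftpnp.constants import IonSpecies
from cleftpnp.receptors import CurrentTrace
from cleftpnp.solvers import SimulationResult, SolverSettings, DiffusionStepper
from cleftpnp.state import FieldState


def single_species_state(mesh, c, phi):
    species = [IonSpecies("Na+", 1, 1.0e6)]
    return FieldState(t=0.0, conc=np.asarray(c).reshape((1,) + mesh.shape),
                      phi=None if phi is None else
                      np.asarray(phi).reshape(mesh.shape),
                      species=species)


class TestFluxDecomposition:
    def test_uniform_concentration_has_no_diffusive_flux(self):
        mesh = cp.build_interval_mesh(10.0, 20)
        x = mesh.cx
        st = single_species_state(mesh, np.full_like(x, 50.0), -0.5 * x)
        ff = flux_decomposition(st, mesh, "Na+")
        assert np.abs(ff.j_d).max() == 0.0
        assert np.abs(ff.j_e).max() > 0.0

    def test_uniform_potential_has_no_electrical_flux(self):
        mesh = cp.build_interval_mesh(10.0, 20)
        x = mesh.cx
        st = single_species_state(mesh, 50.0 + x, np.zeros_like(x))
        ff = flux_decomposition(st, mesh, "Na+")
        assert np.abs(ff.j_e).max() == 0.0
        assert np.abs(ff.j_d).max() > 0.0

    def test_linear_potential_drift_value(self, constants):
        # J_e = -D z e/(kB T) c dphi/dx, hand-evaluated for c = 100 mM and
        # a -0.5 mV/nm slope
        mesh = cp.build_interval_mesh(10.0, 20)
        x = mesh.cx
        slope = -0.5
        st = single_species_state(mesh, np.full_like(x, 100.0), slope * x)
        ff = flux_decomposition(st, mesh, "Na+")
        expected = -1.0e6 * 1 * constants.beta * 100.0 * slope
        np.testing.assert_allclose(ff.j_e, expected, rtol=1e-12)

    def test_pure_diffusion_state_has_no_electrical_flux(self):
        mesh = cp.build_interval_mesh(10.0, 20)
        st = single_species_state(mesh, np.full(20, 50.0), None)
        with pytest.raises(ValueError, match="potential"):
            flux_decomposition(st, mesh, "Na+")
        ff = flux_decomposition(st, mesh, "Na+", require_potential=False)
        assert ff.j_e is None


class TestDivergenceCheck:
    def test_accepted_diffusion_step_balances(self, closed_box):
        species = [IonSpecies("Na+", 1, 1.0e6), IonSpecies("Cl-", -1, 1.0e6)]
        nx, ny, nz = closed_box.shape
        conc = np.full((2, nx, ny, nz), 50.0)
        conc[:, 2:4, 2:4, 2:4] += 25.0
        st = FieldState(t=0.0, conc=conc, phi=None, species=species)
        bc = cp.BoundarySpec.closed()
        stepper = DiffusionStepper(closed_box, species, bc,
                                   settings=SolverSettings(dt=0.001))
        new = stepper.step(st)
        res = divergence_check(st, new, closed_box, bc, model="d")
        assert np.abs(res).max() < 1e-9

    def test_steady_state_residual_vanishes(self, closed_box):
        species = [IonSpecies("Na+", 1, 1.0e6)]
        nx, ny, nz = closed_box.shape
        st = FieldState(t=0.0, conc=np.full((1, nx, ny, nz), 10.0), phi=None,
                        species=species)
        new = st.copy()
        new.t = 0.01
        res = divergence_check(st, new, closed_box, cp.BoundarySpec.closed(),
                               model="d")
        assert np.abs(res).max() == 0.0

    def test_model_mismatch_is_detectable(self, closed_box):
        # attaching an artificial potential to a D-model step leaves a
        # nonzero PNP-form residual
        species = [IonSpecies("Na+", 1, 1.0e6)]
        nx, ny, nz = closed_box.shape
        conc = np.full((1, nx, ny, nz), 50.0)
        conc[0, :3] += 20.0
        st = FieldState(t=0.0, conc=conc, phi=None, species=species)
        bc = cp.BoundarySpec.closed()
        stepper = DiffusionStepper(closed_box, species, bc,
                                   settings=SolverSettings(dt=0.001))
        new = stepper.step(st)
        x = closed_box.cx
        fake_phi = np.broadcast_to(-1.0 * x[:, None, None],
                                   closed_box.shape).copy()
        st.phi = fake_phi
        new.phi = fake_phi
        res = divergence_check(st, new, closed_box, bc, model="pnp")
        assert np.abs(res).max() > 1e-4

    def test_mismatched_states_rejected(self, closed_box):
        species = [IonSpecies("Na+", 1, 1.0e6)]
        st = FieldState(t=0.0, conc=np.zeros((1, 2, 2, 2)), phi=None,
                        species=species)
        with pytest.raises(ValueError):
            divergence_check(st, st, closed_box, cp.BoundarySpec.closed())


class TestPoissonBoltzmannOracle:
    MIX = [(1, 100.0), (-1, 99.0), (-1, 1.0)]

    def test_zero_potential_keeps_uniform_profiles(self):
        sol = poisson_boltzmann_oracle(self.MIX, 0.0, n=501)
        np.testing.assert_allclose(sol.phi, 0.0, atol=1e-12)
        for k, (_, c0) in enumerate(self.MIX):
            np.testing.assert_allclose(sol.conc[k], c0, rtol=1e-12)

    def test_boltzmann_self_consistency(self):
        sol = poisson_boltzmann_oracle(self.MIX, -10.0)
        assert sol.boltzmann_residual() < 1e-8
        # cations accumulate, anions deplete near the negative plate
        assert sol.conc[0, -1] > sol.conc[0, 0]
        assert sol.conc[1, -1] < sol.conc[1, 0]

    def test_content_is_conserved(self):
        sol = poisson_boltzmann_oracle(self.MIX, -15.0)
        for k, (_, c0) in enumerate(self.MIX):
            content = np.trapezoid(sol.conc[k], sol.x)
            assert content == pytest.approx(c0 * 10.0, rel=1e-10)

    def test_deviation_grows_with_field(self):
        devs = [poisson_boltzmann_oracle(self.MIX, p).deviation_from_uniformity()
                for p in (-5.0, -10.0, -15.0)]
        assert devs[0] < devs[1] < devs[2]

    def test_non_electroneutral_mixture_rejected(self):
        with pytest.raises(ValueError, match="electroneutral"):
            poisson_boltzmann_oracle([(1, 100.0), (-1, 50.0)], -10.0)


class TestScalarUtilities:
    def test_molecule_count_zero(self):
        assert molecule_count(0.0, 64000.0) == 0.0

    @pytest.mark.parametrize("conc,expected_thousands", [
        (100.0, 4), (150.0, 6), (200.0, 8),
    ])
    def test_vesicle_loads_to_nearest_thousand(self, conc, expected_thousands):
        n = molecule_count(conc, 40.0 ** 3)
        assert round(n / 1000.0) == expected_thousands

    def test_count_values(self):
        # 150 mM * 64000 nm^3 = 9.6e-21 mol -> ~5781 molecules
        assert molecule_count(150.0, 40.0 ** 3) == pytest.approx(5781.3, abs=0.5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            molecule_count(-1.0, 10.0)

    def test_electroneutral_complete_reference_mixtures(self, species):
        ext = electroneutral_complete(
            {"Na+": 100.0, "K+": 4.0, "Ca2+": 1.4, "Glu-": 0.0}, species)
        assert ext["Cl-"] == pytest.approx(106.8, abs=1e-12)
        intra = electroneutral_complete(
            {"Na+": 12.0, "K+": 125.0, "Ca2+": 0.0001, "Glu-": 0.0}, species)
        assert intra["Cl-"] == pytest.approx(137.0002, abs=1e-12)

    def test_electroneutral_complete_trivial_and_invalid(self, species):
        assert electroneutral_complete(
            {"Na+": 0.0, "K+": 0.0, "Ca2+": 0.0, "Glu-": 0.0},
            species)["Cl-"] == 0.0
        with pytest.raises(ValueError, match="negative"):
            electroneutral_complete(
                {"Na+": 0.0, "K+": 0.0, "Ca2+": 0.0, "Glu-": 10.0}, species)


def _fake_run(values, currents, species, t_eval=0.5):
    rows = []
    for name, v in values.items():
        rows.append((t_eval, "cleft_center", name, v))
    probes = pd.DataFrame(rows, columns=["t_ms", "probe", "quantity", "value"])
    st = FieldState(t=t_eval, conc=np.zeros((len(species), 2, 2, 2)),
                    phi=None, species=species)
    times = np.array([0.0, t_eval])
    return SimulationResult(
        model="x", times=times, snapshots={t_eval: st}, final_state=st,
        current=CurrentTrace(t=times, I=np.asarray(currents)),
        probes=probes, mesh=None)


class TestCompareRuns:
    def _pair(self, species):
        a = _fake_run({"Na+": 80.0, "K+": 10.0, "Ca2+": 1.0, "Cl-": 90.0,
                       "Glu-": 2.0}, [0.0, -0.105], species)
        b = _fake_run({"Na+": 70.0, "K+": 14.0, "Ca2+": 1.0, "Cl-": 91.0,
                       "Glu-": 3.0}, [0.0, -0.100], species)
        return a, b

    def test_self_comparison_is_trivial(self, species):
        a, _ = self._pair(species)
        rep = compare_runs(a, a, t_eval=0.5)
        for v in rep.conc_ratio.values():
            assert v == pytest.approx(1.0)
        for v in rep.conc_diff.values():
            assert v == 0.0
        assert rep.peak_excess_percent == pytest.approx(0.0)

    def test_swapping_inverts_ratios_and_negates_differences(self, species):
        a, b = self._pair(species)
        fwd = compare_runs(a, b, t_eval=0.5)
        rev = compare_runs(b, a, t_eval=0.5)
        for name in fwd.conc_ratio:
            assert rev.conc_ratio[name] == pytest.approx(
                1.0 / fwd.conc_ratio[name])
            assert rev.conc_diff[name] == pytest.approx(-fwd.conc_diff[name])
        assert rev.peak_current_ratio == pytest.approx(
            1.0 / fwd.peak_current_ratio)

    def test_excess_percent_semantics(self, species):
        a, b = self._pair(species)
        rep = compare_runs(a, b, t_eval=0.5)
        # Glu-: 2 mM in A, 3 mM in B -> B exceeds A by 50%
        assert rep.excess_percent("Glu-") == pytest.approx(50.0)
        # peak: -0.105 vs -0.100 -> A is 5% more negative
        assert rep.peak_excess_percent == pytest.approx(5.0)

    def test_mismatched_schedule_rejected(self, species):
        a, b = self._pair(species)
        b.times = np.array([0.0, 0.25, 0.5])
        with pytest.raises(ValueError, match="schedule"):
            compare_runs(a, b, t_eval=0.5)
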