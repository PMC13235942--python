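"""Transport steppers: fixed points, conservation, reduction, heat kernel."""

import numpy as np
import pytest

import cleftpnp as cp
from cleftpnp.constants import IonSpecies
from cleftpnp.solvers import (
    DiffusionStepper,
    PnpStepper,
    SolverSettings,
    diffusion_step,
    pnp_step,
    run_simulation,
)
from cleftpnp.state import FieldState


def uniform_state(mesh, species, values, phi=0.0):
    nx, ny, nz = mesh.shape
    conc = np.zeros((len(species), nx, ny, nz))
    for k, v in enumerate(values):
        conc[k] = v
    return FieldState(t=0.0, conc=conc, phi=np.full((nx, ny, nz), phi),
                      species=species)


def three_species():
    return [IonSpecies("Na+", 1, 1.33e6), IonSpecies("Cl-", -1, 2.03e6),
            IonSpecies("Glu-", -1, 0.86e6)]


class TestFixedPoints:
    def test_uniform_closed_diffusion_unchanged(self, closed_box):
        species = three_species()
        st = uniform_state(closed_box, species, [100.0, 99.0, 1.0])
        new = diffusion_step(st, closed_box, cp.BoundarySpec.closed())
        np.testing.assert_allclose(new.conc, st.conc, atol=1e-12)

    def test_uniform_electroneutral_pnp_unchanged(self, closed_box):
        # zero-flux concentrations, grounded potential at both x faces:
        # the uniform electroneutral state is a stationary point
        species = three_species()
        st = uniform_state(closed_box, species, [100.0, 99.0, 1.0])
        bc = cp.BoundarySpec.phi_ends(0.0, 0.0)
        new = pnp_step(st, closed_box, bc, SolverSettings(dt=0.01))
        np.testing.assert_allclose(new.conc, st.conc, atol=1e-8)
        assert np.abs(new.phi).max() < 1e-8

    def test_duration_zero_returns_initial_only(self, closed_box):
        species = three_species()
        st = uniform_state(closed_box, species, [100.0, 99.0, 1.0])
        res = run_simulation(st, closed_box, cp.BoundarySpec.closed(),
                             duration=0.0, model="d")
        assert len(res.times) == 1
        np.testing.assert_array_equal(res.final_state.conc, st.conc)


class TestConservation:
    def test_closed_domain_conserves_moles_both_models(self, closed_box):
        species = three_species()
        st = uniform_state(closed_box, species, [100.0, 99.0, 1.0])
        # non-uniform, electroneutral perturbation
        bump = np.zeros(closed_box.shape)
        bump[2:4, 2:4, 2:4] = 30.0
        st.conc[0] += bump
        st.conc[1] += bump  # Na+ and Cl- together stay electroneutral
        total0 = st.total_moles(closed_box)

        d_new = diffusion_step(st, closed_box, cp.BoundarySpec.closed(),
                               SolverSettings(dt=0.001))
        np.testing.assert_allclose(d_new.total_moles(closed_box), total0,
                                   rtol=1e-12)

        bc = cp.BoundarySpec.phi_ends(0.0, -5.0)  # concentrations zero-flux
        p_new = pnp_step(st, closed_box, bc, SolverSettings(dt=0.001))
        np.testing.assert_allclose(p_new.total_moles(closed_box), total0,
                                   rtol=1e-10)
        assert p_new.conc.min() >= -1e-10


class TestReduction:
    def test_zero_valence_pnp_equals_diffusion(self, closed_box):
        # with all valences zero the drift term vanishes identically and
        # the PNP trajectory must coincide with the pure-diffusion one
        species = [IonSpecies("Na+", 0, 1.33e6), IonSpecies("Cl-", 0, 2.03e6)]
        st = uniform_state(closed_box, species, [50.0, 20.0])
        st.conc[0, :3] *= 2.0
        st.conc[1, 3:] += 10.0
        bc = cp.BoundarySpec.phi_ends(0.0, -10.0)
        settings = SolverSettings(dt=0.005)
        p = st.copy()
        d = st.copy()
        pnp = PnpStepper(closed_box, species, bc, settings=settings)
        dif = DiffusionStepper(closed_box, species, bc, settings=settings)
        for _ in range(5):
            p = pnp.step(p)
            d = dif.step(d)
        np.testing.assert_allclose(p.conc, d.conc, atol=1e-8)


class TestHeatKernel:
    def test_gaussian_spreads_like_green_function(self):
        # single species, fine 1D mesh: a Gaussian initial profile stays
        # Gaussian with variance sigma^2 + 2 D t (closed-form oracle)
        L, n = 4000.0, 400
        D = 1.0e5
        mesh = cp.build_interval_mesh(L, n)
        species = [IonSpecies("Glu-", -1, D)]
        x = mesh.cx
        sig0 = 80.0
        c0 = np.exp(-0.5 * ((x - L / 2) / sig0) ** 2)
        st = FieldState(t=0.0, conc=c0.reshape(1, n, 1, 1), phi=None,
                        species=species)
        t_end, dt = 0.02, 0.0005
        stepper = DiffusionStepper(mesh, species, cp.BoundarySpec.closed(),
                                   settings=SolverSettings(dt=dt))
        for _ in range(int(round(t_end / dt))):
            st = stepper.step(st)
        sig = np.sqrt(sig0 ** 2 + 2 * D * t_end)
        expected = sig0 / sig * np.exp(-0.5 * ((x - L / 2) / sig) ** 2)
        err = np.abs(st.conc[0, :, 0, 0] - expected).max()
        assert err < 5e-3 * expected.max()


class TestDModelInvariants:
    def test_quiescent_synapse_stays_at_rest(self, coarse_mesh, ics):
        # blocked vesicle, no receptors: the initial state is an equilibrium
        st = cp.initialize_state(coarse_mesh, ics)
        bc = cp.BoundarySpec.synapse_default(ics)
        settings = SolverSettings(vesicle_open=False)
        res = run_simulation(st, coarse_mesh, bc, settings, duration=0.1,
                             model="d")
        np.testing.assert_allclose(res.final_state.conc, st.conc, atol=1e-9)

    def test_blocked_vesicle_conserves_content(self, coarse_mesh, ics):
        st = cp.initialize_state(coarse_mesh, ics)
        bc = cp.BoundarySpec.synapse_default(ics)
        settings = SolverSettings(vesicle_open=False)
        stepper = DiffusionStepper(coarse_mesh, st.species, bc,
                                   settings=settings)
        ves = coarse_mesh.region == cp.Region.VESICLE
        vols = coarse_mesh.volumes[ves]
        glu0 = float((st.conc[-1][ves] * vols).sum())
        cur = st
        for _ in range(5):
            cur = stepper.step(cur)
        glu1 = float((cur.conc[-1][ves] * vols).sum())
        assert glu1 == pytest.approx(glu0, rel=1e-12)


class TestErrors:
    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            SolverSettings(dt=0.0)
        with pytest.raises(ValueError):
            SolverSettings(advection="qmom")
        with pytest.raises(ValueError):
            SolverSettings(linear_solver="magic")

    def test_pnp_requires_phi_anchor(self, closed_box):
        species = three_species()
        st = uniform_state(closed_box, species, [100.0, 99.0, 1.0])
        with pytest.raises(ValueError, match="Dirichlet"):
            pnp_step(st, closed_box, cp.BoundarySpec.closed())

    def test_duration_must_match_dt(self, closed_box):
        species = three_species()
        st = uniform_state(closed_box, species, [100.0, 99.0, 1.0])
        with pytest.raises(ValueError, match="multiple"):
            run_simulation(st, closed_box, cp.BoundarySpec.closed(),
                           SolverSettings(dt=0.02), duration=0.03, model="d")
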