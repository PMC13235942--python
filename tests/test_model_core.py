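"""Constants, geometry, mesh construction and state initialization."""

import numpy as np
import pytest

import cleftpnp as cp
from cleftpnp.mesh import MeshResolution, Region


class TestConstantsAndSpecies:
    def test_default_constants(self, constants):
        assert constants.F == 96485.3365
        assert constants.T == 310.0
        assert constants.eps_bulk == 80.0
        assert constants.eps_mem == 2.0
        assert constants.eps0 == 8854.0
        # thermal voltage ~26.7 mV at 310 K
        assert constants.thermal_voltage == pytest.approx(26.714, abs=0.01)

    def test_constants_must_be_positive(self):
        with pytest.raises(ValueError):
            cp.PhysicalConstants(T=-1.0)

    def test_default_species_table(self, species):
        table = {sp.name: (sp.z, sp.D_bulk) for sp in species}
        assert table == {
            "Na+": (1, 1.33e6), "K+": (1, 1.96e6), "Ca2+": (2, 0.71e6),
            "Cl-": (-1, 2.03e6), "Glu-": (-1, 0.86e6),
        }
        for sp in species:
            assert sp.cleft_factor == 2.56
            assert sp.D_cleft == pytest.approx(sp.D_bulk / 2.56)
            assert sp.D_membrane == 0.0

    def test_species_validation(self):
        with pytest.raises(ValueError):
            cp.IonSpecies("X", 3, 1e6)
        with pytest.raises(ValueError):
            cp.IonSpecies("X", 1, -1.0)
        with pytest.raises(ValueError):
            cp.IonSpecies("X", 1, 1e6, cleft_factor=0.0)


class TestGeometry:
    def test_defaults_and_derived(self, geometry):
        g = geometry
        assert (g.h, g.l_m, g.w_a, g.w_v, g.w_vo) == (15, 5, 140, 40, 4)
        assert (g.l_ex, g.l_ix, g.l_iy) == (1000, 600, 1000)
        assert g.y_total == 2 * g.l_iy + 2 * g.l_m + g.h
        assert g.cleft_aspect_ratio == pytest.approx(40.0)
        assert g.vesicle_volume == 40.0 ** 3

    @pytest.mark.parametrize("kwargs", [
        {"w_vo": 0.0},              # degenerate: no opening
        {"w_vo": 50.0},             # opening wider than the vesicle
        {"h": -1.0},
        {"w_a": 700.0},             # AMPA area wider than the cleft
        {"l_ix": 1200.0},           # cleft wider than the domain
    ])
    def test_invalid_geometry(self, kwargs):
        with pytest.raises(ValueError):
            cp.Geometry(**kwargs)


class TestMesh:
    def test_y_extent_is_sum_of_layers(self, coarse_mesh, geometry):
        assert coarse_mesh.ey[0] == 0.0
        assert coarse_mesh.ey[-1] == pytest.approx(geometry.y_total)

    def test_cleft_label_spans_cleft_width(self, coarse_mesh, geometry):
        mesh = coarse_mesh
        y_mid = 0.5 * sum(geometry.y_cleft)
        j = np.searchsorted(mesh.ey, y_mid) - 1
        half = geometry.l_ix / 2.0
        for i, x in enumerate(mesh.cx):
            for k, z in enumerate(mesh.cz):
                expected = (Region.CLEFT if abs(x) < half and abs(z) < half
                            else Region.EXTRACELLULAR)
                assert mesh.region[i, j, k] == expected

    def test_region_volumes_exact(self, coarse_mesh, geometry):
        # region boundaries are snapped to mesh edges, so volumes are exact
        g = geometry
        assert coarse_mesh.region_volume(Region.VESICLE) == pytest.approx(g.w_v ** 3)
        opening_vol = g.w_vo ** 2 * g.l_m
        assert coarse_mesh.region_volume(Region.VESICLE_OPENING) == pytest.approx(
            opening_vol)
        cleft_vol = g.l_ix * g.l_iz * g.h - opening_area_overlap(g)
        assert coarse_mesh.region_volume(Region.CLEFT) == pytest.approx(cleft_vol)

    def test_finer_mesh_keeps_volumes(self, geometry):
        mesh = cp.build_mesh(geometry, MeshResolution(n_cleft=5, n_mem=2,
                                                      n_vesicle=4, ratio=1.5))
        assert mesh.region_volume(Region.VESICLE) == pytest.approx(
            geometry.vesicle_volume)

    def test_ampa_zone_covers_area(self, coarse_mesh, geometry):
        mesh = coarse_mesh
        areas = mesh.wx[mesh.ampa_ix] * mesh.wz[mesh.ampa_iz]
        assert areas.sum() == pytest.approx(geometry.w_a ** 2)
        # faces sit on the postsynaptic membrane: cleft below, cell above
        r = mesh.region
        assert np.all(r[mesh.ampa_ix, mesh.j_cleft_top, mesh.ampa_iz]
                      == Region.CLEFT)
        assert np.all(r[mesh.ampa_ix, mesh.j_intra_post, mesh.ampa_iz]
                      == Region.INTRA_POST)
        assert np.all(r[mesh.ampa_ix, mesh.j_cleft_top + 1, mesh.ampa_iz]
                      == Region.MEMBRANE_POST)

    def test_mesh_determinism(self, geometry):
        m1 = cp.build_mesh(geometry, MeshResolution.coarse())
        m2 = cp.build_mesh(geometry, MeshResolution.coarse())
        assert np.array_equal(m1.ex, m2.ex)
        assert np.array_equal(m1.ey, m2.ey)
        assert np.array_equal(m1.region, m2.region)

    def test_underresolved_cleft_rejected(self, geometry):
        with pytest.raises(ValueError, match="cleft"):
            cp.build_mesh(geometry, MeshResolution(n_cleft=2))

    def test_every_cell_has_one_label(self, coarse_mesh):
        labels = set(np.unique(coarse_mesh.region))
        assert labels <= set(Region.NAMES)

    def test_find_cell(self, coarse_mesh):
        i, j, k = coarse_mesh.find_cell(0.0, 1012.5, 0.0)
        assert coarse_mesh.region[i, j, k] == Region.CLEFT


def opening_area_overlap(g):
    # the opening lives in the membrane slab, not in the cleft slab
    return 0.0


class TestInitialState:
    def test_extracellular_values(self, synapse_state, coarse_mesh, ics):
        st = synapse_state
        mask = coarse_mesh.region == Region.EXTRACELLULAR
        expected = {"Na+": 100.0, "K+": 4.0, "Ca2+": 1.4, "Cl-": 106.8,
                    "Glu-": 0.0}
        for k, sp in enumerate(st.species):
            vals = st.conc[k][mask]
            assert np.all(vals == expected[sp.name])

    def test_vesicle_values(self, synapse_state, coarse_mesh):
        st = synapse_state
        mask = coarse_mesh.region == Region.VESICLE
        conc = {sp.name: st.conc[k][mask] for k, sp in enumerate(st.species)}
        assert np.all(conc["Glu-"] == 150.0)
        assert np.all(conc["Cl-"] == 0.0)
        assert np.all(conc["Na+"] == 145.0)

    def test_charge_density_zero_everywhere(self, synapse_state, constants):
        rho = synapse_state.charge_density(constants)
        assert np.abs(rho).max() == 0.0

    def test_potential_by_region(self, synapse_state, coarse_mesh):
        st = synapse_state
        r = coarse_mesh.region
        assert np.all(st.phi[r == Region.EXTRACELLULAR] == 0.0)
        assert np.all(st.phi[r == Region.INTRA_PRE] == -70.0)
        assert np.all(st.phi[r == Region.INTRA_POST] == -70.0)

    def test_markov_starts_in_c0(self, synapse_state):
        assert np.all(synapse_state.markov[:, 0] == 1.0)
        assert np.all(synapse_state.markov[:, 1:] == 0.0)

    def test_non_electroneutral_rejected(self, coarse_mesh):
        bad = cp.InitialConditions(extracellular={
            "Na+": 100.0, "K+": 4.0, "Ca2+": 1.4, "Cl-": 100.0, "Glu-": 0.0})
        with pytest.raises(ValueError, match="electroneutral"):
            cp.initialize_state(coarse_mesh, bad)
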