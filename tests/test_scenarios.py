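"""Configuration handling, sweeps, 1D demo, fixtures, CLI plumbing."""

import numpy as np
import pytest
import yaml

import cleftpnp as cp
from cleftpnp.scenarios import (
    Demo1DConfig,
    ScenarioConfig,
    SweepSpec,
    config_hash,
    dump_defaults,
    load_config,
    make_demo_1d_suite,
)


class TestConfig:
    def test_empty_file_gives_full_defaults(self, tmp_path):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        cfg = load_config(p)
        assert cfg.to_dict() == ScenarioConfig().to_dict()

    def test_json_is_accepted(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text('{"kappa": 3.0}')
        assert load_config(p).kappa == 3.0

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("banana: 1\n")
        with pytest.raises(ValueError, match="banana"):
            load_config(p)

    def test_invalid_kappa_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("kappa: 0.0\n")
        with pytest.raises(ValueError, match="kappa"):
            load_config(p)

    def test_override_changes_only_that_field(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("ampa: {N_AMPA: 50}\n")
        cfg = load_config(p)
        base = ScenarioConfig()
        assert cfg.ampa.N_AMPA == 50
        d1, d2 = cfg.to_dict(), base.to_dict()
        d1["ampa"]["N_AMPA"] = d2["ampa"]["N_AMPA"]
        assert d1 == d2

    def test_dump_defaults_roundtrip(self):
        text = dump_defaults()
        data = yaml.safe_load(text)
        cfg = ScenarioConfig.from_dict(data)
        assert cfg.to_dict() == ScenarioConfig().to_dict()

    def test_config_hash_stable_and_sensitive(self):
        a = ScenarioConfig()
        b = ScenarioConfig(kappa=3.0)
        assert config_hash(a) == config_hash(ScenarioConfig())
        assert config_hash(a) != config_hash(b)

    def test_snapshot_schedule_respects_dt(self):
        cfg = ScenarioConfig(duration=0.5)
        times = cfg.active_snapshot_times()
        # 0.001 and 0.05 are not multiples of dt = 0.02 and must be dropped
        assert 0.001 not in times and 0.05 not in times
        assert {0.1, 0.2, 0.3, 0.5} <= set(times)


class TestSweeps:
    def test_vesicle_glutamate_sweep_scales_counter_ions(self):
        base = ScenarioConfig()
        sweep = SweepSpec(axis="vesicle_glu", values=(100.0, 150.0, 200.0))
        for value, factor in zip(sweep.values, (2 / 3, 1.0, 4 / 3)):
            cfg = sweep.apply(base, value)
            ves = cfg.ics.vesicle
            assert ves["Glu-"] == pytest.approx(value)
            assert ves["Na+"] == pytest.approx(145.0 * factor)
            assert ves["K+"] == pytest.approx(5.0 * factor)
            net = sum(sp.z * ves.get(sp.name, 0.0) for sp in cfg.species())
            assert net == pytest.approx(0.0, abs=1e-9)

    def test_other_axes(self):
        base = ScenarioConfig()
        assert SweepSpec("N_AMPA", (80.0,)).apply(base, 80.0).ampa.N_AMPA == 80.0
        assert SweepSpec("cleft_height", (20.0,)).apply(base, 20.0).geometry.h == 20.0
        assert SweepSpec("kappa", (5.0,)).apply(base, 5.0).kappa == 5.0

    def test_invalid_axis_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec(axis="temperature", values=(300.0,))
        with pytest.raises(ValueError):
            SweepSpec(axis="kappa", values=())


class TestDemo1D:
    def test_mixture_is_electroneutral(self):
        cfg = cp.make_demo_1d()
        assert sum({"Na+": 1, "Cl-": -1, "Glu-": -1}[n] * c
                   for n, c in cfg.mixture.items()) == 0.0

    def test_suite_emits_three_potentials(self):
        suite = make_demo_1d_suite()
        assert [c.phi0 for c in suite] == [-5.0, -10.0, -15.0]

    def test_non_electroneutral_mixture_rejected(self):
        with pytest.raises(ValueError):
            Demo1DConfig(mixture={"Na+": 100.0, "Cl-": 90.0, "Glu-": 1.0})

    def test_zero_potential_variant_is_stationary(self):
        cfg = Demo1DConfig(phi0=0.0, n_cells=60)
        st = cfg.run_stationary(dt=5e-5, max_steps=200)
        for k, sp in enumerate(cfg.species()):
            np.testing.assert_allclose(st.conc[k], cfg.mixture[sp.name],
                                       atol=1e-8)
        np.testing.assert_allclose(st.phi, 0.0, atol=1e-8)


class TestFixtures:
    def test_generate_fixture_kinds(self):
        assert isinstance(cp.generate_fixture("coarse3d"), ScenarioConfig)
        assert isinstance(cp.generate_fixture("demo1d"), Demo1DConfig)
        assert isinstance(cp.generate_fixture("markov_pulse"),
                          cp.MarkovPulseFixture)
        with pytest.raises(ValueError):
            cp.generate_fixture("nope")

    def test_demo1d_build_deterministic(self):
        m1, s1, _ = cp.make_demo_1d().build()
        m2, s2, _ = cp.make_demo_1d().build()
        assert np.array_equal(m1.ex, m2.ex)
        assert np.array_equal(s1.conc, s2.conc)


class TestCli:
    def test_dump_defaults_command(self):
        from click.testing import CliRunner
        from cleftpnp.cli import main

        result = CliRunner().invoke(main, ["dump-defaults"])
        assert result.exit_code == 0
        data = yaml.safe_load(result.output)
        assert data["kappa"] == 2.56
        assert data["ampa"]["N_AMPA"] == 200

    def test_run_writes_outputs_and_manifest(self, tmp_path):
        from click.testing import CliRunner
        from cleftpnp.cli import main

        cfg = tmp_path / "tiny.yaml"
        cfg.write_text("model: d\nduration_ms: 0.04\n"
                       "snapshot_times_ms: [0.04]\n")
        out = tmp_path / "out"
        result = CliRunner().invoke(
            main, ["run", "--config", str(cfg), "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert (out / "manifest.json").exists()
        assert (out / "d_probes.csv").exists()
        header = (out / "d_probes.csv").read_text().splitlines()[0]
        assert header == "t_ms,quantity,value"
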