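import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxycpap import concentrator as conc
from oxycpap.concentrator import (
    AMBIENT_O2,
    ConcentratorCommand,
    ConcentratorError,
    PolySurfaceCoeffs,
    ReservoirFilter,
    TruthSurfaces,
    fit_inverse_cs,
    fit_inverse_sv,
    reservoir_filter,
    run_characterization,
    standard_mode_cs,
    truth_surfaces,
)

cmd_strategy = st.one_of(
    st.just(ConcentratorCommand(0.0, 0.0)),
    st.builds(
        ConcentratorCommand,
        st.floats(20.0, 100.0),
        st.floats(10.0, 100.0),
    ),
)


class TestCommand:
    def test_off_state(self):
        assert ConcentratorCommand(0.0, 0.0).is_off

    @pytest.mark.parametrize("cs,sv", [(10.0, 50.0), (110.0, 50.0), (50.0, 5.0), (0.0, 50.0)])
    def test_invalid_commands(self, cs, sv):
        with pytest.raises(ConcentratorError):
            ConcentratorCommand(cs, sv)


class TestTruthSurfaces:
    def test_power_endpoints_published(self, surfaces):
        # 65 W at minimum speed, 146 W at maximum, proportional in between
        assert surfaces.compressor_power(20.0) == 65.0
        assert surfaces.compressor_power(100.0) == 146.0

    def test_power_affine_interpolation(self, surfaces):
        assert surfaces.compressor_power(60.0) == pytest.approx(105.5)

    def test_power_strictly_increasing(self, surfaces):
        cs = np.linspace(20, 100, 81)
        p = [surfaces.compressor_power(c) for c in cs]
        assert np.all(np.diff(p) > 0)

    def test_closed_valve(self, surfaces):
        out = surfaces.output(ConcentratorCommand(0.0, 0.0))
        assert out.flow == 0.0 and out.total_power == 0.0

    def test_output_ranges(self, surfaces):
        out = truth_surfaces(ConcentratorCommand(60.0, 50.0), surfaces)
        assert out.flow >= 0
        assert AMBIENT_O2 <= out.o2 <= 0.93
        assert 65.0 <= out.compressor_power <= 146.0

    @given(cmd_strategy)
    def test_o2_mass_conservation(self, cmd):
        # cannot deliver more O2 than produced at that speed
        s = TruthSurfaces()
        produced = s.flow(cmd.cs, cmd.sv) * (s.o2(cmd.cs, cmd.sv) - AMBIENT_O2)
        assert produced <= s.o2_capacity(cmd.cs) + 1e-9

    @given(cmd_strategy)
    def test_power_overhead_budget(self, cmd):
        # valves + sensors: 10 W sensors + up to 5 W solenoids + 3.2 W
        # switching valves (published component budgets)
        s = TruthSurfaces()
        out = s.output(cmd)
        assert out.total_power - out.compressor_power <= 10.0 + 5.0 + 3.2 + 1e-9

    def test_standard_mode_anchor(self):
        # 130 W standard mode lies on the affine map at cs ~ 84.2
        s = TruthSurfaces()
        assert s.compressor_power(standard_mode_cs()) == pytest.approx(130.0)

    def test_monotone_trends_fine_grid(self, surfaces):
        cs = np.linspace(20, 100, 81)
        sv = np.linspace(10, 100, 91)
        CS, SV = np.meshgrid(cs, sv, indexing="ij")
        F, O = surfaces.flow(CS, SV), surfaces.o2(CS, SV)
        assert (np.diff(F, axis=1) > 0).all()  # flow increases with duty
        assert (np.diff(O, axis=1) < 0).all()  # purity drops with duty
        assert (np.diff(F, axis=0) > 0).all()  # flow increases with speed
        assert (np.diff(O, axis=0) > 0).all()  # purity increases with speed


class TestCharacterization:
    def test_grid_shape(self, char_table):
        assert len(char_table) == 90
        assert sorted(char_table.cs_pct.unique()) == list(range(20, 101, 10))
        assert sorted(char_table.sv_pct.unique()) == list(range(10, 101, 10))

    def test_noiseless_equals_truth(self, surfaces, char_table):
        row = char_table.iloc[37]
        out = surfaces.output(ConcentratorCommand(row.cs_pct, row.sv_pct))
        assert row.flow_Lmin == pytest.approx(out.flow)
        assert row.o2_frac == pytest.approx(out.o2)

    def test_monotone_trends_on_table(self, char_table):
        f = char_table.pivot(index="cs_pct", columns="sv_pct", values="flow_Lmin")
        o = char_table.pivot(index="cs_pct", columns="sv_pct", values="o2_frac")
        assert (f.diff(axis=1).iloc[:, 1:] > 0).all().all()
        assert (o.diff(axis=1).iloc[:, 1:] < 0).all().all()
        assert (f.diff(axis=0).iloc[1:] > 0).all().all()
        assert (o.diff(axis=0).iloc[1:] > 0).all().all()

    def test_noise_determinism(self, surfaces):
        a = run_characterization(surfaces, noise_seed=7)
        b = run_characterization(surfaces, noise_seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestInverseFits:
    def test_exact_quadratic_recovery(self):
        # oracle: a table generated from an exact quadratic inverse must be
        # recovered to 1e-8 in every coefficient
        true = PolySurfaceCoeffs(12.0, 8.0, 55.0, 1.5, -3.0, -20.0)
        flow = np.linspace(0.2, 5.0, 10)
        o2 = np.linspace(0.45, 0.92, 9)
        F, O = np.meshgrid(flow, o2, indexing="ij")
        table = pd.DataFrame({
            "flow_Lmin": F.ravel(),
            "o2_frac": O.ravel(),
            "cs_pct": true.evaluate(F.ravel(), O.ravel()),
            "sv_pct": 0.0,
        })
        got = fit_inverse_cs(table)
        for name in ("p00", "p10", "p01", "p20", "p11", "p02"):
            assert getattr(got, name) == pytest.approx(getattr(true, name), abs=1e-8)
        assert got.rmse < 1e-8

    def test_constant_target_degenerate_surface(self):
        # constant-cs table: intercept carries the constant, the rest vanish
        sv = np.linspace(10, 100, 10)
        s = TruthSurfaces()
        table = pd.DataFrame({
            "flow_Lmin": s.flow(40.0, sv),
            "o2_frac": s.o2(40.0, sv),
            "cs_pct": 40.0,
            "sv_pct": sv,
        })
        got = fit_inverse_cs(table)
        assert got.p00 == pytest.approx(40.0, abs=1e-6)
        for name in ("p10", "p01", "p20", "p11", "p02"):
            assert abs(getattr(got, name)) < 1e-6

    def test_rank_deficient_raises(self):
        table = pd.DataFrame({
            "flow_Lmin": np.ones(12),
            "o2_frac": np.ones(12) * 0.8,
            "cs_pct": np.linspace(20, 100, 12),
            "sv_pct": np.ones(12) * 50,
        })
        with pytest.raises(ConcentratorError):
            fit_inverse_cs(table)

    def test_roundtrip_quality_on_default_surfaces(self, char_table, coeffs):
        # fit-quality oracle: median |cs - fit(flow, o2)| < 5 pct over the grid
        ccs, csv_ = coeffs
        err = np.abs(
            ccs.evaluate(char_table.flow_Lmin.values, char_table.o2_frac.values)
            - char_table.cs_pct.values
        )
        assert np.median(err) < 5.0
        err_sv = np.abs(
            csv_.evaluate(char_table.cs_pct.values, char_table.flow_Lmin.values)
            - char_table.sv_pct.values
        )
        assert np.median(err_sv) < 5.0

    def test_fit_determinism(self, char_table):
        a, b = fit_inverse_cs(char_table), fit_inverse_cs(char_table)
        assert a == b

    def test_json_roundtrip(self, coeffs, tmp_path):
        ccs, _ = coeffs
        path = tmp_path / "coeffs.json"
        ccs.to_json(path)
        loaded = PolySurfaceCoeffs.from_json(path)
        assert loaded == ccs
        with open(path) as fh:
            keys = set(json.load(fh))
        assert keys == {"p00", "p10", "p01", "p20", "p11", "p02", "rmse"}


class TestReservoirFilter:
    def test_constant_passthrough(self):
        x = np.full(100, 2.5)
        assert np.allclose(reservoir_filter(x, 3.4, 0.01), x)

    def test_square_wave_attenuation(self):
        # bed-switching ripple: square wave with 1.5 s half-period through
        # tau = 3.4 s; closed form peak-to-peak attenuation 1/tanh(h/2tau)
        dt, tau, half = 0.005, 3.4, 1.5
        n_half = int(half / dt)
        x = np.tile(np.r_[np.ones(n_half), -np.ones(n_half)], 40)
        y = reservoir_filter(x, tau, dt)
        tail = y[-6 * n_half:]
        expected = math.tanh(half / (2 * tau))  # ~0.217
        assert tail.max() == pytest.approx(expected, rel=0.02)
        attenuation = (x.max() - x.min()) / (tail.max() - tail.min())
        assert attenuation > 4.0

    def test_impulse_decay(self):
        dt, tau = 0.01, 0.5
        x = np.zeros(500)
        x[0] = 1.0
        y = reservoir_filter(x, tau, dt)
        # exponential decay with the filter's own time constant
        ratio = y[200] / y[100]
        assert ratio == pytest.approx(math.exp(-100 * dt / tau), rel=0.01)

    def test_streaming_matches_batch(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        batch = reservoir_filter(x, 1.0, 0.01)
        f = ReservoirFilter(1.0, 0.01, initial=x[0])
        stream = [f.value] + [f.update(v) for v in x[1:]]
        assert np.allclose(batch, stream)

    def test_validation(self):
        with pytest.raises(ValueError):
            reservoir_filter([1.0], 0.0, 0.01)
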