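"""Two-site exchange forward models: closed form vs numerical propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rnaexcite import (
    CESTSetting,
    ExchangeParams,
    RelaxationRates,
    SpinLockSetting,
    SpinProbe,
    bm_evolve_r1rho,
    effective_field_geometry,
    laguerre_r1rho,
    simulate_cest,
)
from rnaexcite.exchange import laguerre_rate


class TestEffectiveFieldGeometry:
    def test_on_resonance_is_perpendicular(self, rates):
        probe = SpinProbe.from_ppm(1, "N1", 60.8)
        params = ExchangeParams.from_populations(0.0, 0.0)
        sl = SpinLockSetting.from_hz(150.0, 0.0)
        g = effective_field_geometry(params, probe, sl)
        assert g.delta_Omega == 0.0
        assert g.theta == pytest.approx(math.pi / 2)

    def test_population_weighted_average_offset(self):
        probe = SpinProbe(1, "N1", 60.8, omega_GS=0.0, delta_omega=764.0)
        params = ExchangeParams.from_populations(0.062, 453.0)
        sl = SpinLockSetting.from_hz(150.0, 0.0)
        g = effective_field_geometry(params, probe, sl)
        assert g.omega_bar == pytest.approx(0.062 * 764.0)  # 47.37 rad/s

    def test_equal_components_tilt_45_degrees(self):
        # average offset equals the spin-lock strength -> theta = pi/4
        probe = SpinProbe(1, "N1", 60.8, omega_GS=2 * math.pi * 150.0)
        params = ExchangeParams.from_populations(0.0, 0.0)
        sl = SpinLockSetting.from_hz(150.0, 0.0)
        g = effective_field_geometry(params, probe, sl)
        assert g.theta == pytest.approx(math.pi / 4)
        assert math.sin(g.theta) ** 2 + math.cos(g.theta) ** 2 == pytest.approx(1.0)


class TestLaguerre:
    @pytest.mark.parametrize(
        "pES,kex,dw_ppm",
        [(0.0, 453.0, 2.0), (0.062, 453.0, 0.0), (0.0, 0.0, 0.0)],
        ids=["no-ES", "no-shift", "no-exchange"],
    )
    def test_no_exchange_limit_is_tilted_average(self, pES, kex, dw_ppm, rates):
        probe = SpinProbe.from_ppm(1, "N1", 60.8, delta_omega_ppm=dw_ppm)
        params = ExchangeParams.from_populations(pES, kex)
        for offset in (0.0, 120.0, -300.0):
            sl = SpinLockSetting.from_hz(150.0, offset)
            g = effective_field_geometry(params, probe, sl)
            expected = rates.R1 * math.cos(g.theta) ** 2 + rates.R2 * math.sin(g.theta) ** 2
            assert laguerre_r1rho(params, probe, sl, rates) == pytest.approx(
                expected, rel=1e-12
            )

    def test_agrees_with_bloch_mcconnell_in_study_regime(
        self, t1_params, probe_15n, sl_150, rates, delays
    ):
        lg = laguerre_r1rho(t1_params, probe_15n, sl_150, rates)
        bm = bm_evolve_r1rho(t1_params, probe_15n, sl_150, rates, delays)
        assert lg == pytest.approx(bm.rate, rel=0.02)

    def test_large_spin_lock_suppresses_exchange(self, t1_params, probe_15n, rates):
        sl = SpinLockSetting.from_hz(1e6, 200.0)
        g = effective_field_geometry(t1_params, probe_15n, sl)
        base = rates.R1 * math.cos(g.theta) ** 2 + rates.R2 * math.sin(g.theta) ** 2
        assert laguerre_r1rho(t1_params, probe_15n, sl, rates) - base < 1e-3

    def test_exchange_term_monotone_in_spin_lock_on_resonance(
        self, t1_params, probe_15n, rates
    ):
        omega_bar = t1_params.pES * probe_15n.delta_omega
        rex = []
        for p in np.linspace(100.0, 500.0, 20):
            sl = SpinLockSetting(2 * math.pi * p, omega_bar)
            rex.append(laguerre_r1rho(t1_params, probe_15n, sl, rates) - rates.R2)
        assert np.all(np.diff(rex) <= 1e-12)

    def test_denominator_positive_over_study_domain(self):
        rng = np.random.default_rng(42)
        pes = rng.uniform(0.005, 0.5, 2000)
        kex = 10 ** rng.uniform(0, 4, 2000)
        dw = 10 ** rng.uniform(1, 4, 2000)
        wsl = 2 * math.pi * 10 ** rng.uniform(0.5, 3, 2000)
        off = rng.uniform(-2, 2, 2000) * dw
        _, den = laguerre_rate(pes, kex, dw, 2.0, 18.0, wsl, off, 0.0, check=False)
        assert np.all(den > 0)

    def test_seeded_sweep_against_bm_oracle(self, rates, delays):
        rng = np.random.default_rng(7)
        devs = []
        for _ in range(20):
            params = ExchangeParams.from_populations(
                rng.uniform(0.005, 0.10), rng.uniform(300, 2000)
            )
            probe = SpinProbe.from_ppm(1, "N1", 60.8, 0.0, rng.uniform(0.3, 3.0))
            power = rng.uniform(100, 500)
            sl = SpinLockSetting.from_hz(power, rng.uniform(-3, 3) * power)
            lg = laguerre_r1rho(params, probe, sl, rates)
            bm = bm_evolve_r1rho(params, probe, sl, rates, delays).rate
            devs.append(abs(lg - bm) / bm)
        assert np.median(devs) < 0.02
        assert max(devs) < 0.10


class TestBlochMcConnell:
    def test_pure_transverse_decay_without_exchange(self, rates, delays):
        params = ExchangeParams.from_populations(0.0, 0.0)
        probe = SpinProbe.from_ppm(1, "N1", 60.8)
        res = bm_evolve_r1rho(params, probe, SpinLockSetting.from_hz(150.0), rates, delays)
        assert res.rate == pytest.approx(rates.R2, rel=1e-6)

    def test_tilted_frame_mixes_r1_and_r2(self, rates, delays):
        params = ExchangeParams.from_populations(0.0, 0.0)
        probe = SpinProbe(1, "N1", 60.8, omega_GS=2 * math.pi * 1000.0)
        res = bm_evolve_r1rho(
            params, probe, SpinLockSetting.from_hz(1000.0), rates, delays
        )
        assert res.rate == pytest.approx((rates.R1 + rates.R2) / 2, rel=1e-4)

    def test_state_relabelling_symmetry(self, t1_params, probe_15n, sl_150, rates, delays):
        fwd = bm_evolve_r1rho(t1_params, probe_15n, sl_150, rates, delays)
        swapped_probe = SpinProbe(
            probe_15n.residue_id,
            probe_15n.nucleus,
            probe_15n.larmor_MHz,
            omega_GS=probe_15n.omega_ES,
            delta_omega=-probe_15n.delta_omega,
        )
        bwd = bm_evolve_r1rho(
            t1_params.swapped(), swapped_probe, sl_150, rates, delays
        )
        assert fwd.rate == pytest.approx(bwd.rate, rel=1e-10)

    def test_rejects_degenerate_delay_grids(self, t1_params, probe_15n, sl_150, rates):
        with pytest.raises(ValueError, match="3 distinct delays"):
            bm_evolve_r1rho(t1_params, probe_15n, sl_150, rates, [0.0, 0.01])


class TestCEST:
    def setting(self, **kw):
        kw.setdefault("larmor_MHz", 600.0)
        return CESTSetting.ppm_scan(**kw)

    def probe(self, dw=0.5):
        return SpinProbe.from_ppm(1, "H1", 600.0, gs_ppm=12.0, delta_omega_ppm=dw)

    def test_zero_mixing_time_gives_flat_profile(self, t1_params):
        prof = simulate_cest(
            t1_params, self.probe(), self.setting(mixing_time=0.0),
            RelaxationRates(2.5, 30.0),
        )
        assert np.allclose(prof.intensity, 1.0)

    def test_single_state_dips_at_gs_position(self):
        params = ExchangeParams.from_populations(0.0, 0.0)
        setting = self.setting()
        prof = simulate_cest(params, self.probe(), setting, RelaxationRates(2.5, 30.0))
        grid = setting.grid
        assert abs(grid[np.argmin(prof.intensity)] - 12.0) <= grid[1] - grid[0]

    def test_minor_dip_deepens_with_population(self):
        setting = self.setting()
        grid = setting.grid
        near_es = np.abs(grid - 12.5) < 0.15
        depths = []
        for pes in (0.02, 0.04, 0.06):
            params = ExchangeParams.from_populations(pes, 453.0)
            prof = simulate_cest(
                params, self.probe(), setting, RelaxationRates(2.5, 30.0)
            )
            depths.append(1.0 - prof.intensity[near_es].min())
        assert depths[0] < depths[1] < depths[2]

    def test_grid_must_be_monotone(self):
        with pytest.raises(ValueError, match="monotone"):
            CESTSetting(b1_Hz=15.0, mixing_time=0.2, carrier_grid=(9.0, 8.5, 10.0))


class TestTypes:
    @given(st.floats(-20, 20).filter(lambda x: abs(x) > 1e-6))
    def test_ppm_rads_round_trip(self, ppm):
        probe = SpinProbe.from_ppm(1, "N3", 60.8)
        back = probe.rads_to_ppm(probe.ppm_to_rads(ppm))
        assert back == pytest.approx(ppm, rel=1e-9)

    @given(st.floats(1e-4, 0.999), st.floats(1.0, 1e5))
    def test_exchange_params_internal_consistency(self, pes, kex):
        p = ExchangeParams.from_populations(pes, kex)
        assert p.pGS + p.pES == pytest.approx(1.0, abs=1e-12)
        assert p.kex == pytest.approx(p.k1 + p.kminus1, rel=1e-9)
        assert p.k1 == pytest.approx(p.pES * p.kex, rel=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pGS=0.9, pES=0.2, kex=100.0, k1=20.0, kminus1=90.0),
            dict(pGS=0.9, pES=0.1, kex=100.0, k1=50.0, kminus1=50.0),
            dict(pGS=0.9, pES=0.1, kex=-1.0, k1=-0.1, kminus1=-0.9),
        ],
    )
    def test_inconsistent_exchange_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExchangeParams(**kwargs)

    def test_spin_lock_requires_positive_field(self):
        with pytest.raises(ValueError):
            SpinLockSetting(omega_SL=0.0)

    def test_r1_exceeding_r2_is_flagged_not_fatal(self):
        assert RelaxationRates(R1=5.0, R2=2.0).suspicious
        assert not RelaxationRates(R1=2.0, R2=18.0).suspicious
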