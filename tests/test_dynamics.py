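"""EMA lag filter and the full daily site simulation."""

import numpy as np
import pandas as pd
import pytest

from prolai import (DEFAULT_CONSTANTS, SyntheticForcingSpec,
                    alpha_from_memory_days, ema_update, generate_forcing,
                    simulate_site)


def ema_series(ls, alpha, init):
    out = np.empty(len(ls))
    prev = init
    for i, v in enumerate(ls):
        prev = ema_update(prev, v, alpha)
        out[i] = prev
    return out


class TestAlphaMapping:
    @pytest.mark.parametrize("days,alpha", [
        (3, 0.333), (7, 0.143), (10, 0.1), (15, 0.067), (20, 0.05),
        (25, 0.04), (30, 0.033), (45, 0.022), (60, 0.017),
    ])
    def test_memory_day_pairs(self, days, alpha):
        assert alpha_from_memory_days(days) == pytest.approx(alpha,
                                                             abs=5e-4)

    def test_one_day_means_no_memory(self):
        assert alpha_from_memory_days(1) == 1.0

    def test_sub_day_memory_rejected(self):
        with pytest.raises(ValueError):
            alpha_from_memory_days(0.5)


class TestEMAUpdate:
    def test_alpha_one_tracks_input(self):
        assert ema_update(5.0, 2.0, 1.0) == 2.0

    def test_fixed_point(self):
        assert ema_update(3.3, 3.3, 0.067) == pytest.approx(3.3, rel=1e-14)

    def test_geometric_approach_closed_form(self):
        """Starting at 0 with constant input c, after n steps the EMA equals
        c(1 − (1 − α)ⁿ)."""
        alpha, c, n = 0.067, 2.0, 40
        out = ema_series([c] * n, alpha, 0.0)
        assert out[-1] == pytest.approx(c * (1 - (1 - alpha) ** n),
                                        rel=1e-12)

    def test_invalid_alpha(self):
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                ema_update(1.0, 1.0, bad)

    def test_phase_lag_grows_as_alpha_shrinks(self):
        """On a 365-day sinusoid the EMA peak trails the input peak, and the
        delay grows monotonically as the memory lengthens."""
        doy = np.arange(3 * 365)
        ls = 2.0 + 1.5 * np.sin(2 * np.pi * (doy - 91) / 365)
        delays = []
        for alpha in (0.333, 0.1, 0.067, 0.033):
            sim = ema_series(ls, alpha, ls[0])
            yr = slice(2 * 365, 3 * 365)
            delay = (np.argmax(sim[yr]) - np.argmax(ls[yr])) % 365
            delays.append(delay)
            assert delay > 0
        assert all(b > a for a, b in zip(delays, delays[1:]))


class TestSimulateSite:
    def test_determinism(self, two_year_forcing):
        t1 = simulate_site(two_year_forcing, ai=1.2)
        t2 = simulate_site(two_year_forcing.copy(), ai=1.2)
        assert np.max(np.abs(t1.daily["lai_sim"].to_numpy()
                             - t2.daily["lai_sim"].to_numpy())) <= 1e-12

    def test_output_shapes(self, two_year_forcing):
        traj = simulate_site(two_year_forcing, ai=1.2)
        assert len(traj.daily) == len(two_year_forcing)
        assert list(traj.annual["year"]) == [2001, 2002]
        assert set(traj.daily.columns) == {"date", "a0_gc_m2_d", "ls",
                                           "lai_sim"}

    def test_lai_sim_bounded_by_steady_state_range(self, two_year_forcing):
        traj = simulate_site(two_year_forcing, ai=1.2)
        ls = traj.daily["ls"].to_numpy()
        sim = traj.daily["lai_sim"].to_numpy()
        assert np.all(sim >= ls.min() - 1e-12)
        assert np.all(sim <= ls.max() + 1e-12)
        assert np.all(sim <= traj.annual["lai_max"].max() + 1e-12)

    def test_year_boundary_continuity(self):
        forcing = generate_forcing(SyntheticForcingSpec(years=3, seed=9))
        traj = simulate_site(forcing, ai=1.2)
        sim = traj.daily["lai_sim"].to_numpy()
        ls = traj.daily["ls"].to_numpy()
        dates = pd.to_datetime(traj.daily["date"])
        jan1 = np.flatnonzero((dates.dt.month == 1) & (dates.dt.day == 1))
        alpha = DEFAULT_CONSTANTS.alpha
        span = ls.max() - ls.min()
        for i in jan1[1:]:
            assert abs(sim[i] - sim[i - 1]) <= alpha * span + 1e-12

    def test_constant_forcing_converges_to_steady_state(self):
        """Constant warm weather: L_s is a constant c < LAI_max and the EMA
        converges to it geometrically."""
        spec = SyntheticForcingSpec(
            years=3, tair_mean=18.0, tair_amp=0.0, ppfd_mean=30.0,
            ppfd_amp=0.0, vpd_mean=800.0, vpd_amp=0.0, tair_noise_sd=0.0,
            ppfd_noise_sd=0.0, vpd_noise_sd=0.0, wet_day_prob=1.0, seed=1)
        forcing = generate_forcing(spec)
        # make precipitation exactly constant too
        forcing["precip_mm"] = 800.0 / 365.25
        traj = simulate_site(forcing, ai=1.2)
        ls = traj.daily["ls"].to_numpy()
        assert np.allclose(ls, ls[0], atol=1e-9)
        assert traj.daily["lai_sim"].iloc[-1] == pytest.approx(ls[0],
                                                               abs=1e-8)

    def test_cold_dark_forcing_gives_zero_lai(self):
        spec = SyntheticForcingSpec(
            years=1, tair_mean=-10.0, tair_amp=2.0, ppfd_mean=2.0,
            ppfd_amp=1.0, tair_noise_sd=0.0, ppfd_noise_sd=0.0,
            vpd_noise_sd=0.0, seed=1)
        traj = simulate_site(generate_forcing(spec), ai=1.2)
        assert np.all(traj.daily["lai_sim"].to_numpy() == 0.0)
        assert traj.annual["lai_max"].iloc[0] == 0.0

    def test_spin_up_changes_only_early_transient(self, two_year_forcing):
        with_spin = simulate_site(two_year_forcing, ai=1.2, spin_up=True)
        without = simulate_site(two_year_forcing, ai=1.2, spin_up=False)
        late = slice(-200, None)
        assert np.allclose(
            with_spin.daily["lai_sim"].to_numpy()[late],
            without.daily["lai_sim"].to_numpy()[late], atol=1e-6)

    def test_gap_in_forcing_rejected(self, two_year_forcing):
        broken = two_year_forcing.drop(index=100)
        with pytest.raises(ValueError, match="missing dates"):
            simulate_site(broken, ai=1.2)

    def test_fractional_year_rejected(self, two_year_forcing):
        with pytest.raises(ValueError, match="calendar year"):
            simulate_site(two_year_forcing.iloc[:-30], ai=1.2)

    def test_memory_days_lengthens_lag(self, two_year_forcing):
        fast = simulate_site(
            two_year_forcing, ai=1.2,
            constants=DEFAULT_CONSTANTS.with_updates(alpha=0.333))
        slow = simulate_site(
            two_year_forcing, ai=1.2,
            constants=DEFAULT_CONSTANTS.with_updates(alpha=0.017))
        # slower memory damps day-to-day variability
        assert slow.daily["lai_sim"].diff().abs().max() \
            < fast.daily["lai_sim"].diff().abs().max()
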