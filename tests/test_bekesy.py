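import numpy as np
import pytest

from vptsim import (
    BekesyConfig,
    LatencyModel,
    RunawayTrackError,
    bekesy_threshold,
    run_bekesy,
    single_condition_observer,
)
from vptsim.observer import DETERMINISTIC_STEP


def make_gauss(mu=110.0, sigma=4.0, seed=0, latency=None, guess=0.0):
    return single_condition_observer(
        mu, sigma, guess_rate=guess, seed=seed,
        latency=latency or LatencyModel(kind="zero"))


class TestHandTrace:
    """Deterministic step observer (mu = 12) on the identity-dB device."""

    @pytest.fixture()
    def track(self, step_observer, identity_device):
        return run_bekesy(step_observer(12.0), 250.0, "index", identity_device)

    def test_initial_ramp_and_first_reversals(self, track):
        percents = [e.percent for e in track.events[:4]]
        assert percents == [5.0, 10.0, 15.0, 10.0]
        levels = [r.level_db for r in track.reversals[:4]]
        assert levels == [15.0, 10.0, 12.0, 10.0]

    def test_late_reversals_alternate_12_10(self, track):
        late = [r.level_db for r in track.reversals[2:]]
        assert late == [12.0, 10.0] * (len(late) // 2)

    def test_completed_with_enough_time_and_reversals(self, track):
        assert track.termination_reason == "completed"
        assert track.elapsed_s >= 30.0
        assert len(track.reversals) >= 8

    def test_reversals_bracket_mu_within_fine_step(self, track):
        for lo, hi in zip(track.reversals[3::2], track.reversals[2::2]):
            assert hi.level_db - lo.level_db == pytest.approx(2.0)
            assert lo.level_db <= 12.0 <= hi.level_db

    def test_estimate_is_11(self, track):
        est = bekesy_threshold(track)
        assert est.vpt_db == pytest.approx(11.0)
        assert est.reversals_used % 2 == 0


class TestDegenerateObservers:
    def test_never_detecting_terminates_ceiling(self, identity_device):
        obs = make_gauss(mu=1e9)
        track = run_bekesy(obs, 250.0, "index", identity_device)
        assert track.termination_reason == "ceiling"
        assert track.press_times == []
        # 20 ticks of +5% reach 100%
        assert track.events[19].percent == 100.0
        assert all(e.percent == 100.0 for e in track.events[19:])

    def test_always_detecting_terminates_floor(self, identity_device):
        obs = make_gauss(mu=-1e9, guess=1.0)
        track = run_bekesy(obs, 250.0, "index", identity_device)
        assert track.termination_reason == "floor"
        assert len(track.reversals) == 1  # single press at the first epoch
        assert track.reversals[0].t_s == pytest.approx(1.25)
        assert bekesy_threshold(track).vpt_db is None

    def test_runaway_guard_trips(self, identity_device):
        obs = make_gauss(mu=50.0, sigma=4.0, seed=3)
        cfg = BekesyConfig(min_duration_s=200.0, max_duration_s=100.0)
        with pytest.raises(RunawayTrackError):
            run_bekesy(obs, 250.0, "index", identity_device, cfg)


class TestTrackInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_completed_track_structure(self, bench_device, seed):
        track = run_bekesy(make_gauss(seed=seed), 250.0, "index", bench_device)
        assert track.termination_reason == "completed"
        assert track.elapsed_s >= 30.0
        assert len(track.reversals) >= 8
        # timestamps tick regularly; reversal times increase
        ts = [e.t_s for e in track.events]
        assert np.allclose(np.diff(ts), 1.25)
        rts = [r.t_s for r in track.reversals]
        assert all(a < b for a, b in zip(rts, rts[1:]))
        # presses and reversals coincide; final state parity matches count
        assert len(track.press_times) == len(track.reversals)
        assert track.events[-1].reported_state == (len(track.reversals) % 2 == 1)
        assert all(0.0 <= e.percent <= 100.0 for e in track.events)

    def test_translation_equivariance_deterministic(self, step_observer, identity_device):
        """Shifting mu by a step-commensurate delta shifts every reversal."""
        base = run_bekesy(step_observer(12.0), 250.0, "index", identity_device)
        shifted = run_bekesy(step_observer(22.0), 250.0, "index", identity_device)
        for a, b in zip(base.reversals, shifted.reversals):
            assert b.level_db - a.level_db == pytest.approx(10.0)

    def test_translation_equivariance_stochastic(self, bench_device):
        """Mean estimate shifts by delta within Monte-Carlo error."""
        delta = 7.0
        seeds = np.random.SeedSequence(314).spawn(200)
        base, shifted = [], []
        for s in seeds:
            a = bekesy_threshold(run_bekesy(make_gauss(110.0, seed=s),
                                            250.0, "index", bench_device))
            b = bekesy_threshold(run_bekesy(make_gauss(110.0 + delta, seed=s),
                                            250.0, "index", bench_device))
            if a.vpt_db is not None and b.vpt_db is not None:
                base.append(a.vpt_db)
                shifted.append(b.vpt_db)
        assert np.mean(shifted) - np.mean(base) == pytest.approx(delta, abs=0.5)

    def test_detection_latency_raises_thresholds(self, bench_device):
        """Latency on 'detected' presses only inflates the tracked threshold:
        the ramp keeps rising while the press is in flight."""
        lat = LatencyModel(kind="lognormal", mean_s=1.5, sd_s=0.3,
                           detection_only=True)
        seeds = np.random.SeedSequence(99).spawn(200)
        zero, slow = [], []
        for s in seeds:
            a = bekesy_threshold(run_bekesy(make_gauss(seed=s),
                                            250.0, "index", bench_device))
            b = bekesy_threshold(run_bekesy(make_gauss(seed=s, latency=lat),
                                            250.0, "index", bench_device))
            if a.vpt_db is not None:
                zero.append(a.vpt_db)
            if b.vpt_db is not None:
                slow.append(b.vpt_db)
        assert np.mean(slow) > np.mean(zero)

    def test_unconfigured_condition_fails_fast(self, identity_device, step_observer):
        from vptsim import ConfigurationError

        with pytest.raises(ConfigurationError):
            run_bekesy(step_observer(12.0), 500.0, "ring", identity_device)
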