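"""Centrifuge force derivation, censoring rule and CSV round trip."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blephagrip.centrifuge import (
    CentrifugeTrial,
    InvalidTrialError,
    UnresolvableCensoringError,
    censor_adjust,
    centripetal_acceleration,
    detachment_force,
    force_per_body_weight,
    peak_per_individual,
    read_trials_csv,
    trials_to_dataframe,
    write_trials_csv,
)


def trial(species="sp", ind="i1", tid="t1", mass_mg=10.0, radius_mm=70.0,
          freq=20.0, detached=True):
    return CentrifugeTrial(
        species=species, individual_id=ind, trial_id=tid,
        mass=mass_mg * 1e-6, radius=radius_mm * 1e-3, freq=freq,
        detached=detached,
    )


class TestDetachmentForce:
    def test_hand_evaluated_example(self):
        # 10 mg at 20 rps, 70 mm radius: m (2 pi f)^2 r = 11.05 mN
        f = detachment_force(mass=10e-6, freq=20.0, radius=0.07)
        assert f * 1e3 == pytest.approx(11.05, rel=1e-3)

    def test_no_rotation_no_force(self):
        assert detachment_force(10e-6, 0.0, 0.07) == 0.0

    def test_quadratic_in_frequency(self):
        f1 = detachment_force(10e-6, 20.0, 0.07)
        f2 = detachment_force(10e-6, 40.0, 0.07)
        assert f2 == pytest.approx(4.0 * f1)

    @given(
        k=st.floats(0.01, 100),
        mass=st.floats(1e-7, 1e-3),
        freq=st.floats(0.1, 75.0),
        radius=st.floats(0.01, 0.2),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linear_scaling_in_mass(self, k, mass, freq, radius):
        assert detachment_force(k * mass, freq, radius) == pytest.approx(
            k * detachment_force(mass, freq, radius), rel=1e-12
        )

    @pytest.mark.parametrize("bad", [{"mass": -1e-6}, {"mass": 0.0},
                                     {"radius": 0.0}, {"freq": -1.0}])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = {"mass": 10e-6, "freq": 20.0, "radius": 0.07, **bad}
        with pytest.raises(InvalidTrialError):
            detachment_force(**kwargs)


class TestForcePerBodyWeight:
    def test_hand_evaluated_example(self):
        assert force_per_body_weight(20.0, 0.07, g=9.81) == pytest.approx(
            112.7, rel=1e-3
        )

    def test_unit_body_weight(self):
        # choose f so that (2 pi f)^2 r = g exactly
        g, r = 9.81, 0.07
        f = math.sqrt(g / r) / (2 * math.pi)
        assert force_per_body_weight(f, r, g=g) == pytest.approx(1.0)

    @given(st.floats(1e-7, 1e-3), st.floats(1e-7, 1e-3))
    @settings(max_examples=25, derandomize=True)
    def test_mass_independent(self, m1, m2):
        t1, t2 = trial(mass_mg=m1 * 1e6), trial(mass_mg=m2 * 1e6)
        r1, r2 = censor_adjust([t1, t2])
        assert r1.force_per_body_weight == pytest.approx(r2.force_per_body_weight)


class TestCensorAdjust:
    def test_substitution_uses_species_max_detached_acceleration(self):
        trials = [
            trial(ind="a", tid="a1", freq=50.0),
            trial(ind="b", tid="b1", freq=60.0),  # fastest detached
            trial(ind="c", tid="c1", freq=75.0, detached=False),
        ]
        out = censor_adjust(trials)
        expected = centripetal_acceleration(75.0, 0.07)
        a_max_detached = centripetal_acceleration(60.0, 0.07)
        censored = out[2]
        assert censored.censored_substituted
        # the censored larva held on beyond the fastest detached one, so its
        # own (higher) ceiling acceleration is kept
        assert censored.acceleration == pytest.approx(max(expected, a_max_detached))
        assert not out[0].censored_substituted and not out[1].censored_substituted

    def test_toy_substitution_value(self):
        # detached max acceleration 5000 m/s2 replaces the censored trial's
        r = 0.07
        f_detached = math.sqrt(5000.0 / r) / (2 * math.pi)
        trials = [
            trial(ind="a", tid="a1", freq=f_detached),
            trial(ind="b", tid="b1", freq=10.0),
            trial(ind="c", tid="c1", freq=20.0, detached=False),
        ]
        out = censor_adjust(trials)
        assert out[2].acceleration == pytest.approx(5000.0, rel=1e-9)
        assert out[2].force == pytest.approx(out[2].trial.mass * 5000.0)

    def test_no_censored_passthrough(self):
        trials = [trial(ind=c, tid=c, freq=f) for c, f in [("a", 30), ("b", 40)]]
        out = censor_adjust(trials)
        for t, r in zip(trials, out):
            assert r.acceleration == pytest.approx(
                centripetal_acceleration(t.freq, t.radius)
            )
            assert not r.censored_substituted

    def test_never_decreases_acceleration_and_idempotent(self):
        trials = [
            trial(ind="a", tid="a1", freq=55.0),
            trial(ind="b", tid="b1", freq=40.0, detached=False),
            trial(ind="c", tid="c1", freq=75.0, detached=False),
        ]
        out = censor_adjust(trials)
        for t, r in zip(trials, out):
            assert r.acceleration >= centripetal_acceleration(t.freq, t.radius) - 1e-9
        # idempotence: feed substituted accelerations back as detached trials
        refit = [
            CentrifugeTrial(
                species=r.species, individual_id=r.individual_id,
                trial_id=r.trial.trial_id, mass=r.trial.mass,
                radius=r.trial.radius,
                freq=math.sqrt(r.acceleration / r.trial.radius) / (2 * math.pi),
                detached=r.trial.detached,
            )
            for r in out
        ]
        out2 = censor_adjust(refit)
        for r, r2 in zip(out, out2):
            assert r2.acceleration == pytest.approx(r.acceleration, rel=1e-12)

    def test_all_censored_species_raises(self):
        trials = [trial(species="only_censored", freq=75.0, detached=False)]
        with pytest.raises(UnresolvableCensoringError):
            censor_adjust(trials)


class TestPeakPerIndividual:
    def test_max_across_repeats(self):
        trials = [
            trial(ind="a", tid="a1", freq=30.0),
            trial(ind="a", tid="a2", freq=25.0),
            trial(ind="b", tid="b1", freq=20.0),
        ]
        peaks = peak_per_individual(censor_adjust(trials))
        assert len(peaks) == 2
        assert peaks[0].trial.trial_id == "a1"

    def test_brute_force_over_four_repeats(self):
        freqs = [22.0, 31.0, 27.5, 29.0]
        trials = [trial(ind="a", tid=f"a{i}", freq=f) for i, f in enumerate(freqs)]
        results = censor_adjust(trials)
        expected = max(results, key=lambda r: r.force)
        assert peak_per_individual(results)[0] is expected

    def test_single_repeat_is_itself(self):
        results = censor_adjust([trial()])
        assert peak_per_individual(results)[0] is results[0]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            peak_per_individual([])


class TestTrialCsv:
    def test_round_trip_preserves_values(self, tmp_path):
        trials = [
            trial(ind="a", tid="a1", mass_mg=3.21, radius_mm=68.5, freq=41.137),
            trial(ind="b", tid="b1", mass_mg=7.77, radius_mm=70.0, freq=75.0,
                  detached=False),
        ]
        path = tmp_path / "trials.csv"
        write_trials_csv(trials, path)
        back = read_trials_csv(path)
        assert back == trials
        # a second write is byte-identical (formatting rule is stable)
        path2 = tmp_path / "again.csv"
        write_trials_csv(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_ceiling_enforced_at_parse(self, tmp_path):
        df = trials_to_dataframe([trial(freq=80.0)])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(InvalidTrialError):
            read_trials_csv(path, ceiling=75.0)
        assert len(read_trials_csv(path, ceiling=None)) == 1
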