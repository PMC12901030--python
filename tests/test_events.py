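"""Event detection, IEI histograms, shuffle nulls, modes, sweeps, regression."""

import numpy as np
import pandas as pd
import pytest

from attnrhythm.attention import AttentionTrace
from attnrhythm.events import (
    attach_null,
    boxcar_smooth,
    choice_regression,
    conditioned_iei,
    detect_events,
    detect_histogram_modes,
    event_counts_by_value,
    event_matrix,
    iei_histogram,
    label_stay_switch,
    local_maxima,
    modulation_intensity,
    threshold_sweep,
    trial_shuffle_null,
)

from conftest import make_ground_truth_events, make_poisson_events
from attnrhythm.synth import AttentionProcessSpec

FS = 400.0


def toy_trace(n=400, blocks=(), angles=(), n_trials=1):
    """Trace with unit-amplitude MAS/length blocks at given sample spans."""
    length = np.zeros((n_trials, n))
    mas = np.zeros((n_trials, n))
    angle = np.full((n_trials, n), 60.0)
    for (a, b), ang in zip(blocks, angles):
        length[0, a:b] = 1.0
        mas[0, a:b] = 1.0
        angle[0, a:b] = ang
    return AttentionTrace(length=length, angle=angle, mas=mas, fs=FS, t0=0.0)


class TestDetection:
    def test_two_blocks_two_events(self):
        tr = toy_trace(blocks=[(50, 80), (150, 180)], angles=[0.0, 120.0])
        ev = detect_events(tr)
        assert len(ev) == 2
        assert list(ev["locus"]) == [0.0, 120.0]
        assert np.allclose(ev["onset"], [50 / FS, 150 / FS])

    def test_refractory_merges_close_crossings(self):
        # two crossings 8 samples (0.02 s) apart at the same locus
        tr = toy_trace(blocks=[(50, 53), (58, 100)], angles=[0.0, 0.0])
        ev = detect_events(tr)
        assert len(ev) == 1

    def test_spacing_respects_refractory(self, decision_trace):
        ev = detect_events(decision_trace, stim_window=(0.0, 3.8))
        for _, grp in ev.groupby("trial"):
            if len(grp) > 1:
                assert np.diff(grp["onset"].to_numpy()).min() >= 0.025 - 1e-9

    def test_subthreshold_trace_yields_no_events(self):
        # an all-zero channel response has no vector direction anywhere,
        # so no sample can pass the MAS gate
        from attnrhythm.attention import attentional_vector
        tr = attentional_vector(np.zeros((2, 3, 400)), fs=FS)
        assert len(detect_events(tr)) == 0

    def test_locus_change_while_suprathreshold_is_an_event(self):
        tr = toy_trace(blocks=[(50, 75), (75, 100)], angles=[0.0, 120.0])
        ev = detect_events(tr)
        assert len(ev) == 2
        assert list(ev["label"]) == ["first", "switch"]

    def test_detections_enriched_at_planted_times_at_unit_snr(
            self, decision_session, decision_trace):
        # at snr=1 single events are noise-limited; detections must still
        # be strongly enriched at planted onsets (chance ~= rate*3/fs ~ 0.08)
        _, truth, _ = decision_session
        det = detect_events(decision_trace, stim_window=(0.0, 3.8))
        hits = 0
        for _, ev in det.iterrows():
            tt = truth.loc[truth["trial"] == ev["trial"], "onset"].to_numpy()
            if len(tt) and np.min(np.abs(tt - ev["onset"])) <= 1.5 / FS:
                hits += 1
        assert hits / len(det) > 0.16  # >2x the chance rate

    def test_high_snr_recovery_of_onsets_and_labels(self, fm):
        # At high snr the detector must land on planted onsets to the
        # sample and the stay/switch labeler must agree with the planted
        # labels.  mas_pct is lowered because with negligible noise the
        # MAS is ~1 everywhere and its within-dataset percentile would
        # rank numerical ties.
        from attnrhythm.design import enumerate_design
        from attnrhythm.encoding import train_encoding_model, invert_model
        from attnrhythm.attention import attentional_vector
        from attnrhythm.synth import simulate_decision_session, simulate_localizer
        loc = simulate_localizer(fm, n_blocks=2, snr=20.0, seed=21)
        model = train_encoding_model(loc, training_window=(0.14, 0.17))
        epochs, truth, _ = simulate_decision_session(
            enumerate_design(), fm, AttentionProcessSpec(), n_trials=20,
            seed=22, snr=20.0)
        tr = attentional_vector(invert_model(model, epochs))
        det = detect_events(tr, mas_pct=50.0, stim_window=(0.0, 3.8))
        hits = agree = total = 0
        for _, ev in det.iterrows():
            sel = truth["trial"] == ev["trial"]
            tt = truth.loc[sel, "onset"].to_numpy()
            if not len(tt):
                continue
            j = np.argmin(np.abs(tt - ev["onset"]))
            if abs(tt[j] - ev["onset"]) <= 1.5 / FS:
                hits += 1
                planted = truth.loc[sel].iloc[j]
                if ev["label"] != "first":
                    total += 1
                    agree += planted["label"] == ev["label"]
        assert hits / len(det) > 0.9   # onsets recovered to ~the sample
        assert total > 50
        assert agree / total > 0.9     # labels agree with planted


class TestLabeling:
    def test_label_sequence(self):
        ev = pd.DataFrame(dict(
            trial=[0] * 5,
            onset=np.arange(5) * 0.1,
            locus=[0.0, 0.0, 120.0, 120.0, 240.0],
        ))
        lab = label_stay_switch(ev)
        assert list(lab["label"]) == ["first", "stay", "switch", "stay", "switch"]

    def test_single_event_per_trial_has_no_sequence_label(self):
        ev = pd.DataFrame(dict(trial=[0, 1], onset=[0.1, 0.2],
                               locus=[0.0, 120.0]))
        lab = label_stay_switch(ev)
        assert list(lab["label"]) == ["first", "first"]


class TestHistogram:
    def test_fixed_interval_single_bin(self):
        ev = pd.DataFrame(dict(trial=np.repeat(np.arange(30), 2),
                               onset=np.tile([0.5, 0.6], 30),
                               locus=0.0))
        h = iei_histogram(ev, FS)
        k = np.argmin(np.abs(h.lags - 0.1))
        assert h.prob[k] == pytest.approx(1.0)
        assert h.prob.sum() == pytest.approx(1.0)

    def test_alternating_intervals_split_half(self):
        onsets = [0.5, 0.59, 0.77]  # gaps 0.09 and 0.18
        ev = pd.DataFrame(dict(trial=np.repeat(np.arange(20), 3),
                               onset=np.tile(onsets, 20), locus=0.0))
        h = iei_histogram(ev, FS)
        k1 = np.argmin(np.abs(h.lags - 0.09))
        k2 = np.argmin(np.abs(h.lags - 0.18))
        assert h.prob[k1] == pytest.approx(0.5)
        assert h.prob[k2] == pytest.approx(0.5)

    def test_poisson_intervals_decay_exponentially(self):
        ev = make_poisson_events(400, rate=8.0, seed=5)
        h = iei_histogram(ev, FS)
        expected = (np.exp(-8.0 * h.lags)
                    - np.exp(-8.0 * (h.lags + 1 / FS)))
        r = np.corrcoef(h.prob, expected)[0, 1]
        assert r > 0.95

    def test_long_intervals_count_in_denominator(self):
        ev = pd.DataFrame(dict(trial=[0, 0, 0], onset=[0.1, 0.2, 1.5],
                               locus=0.0))  # gaps 0.1 and 1.3 (> 0.5)
        h = iei_histogram(ev, FS)
        assert h.n_intervals == 2
        assert h.prob.sum() == pytest.approx(0.5)

    def test_no_intervals_raises(self):
        ev = pd.DataFrame(dict(trial=[0, 1], onset=[0.1, 0.2], locus=0.0))
        with pytest.raises(ValueError):
            iei_histogram(ev, FS)

    def test_invariant_to_trial_relabeling(self):
        ev = make_poisson_events(50, rate=6.0, seed=6)
        h1 = iei_histogram(ev, FS)
        perm = np.random.default_rng(0).permutation(50)
        ev2 = ev.assign(trial=perm[ev["trial"].to_numpy()])
        h2 = iei_histogram(ev2, FS)
        assert np.allclose(h1.prob, h2.prob)


class TestShuffleNull:
    def test_per_timepoint_counts_conserved(self):
        ev = make_poisson_events(80, rate=8.0, seed=7)
        mat = event_matrix(ev, 80, 1520, FS)
        rng = np.random.default_rng(1)
        perm = np.argsort(rng.random(mat.shape), axis=0)
        shuf = np.take_along_axis(mat, perm, axis=0)
        assert np.array_equal((mat >= 0).sum(axis=0), (shuf >= 0).sum(axis=0))

    def test_fixed_seed_bit_identical(self):
        ev = make_poisson_events(40, rate=6.0, seed=8)
        a = trial_shuffle_null(ev, 40, 1520, FS, n_shuffles=10, seed=3)
        b = trial_shuffle_null(ev, 40, 1520, FS, n_shuffles=10, seed=3)
        assert np.array_equal(a, b)

    def test_single_trial_raises(self):
        ev = pd.DataFrame(dict(trial=[0, 0], onset=[0.1, 0.2], locus=0.0))
        with pytest.raises(ValueError):
            trial_shuffle_null(ev, 1, 1520, FS)

    def test_independent_events_sit_inside_null_band(self):
        ev = make_poisson_events(200, rate=8.0, seed=9)
        h = iei_histogram(ev, FS)
        null = trial_shuffle_null(ev, 200, 1520, FS, n_shuffles=200, seed=4)
        attach_null(h, null)
        z = np.abs(h.prob - h.null_mean) / np.where(h.null_sd > 0,
                                                    h.null_sd, np.inf)
        assert np.mean(z > 2) < 0.10  # approx the nominal two-sided rate


class TestModes:
    def test_planted_rhythm_cycle_length(self):
        ev = make_ground_truth_events(AttentionProcessSpec(), 250, seed=10)
        hists = conditioned_iei(ev, 250, 1520, FS, n_shuffles=150, seed=5)
        stay = detect_histogram_modes(hists["stay"])
        assert stay.cycle_length == pytest.approx(1 / 11.0, abs=1.0 / FS)

    def test_smoothing_and_maxima_helpers(self):
        y = np.array([0, 1, 3, 1, 0, 2, 2, 2, 1, 0], dtype=float)
        assert local_maxima(y) == [2, 5]  # plateau takes leftmost sample
        sm = boxcar_smooth(y, 3)
        assert sm.shape == y.shape
        assert sm[0] == pytest.approx((0 + 0 + 1) / 3)  # edge padded

    def test_mode_detection_requires_null(self):
        ev = make_poisson_events(30, rate=6.0, seed=11)
        h = iei_histogram(ev, FS)
        with pytest.raises(ValueError):
            detect_histogram_modes(h)


class TestSecondOrder:
    def test_no_switch_sequences_leave_switch_classes_empty(self):
        ev = pd.DataFrame(dict(trial=np.repeat(np.arange(10), 4),
                               onset=np.tile([0.1, 0.2, 0.3, 0.4], 10),
                               locus=0.0))
        h = conditioned_iei(ev, 10, 200, FS, second_order=True)
        assert h["switch_after_stay"].n_intervals == 0
        assert h["switch_after_switch"].n_intervals == 0
        assert h["stay_after_stay"].n_intervals > 0

    def test_reset_regime_is_history_invariant(self):
        ev = make_ground_truth_events(
            AttentionProcessSpec(reset_on_switch=True), 250, seed=12)
        h = conditioned_iei(ev, 250, 1520, FS, second_order=True,
                            n_shuffles=100, seed=6)
        for h_ in h.values():
            detect_histogram_modes(h_)
        assert abs(h["stay_after_stay"].modes[0][0]
                   - h["stay_after_switch"].modes[0][0]) <= 1.0 / FS
        assert abs(h["switch_after_stay"].modes[0][0]
                   - h["switch_after_switch"].modes[0][0]) <= 1.0 / FS

    def test_follow_regime_offsets_repetitions_from_alternations(self):
        ev = make_ground_truth_events(
            AttentionProcessSpec(reset_on_switch=False), 250, seed=13)
        h = conditioned_iei(ev, 250, 1520, FS, second_order=True,
                            n_shuffles=100, seed=7)
        for h_ in h.values():
            detect_histogram_modes(h_)
        offset = abs(h["stay_after_stay"].modes[0][0]
                     - h["stay_after_switch"].modes[0][0])
        assert offset == pytest.approx(0.5 / 11.0, abs=2.0 / FS)


class TestThresholdSweep:
    def test_grid_has_144_cells(self):
        rng = np.random.default_rng(14)
        n, nt = 600, 10
        length = rng.random((nt, n))
        angle = rng.uniform(0, 360, (nt, n))
        from attnrhythm.attention import max_angular_similarity
        tr = AttentionTrace(length=length, angle=angle,
                            mas=max_angular_similarity(angle), fs=FS)
        grid = threshold_sweep(tr)
        assert grid.shape == (12, 12)
        assert grid.size == 144

    def test_poisson_intensity_below_planted_rhythm(self):
        ev_p = make_poisson_events(250, rate=8.0, seed=15)
        ev_r = make_ground_truth_events(AttentionProcessSpec(), 250, seed=16)
        i_p = modulation_intensity(iei_histogram(ev_p, FS))
        i_r = modulation_intensity(iei_histogram(ev_r, FS))
        assert np.isfinite(i_p) and np.isfinite(i_r)
        assert i_r > 3 * i_p


class TestChoiceRegression:
    def _counts(self, rng, n):
        cols = [f"{lab}_{rk}" for lab in ("stay", "switch")
                for rk in ("H", "M", "L")]
        return pd.DataFrame(rng.poisson(3.0, size=(n, 6)), columns=cols)

    def test_null_coefficients_near_zero(self):
        rng = np.random.default_rng(17)
        counts = self._counts(rng, 600)
        choices = rng.choice(["H", "M", "L"], 600)
        res = choice_regression(counts, choices)
        for outcome, tab in res.items():
            coefs = tab.drop(index="const")["coef"]
            assert np.all(np.abs(coefs) < 0.25)

    def test_sampling_drives_choice_direction(self):
        rng = np.random.default_rng(18)
        n = 600
        counts = self._counts(rng, n)
        drive = counts["stay_H"] + counts["switch_H"]
        p = 1 / (1 + np.exp(-(drive - drive.mean())))
        choices = np.where(rng.random(n) < p, "H",
                           rng.choice(["M", "L"], n))
        res = choice_regression(counts, choices)
        assert res["H"].loc["stay_H", "coef"] > 0
        assert res["H"].loc["switch_H", "coef"] > 0

    def test_constant_predictor_dropped(self):
        rng = np.random.default_rng(19)
        counts = self._counts(rng, 100)
        counts["switch_L"] = 2
        with pytest.warns(UserWarning, match="constant predictor"):
            res = choice_regression(counts, rng.choice(["H", "M", "L"], 100))
        assert "switch_L" not in res["H"].index

    def test_too_few_trials(self):
        rng = np.random.default_rng(20)
        with pytest.raises(ValueError):
            choice_regression(self._counts(rng, 10), ["H"] * 10)


def test_event_counts_by_value(decision_session):
    _, events, _ = decision_session
    epochs_meta = decision_session[0].meta
    counts = event_counts_by_value(label_stay_switch(events), epochs_meta)
    labeled = label_stay_switch(events)
    n_labeled = (labeled["label"].isin(["stay", "switch"])).sum()
    assert counts.to_numpy().sum() == n_labeled
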