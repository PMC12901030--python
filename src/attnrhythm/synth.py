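"""Synthetic sessions with planted attentional dynamics.

The generator produces the two epoch types the analysis pipeline
consumes, plus their ground truth:

* localizer epochs — exactly one of the three angular positions is
  stimulated per trial; sensor data follow the linear forward model
  ``X = patterns @ c(position) * r(t) + noise`` with a response
  time-course ``r`` confined to a configurable latency window;
* decision epochs — a latent attention process alternates among the
  three positions; the attended position's channel receives a continuous
  ~11 Hz amplitude modulation plus a short pulse (amplitude drawn per
  event) starting exactly at each planted attentional event, so event
  onsets are recoverable to the sample;
* ground-truth event tables (onset, locus, stay/switch label) for
  parameter-recovery tests downstream.

Two phase regimes are supported.  Under ``stay_at_peak_switch_at_trough``
with ``reset_on_switch=True`` ("reset" regime) the oscillation restarts
at each event: refocusing (stay) events fall one full cycle after the
previous event and reorienting (switch) events half a cycle after it,
regardless of history.  With ``reset_on_switch=False`` ("follow" regime)
the oscillation free-runs and events lock to its absolute peaks/troughs,
so repetition intervals (stay-after-stay, switch-after-switch) sit at
full cycles while alternations sit half a cycle off.  The event pipeline
must discriminate these regimes from the event statistics alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.signal import butter, filtfilt

from .containers import EpochSet, GazeRecord
from .design import (
    POSITIONS,
    ConfigurationError,
    TaskDesign,
    enumerate_localizer_block,
    value_ranks,
)

_N_CHANNELS = 3


@dataclass
class ForwardModel:
    """Linear generative map from angular channels to sensors.

    patterns : (sensors, 3) sensor gain per angular channel
    noise_cov : (sensors, sensors) symmetric positive-definite
    snr : default signal-to-noise amplitude ratio used by the simulators
    """

    patterns: np.ndarray
    noise_cov: np.ndarray
    snr: float = 1.0

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.patterns.ndim != 2 or self.patterns.shape[1] != _N_CHANNELS:
            raise ConfigurationError("patterns must be (sensors, 3)")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ConfigurationError("noise_cov must be symmetric")
        w = np.linalg.eigvalsh(self.noise_cov)
        if w.min() <= 0:
            raise ConfigurationError("noise_cov must be positive definite")
        if np.linalg.matrix_rank(self.patterns) < _N_CHANNELS:
            raise ConfigurationError("patterns must have full column rank")
        # Cache a Cholesky factor for fast correlated-noise draws.
        self._chol = np.linalg.cholesky(self.noise_cov)

    @property
    def n_sensors(self) -> int:
        return self.patterns.shape[0]

    def draw_noise(self, shape: tuple[int, ...], snr: float,
                   rng: np.random.Generator) -> np.ndarray:
        """Gaussian noise with covariance ``noise_cov / snr**2``.

        ``shape`` is (..., sensors, time); sensors mix through the
        Cholesky factor, time samples are independent (white in time).
        """
        if np.isinf(snr):
            return np.zeros(shape)
        z = rng.standard_normal(shape)
        return np.einsum("ij,...jn->...in", self._chol, z) / snr


def make_forward_model(
    n_sensors: int,
    seed: int,
    noise_structure: str = "random_spd",
    snr: float = 1.0,
) -> ForwardModel:
    """Reproducible random forward model with unit-norm channel patterns."""
    if n_sensors < _N_CHANNELS:
        raise ConfigurationError("need at least 3 sensors for 3 channels")
    if noise_structure not in ("identity", "random_spd"):
        raise ConfigurationError(f"unknown noise_structure {noise_structure!r}")
    rng = np.random.default_rng(seed)
    patterns = rng.standard_normal((n_sensors, _N_CHANNELS))
    patterns /= np.linalg.norm(patterns, axis=0, keepdims=True)
    if noise_structure == "identity":
        cov = np.eye(n_sensors)
    else:
        a = rng.standard_normal((n_sensors, 2 * n_sensors))
        cov = a @ a.T / (2 * n_sensors)
        cov /= np.mean(np.diag(cov))  # unit average sensor variance
    return ForwardModel(patterns=patterns, noise_cov=cov, snr=snr)


# ---------------------------------------------------------------------------
# Latent attention process
# ---------------------------------------------------------------------------

@dataclass
class AttentionProcessSpec:
    """Configuration of the latent attentional rhythm.

    osc_freq : oscillation frequency, Hz (default 11)
    osc_depth : modulation depth of the continuous strength oscillation,
        in [0, 1]
    phase_policy : "stay_at_peak_switch_at_trough" locks events to the
        oscillation phase; "uniform" plants events at homogeneous-Poisson
        times with random loci (no rhythm)
    reset_on_switch : if True the oscillation phase resets to a peak at
        every event (reset regime); if False it free-runs (follow regime)
    p_event : probability of emitting an event at the first eligible
        phase point; skipped opportunities add whole cycles to the gap
    switch_frac : probability that the next event reorients to a new
        locus rather than refocusing
    event_rate : Poisson event rate, Hz, used only by the uniform policy
    jitter_sd : Gaussian jitter of event times, seconds (0 = exact)
    """

    osc_freq: float = 11.0
    osc_depth: float = 0.5
    phase_policy: str = "stay_at_peak_switch_at_trough"
    reset_on_switch: bool = True
    p_event: float = 0.8
    switch_frac: float = 0.37
    event_rate: float = 8.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.osc_depth <= 1.0:
            raise ConfigurationError("osc_depth must be in [0, 1]")
        if self.phase_policy not in ("stay_at_peak_switch_at_trough", "uniform"):
            raise ConfigurationError(f"unknown phase_policy {self.phase_policy!r}")


@dataclass
class LatentAttentionProcess:
    """One trial's realized latent process (ground truth)."""

    spec: AttentionProcessSpec
    fs: float
    duration: float
    locus_path: np.ndarray        # (n_samples,) locus angle per sample
    phase: np.ndarray             # (n_samples,) oscillation phase, radians
    event_times: np.ndarray       # seconds from trial (stimulus) onset
    event_labels: np.ndarray      # "stay" / "switch"
    event_loci: np.ndarray        # locus angle at/after each event


MIN_EVENT_SPACING = 0.025  # seconds; matches the detector's refractory rule


def sample_attention_process(
    spec: AttentionProcessSpec,
    duration: float,
    fs: float,
    rng: np.random.Generator,
) -> LatentAttentionProcess:
    """Draw one trial of the latent process.

    Events carry their generative label; the locus path changes value
    only at switch events.  Event spacing respects the 0.025 s minimum
    the downstream detector assumes.
    """
    f = spec.osc_freq
    cycle = 1.0 / f
    times: list[float] = []
    labels: list[str] = []
    loci: list[float] = []
    locus = float(rng.choice(POSITIONS))
    initial_locus = locus

    if spec.phase_policy == "uniform":
        t = 0.0
        while True:
            t += rng.exponential(1.0 / spec.event_rate)
            if t >= duration:
                break
            if times and t - times[-1] < MIN_EVENT_SPACING:
                continue
            is_switch = rng.random() < spec.switch_frac
            if is_switch:
                locus = float(rng.choice([p for p in POSITIONS if p != locus]))
            times.append(t)
            labels.append("switch" if is_switch else "stay")
            loci.append(locus)
        phase_ref = 0.0
        reset_times = np.array([])
    elif spec.reset_on_switch:
        # Reset regime: the oscillation restarts (at a peak) at every
        # event.  The next event is a switch with probability
        # ``switch_frac``; its gap from the previous event is half a
        # cycle (trough) for switches, a full cycle (peak) for stays,
        # plus whole skipped cycles with geometric probability.
        t_ref = -rng.uniform(0.0, cycle)  # virtual pre-trial event
        phase_ref = t_ref
        reset: list[float] = []
        while True:
            is_switch = rng.random() < spec.switch_frac
            k = rng.geometric(spec.p_event) - 1  # cycles skipped
            base = 0.5 * cycle if is_switch else cycle
            t_next = t_ref + base + k * cycle
            if spec.jitter_sd > 0:
                t_next += rng.normal(0.0, spec.jitter_sd)
            if t_next >= duration:
                break
            t_ref = t_next
            if t_next < 0 or (times and t_next - times[-1] < MIN_EVENT_SPACING):
                continue
            if is_switch:
                locus = float(rng.choice([p for p in POSITIONS if p != locus]))
            times.append(t_next)
            labels.append("switch" if is_switch else "stay")
            loci.append(locus)
            reset.append(t_next)
        reset_times = np.array(reset)
    else:
        # Follow (free-running) regime: stays lock to the absolute peaks
        # and switches to the absolute troughs of one free-running
        # oscillation.  Per-candidate probabilities reproduce the
        # configured event rate and switch fraction in expectation.
        phase_ref = -rng.uniform(0.0, cycle)  # time of a peak
        q_sw = spec.p_event * spec.switch_frac
        q_st = spec.p_event * (1.0 - spec.switch_frac)
        m = 0
        while True:
            m += 1
            t_cand = phase_ref + 0.5 * m * cycle
            if t_cand >= duration:
                break
            is_trough = bool(m % 2)
            if rng.random() >= (q_sw if is_trough else q_st):
                continue
            t_ev = t_cand
            if spec.jitter_sd > 0:
                t_ev += rng.normal(0.0, spec.jitter_sd)
            if t_ev < 0 or t_ev >= duration:
                continue
            if times and t_ev - times[-1] < MIN_EVENT_SPACING:
                continue
            if is_trough:
                locus = float(rng.choice([p for p in POSITIONS if p != locus]))
            times.append(t_ev)
            labels.append("switch" if is_trough else "stay")
            loci.append(locus)
        reset_times = np.array([])

    n = int(round(duration * fs))
    t_axis = np.arange(n) / fs

    # Phase: free-running from the virtual reference, or piecewise reset
    # to a peak (phase 0) at each event.
    # Event times quantize to the nearest sample everywhere downstream;
    # use the same rule for the piecewise phase and locus path.
    if spec.phase_policy == "uniform" or not spec.reset_on_switch:
        phase = 2 * np.pi * f * (t_axis - phase_ref)
    else:
        last_ref = np.full(n, phase_ref)
        for et in reset_times:
            last_ref[min(int(round(et * fs)), n):] = et
        phase = 2 * np.pi * f * (t_axis - last_ref)

    # Path starts at the initial locus and changes value only at switches.
    locus_path = np.full(n, initial_locus)
    for et, lab, lc in zip(times, labels, loci):
        if lab == "switch":
            locus_path[min(int(round(et * fs)), n):] = lc

    return LatentAttentionProcess(
        spec=spec,
        fs=fs,
        duration=duration,
        locus_path=locus_path,
        phase=phase,
        event_times=np.asarray(times),
        event_labels=np.asarray(labels, dtype=object),
        event_loci=np.asarray(loci),
    )


# ---------------------------------------------------------------------------
# Localizer simulation
# ---------------------------------------------------------------------------

def _channel_response(angles: np.ndarray) -> np.ndarray:
    # Local import avoids a cycle: encoding imports nothing from synth.
    from .encoding import TuningBasis, build_design_matrix

    return build_design_matrix(np.atleast_1d(angles), TuningBasis())


def simulate_localizer(
    fm: ForwardModel,
    n_blocks: int = 18,
    snr: float | None = None,
    seed: int = 0,
    fs: float = 400.0,
    t_pre: float = 0.1,
    t_post: float = 0.35,
    response_window: tuple[float, float] = (0.14, 0.17),
) -> EpochSet:
    """Simulate localizer epochs under the linear forward model.

    Each trial stimulates a single position; the three-channel tuning
    response to that position drives the sensors through ``fm.patterns``
    inside ``response_window`` (a boxcar time-course), on top of
    correlated Gaussian noise scaled by ``1/snr``.
    """
    if snr is None:
        snr = fm.snr
    if not np.isinf(snr) and snr <= 0:
        raise ConfigurationError("snr must be positive")
    rng = np.random.default_rng(seed)
    n = int(round((t_pre + t_post) * fs))
    t = -t_pre + np.arange(n) / fs
    r = ((t >= response_window[0]) & (t < response_window[1])).astype(float)

    rows = []
    for b in range(n_blocks):
        block = enumerate_localizer_block()
        order = rng.permutation(len(block))
        for i in order:
            tr = block[i]
            rows.append(
                dict(position=tr.position, orientation=tr.orientation,
                     flicker=tr.flicker, block=b)
            )
    meta = pd.DataFrame(rows)
    n_trials = len(meta)

    c = _channel_response(meta["position"].to_numpy())      # (3, trials)
    signal = np.einsum("sk,kt,n->tsn", fm.patterns, c, r)    # trials,sensors,time
    data = signal + fm.draw_noise((n_trials, fm.n_sensors, n), snr, rng)
    return EpochSet(data=data, fs=fs, t0=-t_pre, meta=meta)


# ---------------------------------------------------------------------------
# Decision-session simulation
# ---------------------------------------------------------------------------

#: Drive parameters of the attended channel (arbitrary units; the
#: patterns have unit norm so these set the signal scale relative to
#: noise SD = 1/snr).
DRIVE_BASELINE = 0.1
DRIVE_GAIN = 1.0
OSC_COEFF = 0.5            # amplitude of the continuous oscillatory drive
EVENT_PULSE_WIDTH = 0.0125  # seconds (5 samples at 400 Hz)
PULSE_AMP_SPREAD = 0.2      # lognormal sigma of per-event pulse amplitude


def _assign_conditions(design: TaskDesign, n_trials: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    idx = rng.integers(0, design.n_trials, size=n_trials)
    rows = []
    for i in idx:
        tc = design.trial_list[i]
        rows.append(dict(framing=tc.framing, contrasts=tc.contrasts,
                         orientations=tc.orientations))
    return pd.DataFrame(rows)


def simulate_decision_session(
    design: TaskDesign,
    fm: ForwardModel,
    process_spec: AttentionProcessSpec,
    n_trials: int,
    seed: int = 0,
    snr: float | None = None,
    fs: float = 400.0,
    t_pre: float = 1.5,
    stim_duration: float = 3.8,
    choice_follows_sampling: float = 0.35,
    choice_value_bias: float = 0.45,
) -> tuple[EpochSet, pd.DataFrame, list[LatentAttentionProcess]]:
    """Simulate decision epochs with a planted attentional rhythm.

    The attended channel's drive is ``baseline + OSC_COEFF*gain*(1 +
    osc_depth*cos(phase))``; from each planted event onset a pulse of
    ``EVENT_PULSE_WIDTH`` raises it to ``baseline + OSC_COEFF*gain +
    pulse_amp`` with ``pulse_amp`` lognormally spread around ``gain`` —
    the oscillatory part is pinned to its mean during the pulse so pulse
    height is independent of the oscillation phase and percentile
    thresholds cut the event population without label bias.  Unattended
    channels sit at ``baseline``.
    Sensors are ``patterns @ drive`` plus correlated noise of SD
    ``1/snr``.  The drive is zero before stimulus onset (t < 0).

    The reported choice is the correct (highest-value) alternative with
    probability ``choice_value_bias``, the most-sampled alternative with
    probability ``choice_follows_sampling``, and uniform otherwise, so
    choices are above chance (correct trials outnumber errors in a
    stratum, as in the task this emulates) while the per-trial event
    counts still carry decision information for the choice regression.

    Returns (epochs, ground-truth event table, per-trial processes).
    """
    if stim_duration < 3.8 - 1e-9:
        raise ConfigurationError("trial stimulus period must be >= 3.8 s")
    if snr is None:
        snr = fm.snr
    rng = np.random.default_rng(seed)
    n_pre = int(round(t_pre * fs))
    n_stim = int(round(stim_duration * fs))
    n = n_pre + n_stim

    meta = _assign_conditions(design, n_trials, rng)
    data = fm.draw_noise((n_trials, fm.n_sensors, n), snr, rng)

    pulse_len = max(1, int(round(EVENT_PULSE_WIDTH * fs)))
    pos_arr = np.asarray(POSITIONS)

    processes: list[LatentAttentionProcess] = []
    ev_rows = []
    choices, corrects = [], []
    for i in range(n_trials):
        proc = sample_attention_process(process_spec, stim_duration, fs, rng)
        processes.append(proc)

        drive = np.full((_N_CHANNELS, n_stim), DRIVE_BASELINE)
        k_path = np.argmin(
            np.abs(proc.locus_path[:, None] - pos_arr[None, :]), axis=1
        )
        samp = np.arange(n_stim)
        osc = OSC_COEFF * DRIVE_GAIN * (
            1.0 + process_spec.osc_depth * np.cos(proc.phase)
        )
        drive[k_path, samp] += osc
        for et, lc in zip(proc.event_times, proc.event_loci):
            s0 = int(round(et * fs))
            k = int(np.argmin(np.abs(pos_arr - lc)))
            amp = DRIVE_GAIN * np.exp(rng.normal(0.0, PULSE_AMP_SPREAD))
            # during the pulse the oscillatory part is pinned to its mean,
            # so pulse height is label independent and percentile
            # thresholds cut the event population without phase bias
            drive[k, s0:s0 + pulse_len] = (
                DRIVE_BASELINE + OSC_COEFF * DRIVE_GAIN + amp
            )
        data[i, :, n_pre:] += fm.patterns @ drive

        # Choice: value-guided above chance, partly following sampling.
        ranks = value_ranks(meta.loc[i, "contrasts"], meta.loc[i, "framing"])
        counts = {p: int(np.sum(proc.event_loci == p)) for p in POSITIONS}
        target = next(p for p, r in ranks.items() if r == "H")
        u = rng.random()
        if u < choice_value_bias:
            best = target
        elif (u < choice_value_bias + choice_follows_sampling
              and max(counts.values()) > 0):
            best = max(counts, key=lambda p: (counts[p], rng.random()))
        else:
            best = float(rng.choice(pos_arr))
        choices.append(ranks[best])
        corrects.append(best == target)

        for et, lab, lc in zip(proc.event_times, proc.event_labels,
                               proc.event_loci):
            ev_rows.append(dict(trial=i, onset=et, locus=lc, label=lab,
                                source="ground_truth"))

    meta["choice"] = choices
    meta["correct"] = corrects
    meta["block"] = np.arange(n_trials) * 18 // max(n_trials, 1)

    epochs = EpochSet(data=data, fs=fs, t0=-t_pre, meta=meta)
    events = pd.DataFrame(
        ev_rows, columns=["trial", "onset", "locus", "label", "source"]
    )
    return epochs, events, processes


# ---------------------------------------------------------------------------
# Gaze / pupil simulation
# ---------------------------------------------------------------------------

@dataclass
class GazeCoupling:
    """Saccade-to-switch coupling: with probability ``p`` a saccade is
    planted ``delta`` seconds before each switch event."""

    mode: str = "none"               # "none" | "saccade_precedes_switch"
    delta: float = 0.15
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "saccade_precedes_switch"):
            raise ConfigurationError(f"unknown coupling mode {self.mode!r}")
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ConfigurationError("p must be in [0, 1]")


def _lowpass_noise(shape, cutoff_hz: float, fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-SD low-pass Gaussian noise (fixational drift model).

    The noise is generated with padding on both sides and trimmed after
    filtering so the returned traces carry no filter edge transients.
    """
    pad = int(round(2.0 * fs / cutoff_hz))
    w = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    b, a = butter(2, cutoff_hz / (fs / 2.0), btype="low")
    x = filtfilt(b, a, w, axis=-1)[..., pad:pad + shape[-1]]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_gaze(
    events: pd.DataFrame,
    n_trials: int,
    duration: float,
    coupling: GazeCoupling = GazeCoupling(),
    fs: float = 400.0,
    seed: int = 0,
    jitter_sd: float = 0.05,
    drift_cutoff_hz: float = 5.0,
    background_rate: float = 1.5,
    step_amplitude: tuple[float, float] = (0.3, 0.8),
    t0: float = 0.0,
) -> GazeRecord:
    """Fixational gaze with embedded (micro)saccades and a slow pupil drift.

    Gaze is low-pass-filtered Gaussian drift (SD ``jitter_sd`` degrees,
    ``drift_cutoff_hz`` bandwidth) plus instantaneous step displacements
    at planted saccade times: homogeneous-Poisson background saccades at
    ``background_rate`` Hz and, under ``saccade_precedes_switch``
    coupling, a saccade ``delta`` s before a fraction ``p`` of switch
    events.  Planted onsets keep a 0.025 s minimum spacing.  The pupil
    is a slow smooth drift.  Onset times are relative to ``t0`` on the
    trial clock (stimulus onset = 0), like the event table.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = jitter_sd * _lowpass_noise((n_trials, n), drift_cutoff_hz, fs, rng) \
        if jitter_sd > 0 else np.zeros((n_trials, n))
    y = jitter_sd * _lowpass_noise((n_trials, n), drift_cutoff_hz, fs, rng) \
        if jitter_sd > 0 else np.zeros((n_trials, n))
    pupil = 1000.0 + 50.0 * _lowpass_noise((n_trials, n), 0.5, fs, rng)

    switch_times = {
        t: g.loc[g["label"] == "switch", "onset"].to_numpy()
        for t, g in events.groupby("trial")
    } if len(events) else {}

    planted: list[np.ndarray] = []
    for i in range(n_trials):
        times = []
        if coupling.mode == "saccade_precedes_switch":
            for st in switch_times.get(i, ()):  # coupled saccades first
                if rng.random() < coupling.p:
                    t_s = st - coupling.delta
                    if t0 <= t_s < t0 + duration:
                        times.append(t_s)
        t = t0
        while True:
            t += rng.exponential(1.0 / background_rate)
            if t >= t0 + duration:
                break
            if all(abs(t - u) >= MIN_EVENT_SPACING for u in times):
                times.append(t)
        times = np.sort(times)
        # enforce minimum spacing (coupled saccades have priority above)
        keep = [0] if times.size else []
        for j in range(1, times.size):
            if times[j] - times[keep[-1]] >= MIN_EVENT_SPACING:
                keep.append(j)
        times = times[keep] if times.size else times
        planted.append(times)
        for t_s in times:
            s = int(round((t_s - t0) * fs))
            amp = rng.uniform(*step_amplitude)
            ang = rng.uniform(0, 2 * np.pi)
            x[i, s:] += amp * np.cos(ang)
            y[i, s:] += amp * np.sin(ang)

    return GazeRecord(x=x, y=y, pupil=pupil, fs=fs, t0=t0,
                      planted_saccade_times=planted)
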