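"""Band-limited fluctuations of attention strength and sensor TFRs.

Attention-strength spectra use a Butterworth/Hilbert filterbank: 4th
order band-pass filters (applied forward-backward, i.e. zero-phase) at
quarter-octave center frequencies from 2^1.5 to 2^6.5 Hz (2.83-90.5 Hz),
each passband spanning the center frequency times 2^(+-0.5).  The
amplitude envelope is the magnitude of the analytic signal; two cycles
of the center frequency are trimmed from each trial edge (set to NaN)
to exclude filter edge artifacts.  Envelopes can be normalized per
frequency by the trial-average pre-stimulus baseline amplitude and
expressed in dB (20 log10 of the amplitude ratio).

Sensor-level time-frequency decomposition uses Morlet wavelets with
bandwidth f/sigma_f = 5.83 and kernels truncated at +-sigma_t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, fftconvolve, hilbert

from .containers import EpochSet


def quarter_octave_centers(lo_exp: float = 1.5, hi_exp: float = 6.5) -> np.ndarray:
    """Center frequencies 2**lo_exp ... 2**hi_exp in quarter-octave steps."""
    return 2.0 ** np.arange(lo_exp, hi_exp + 1e-9, 0.25)


@dataclass(frozen=True)
class FilterbankSpec:
    centers: tuple[float, ...] = tuple(quarter_octave_centers())
    half_octaves: float = 0.5    # passband = center * 2**(+-half_octaves)
    order: int = 4
    trim_cycles: float = 2.0

    def passband(self, f: float) -> tuple[float, float]:
        return f * 2.0 ** -self.half_octaves, f * 2.0 ** self.half_octaves


@dataclass
class AmplitudeTFR:
    """Amplitude envelopes, shape (trials, frequencies, time).

    ``amp`` is nonnegative; trimmed edge samples are NaN.  ``db`` holds
    the baseline-normalized copy after :func:`baseline_normalize_db`.
    """

    amp: np.ndarray
    centers: np.ndarray
    fs: float
    t0: float = 0.0
    db: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.amp.shape[2]) / self.fs


def bandlimited_amplitude(strength: np.ndarray, fs: float,
                          spec: FilterbankSpec = FilterbankSpec(),
                          t0: float = 0.0) -> AmplitudeTFR:
    """Filterbank + Hilbert amplitude envelope of attention strength.

    ``strength`` is (trials, time) vector length.  Centers whose
    passband reaches the Nyquist frequency are dropped with a warning.
    """
    x = np.atleast_2d(np.asarray(strength, dtype=float))
    nyq = fs / 2.0
    centers = []
    for f in spec.centers:
        lo, hi = spec.passband(f)
        if hi >= nyq:
            warnings.warn(
                f"center {f:.2f} Hz dropped: passband reaches Nyquist",
                stacklevel=2,
            )
            continue
        centers.append(f)
    centers = np.asarray(centers)
    n = x.shape[1]
    lowest = centers.min()
    if n / fs <= 4.0 / lowest:
        raise ValueError(
            f"trials shorter than 4 cycles of the lowest center ({lowest:.2f} Hz)"
        )
    amp = np.empty((x.shape[0], len(centers), n))
    for i, f in enumerate(centers):
        lo, hi = spec.passband(f)
        b, a = butter(spec.order, [lo / nyq, hi / nyq], btype="bandpass")
        filt = filtfilt(b, a, x, axis=1)
        env = np.abs(hilbert(filt, axis=1))
        trim = int(np.ceil(spec.trim_cycles / f * fs))
        env[:, :trim] = np.nan
        env[:, n - trim:] = np.nan
        amp[:, i, :] = env
    return AmplitudeTFR(amp=amp, centers=centers, fs=fs, t0=t0)


def baseline_normalize_db(tfr: AmplitudeTFR,
                          baseline_window: tuple[float, float]) -> AmplitudeTFR:
    """Divide each frequency's envelope by its trial-averaged baseline
    amplitude and convert the ratio to dB (20 log10)."""
    t = tfr.times
    mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not mask.any():
        raise ValueError("baseline window outside the trial")
    base = np.nanmean(tfr.amp[:, :, mask], axis=(0, 2))  # per frequency
    if np.any(~np.isfinite(base)):
        raise ValueError(
            "baseline window overlaps trimmed (NaN) samples at some frequency"
        )
    if np.any(base == 0):
        raise ValueError("zero baseline amplitude")
    tfr.db = 20.0 * np.log10(tfr.amp / base[np.newaxis, :, np.newaxis])
    return tfr


def morlet_kernel(f: float, fs: float, bandwidth: float = 5.83) -> np.ndarray:
    """Complex Morlet kernel at ``f`` Hz with f/sigma_f = ``bandwidth``,
    truncated at +-sigma_t, scaled so an in-band unit-amplitude tone
    yields an envelope of ~1."""
    sigma_f = f / bandwidth
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.floor(sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-0.5 * (t / sigma_t) ** 2)
    k = w * np.exp(2j * np.pi * f * t)
    return 2.0 * k / w.sum()


def wavelet_tfr(epochs: EpochSet | np.ndarray, fs: float | None = None,
                centers: np.ndarray | None = None,
                bandwidth: float = 5.83, t0: float = 0.0) -> AmplitudeTFR:
    """Morlet amplitude TFR of sensor (or any) signals.

    ``epochs`` may be an :class:`EpochSet` (the TFR is computed per
    sensor and averaged over sensors is left to the caller: output keeps
    a (trials*sensors, freq, time)-like layout only for 2-D input) or a
    2-D array (signals, time).
    """
    if isinstance(epochs, EpochSet):
        x = epochs.data.reshape(-1, epochs.n_samples)
        fs, t0 = epochs.fs, epochs.t0
    else:
        x = np.atleast_2d(np.asarray(epochs, dtype=float))
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if centers is None:
        centers = quarter_octave_centers(1.0, 6.5)
    centers = np.asarray(centers, dtype=float)
    n = x.shape[1]
    lowest = centers.min()
    min_len = len(morlet_kernel(lowest, fs, bandwidth))
    if n < min_len:
        raise ValueError(
            f"epochs too short for the {lowest:.2f} Hz kernel: need at "
            f"least {min_len} samples ({min_len / fs:.3f} s)"
        )
    amp = np.empty((x.shape[0], len(centers), n))
    for i, f in enumerate(centers):
        k = morlet_kernel(f, fs, bandwidth)
        amp[:, i, :] = np.abs(fftconvolve(x, k[np.newaxis, :], mode="same", axes=1))
    return AmplitudeTFR(amp=amp, centers=centers, fs=fs, t0=t0)


def stratified_condition_compare(
    tfr_amp: np.ndarray,
    meta: pd.DataFrame,
    n_subsamples: int = 100,
    seed: int = 0,
    correct_col: str = "correct",
    strata_cols: tuple[str, ...] = ("contrasts", "framing"),
):
    """Correct-vs-error amplitude difference under condition matching.

    For each subsample, correct trials are drawn (without replacement)
    to match the per-stratum error-trial counts; the correct-trial
    average amplitude is then averaged over subsamples and compared
    against the error-trial average as ``(correct - error)/correct *
    100``.  Strata whose minority (error) side is empty are dropped with
    a warning; strata where errors outnumber correct trials are dropped
    and recorded.

    Returns (percent_change ndarray over the non-trial axes, counts
    DataFrame per stratum).
    """
    rng = np.random.default_rng(seed)
    amp = np.asarray(tfr_amp, dtype=float)
    correct = meta[correct_col].to_numpy(dtype=bool)
    # strata use the unordered contrast combination: sort sequence-valued
    # stratum variables so e.g. the 60 ordered triplet assignments
    # collapse onto the 10 combinations
    cols = {}
    for c in strata_cols:
        v = meta[c]
        if v.map(lambda x: isinstance(x, (tuple, list))).all():
            v = v.map(lambda x: tuple(sorted(x)))
        cols[c] = v.astype(str)
    strata = pd.DataFrame(cols).agg("|".join, axis=1).to_numpy()

    rows = []
    sampled_sets = {}
    err_idx_all = []
    for s in np.unique(strata):
        in_s = strata == s
        cor = np.flatnonzero(in_s & correct)
        err = np.flatnonzero(in_s & ~correct)
        dropped = False
        if len(err) == 0:
            warnings.warn(f"stratum {s!r}: no error trials; dropped", stacklevel=2)
            dropped = True
        elif len(cor) < len(err):
            warnings.warn(
                f"stratum {s!r}: errors outnumber correct trials; dropped",
                stacklevel=2,
            )
            dropped = True
        rows.append(dict(stratum=s, n_correct=len(cor), n_error=len(err),
                         dropped=dropped))
        if not dropped:
            sampled_sets[s] = (cor, len(err))
            err_idx_all.append(err)
    counts = pd.DataFrame(rows)
    if not sampled_sets:
        raise ValueError("no stratum with both correct and error trials")
    err_idx_all = np.concatenate(err_idx_all)

    acc = np.zeros(amp.shape[1:])
    with warnings.catch_warnings():
        # edge-trimmed samples are all-NaN across trials by construction
        warnings.filterwarnings("ignore", "Mean of empty slice")
        for _ in range(n_subsamples):
            picks = np.concatenate([
                rng.choice(cor, size=n_err, replace=False)
                for cor, n_err in sampled_sets.values()
            ])
            acc += np.nanmean(amp[picks], axis=0)
        mean_cor = acc / n_subsamples
        mean_err = np.nanmean(amp[err_idx_all], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = (mean_cor - mean_err) / mean_cor * 100.0
    return pct, counts
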