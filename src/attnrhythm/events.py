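"""Attentional events: detection, stay/switch sequences, and rhythm analysis.

An attentional event marks a sample at which the attentional vector is
both selective (MAS above the participant-wide 90th percentile over all
stimulus-on samples) and strong (vector length above the within-trial
90th percentile).  The event onset is the first sample at which both
binarized series are true after at least one was false, or a change of
the nearest-target locus while both remain true; onsets within 0.025 s
of the previous accepted onset are excluded.

Rhythmicity is assessed from inter-event-interval (IEI) histograms at
per-sample resolution over 0.025-0.5 s, compared against a trial-shuffle
null that reassigns events to random trials while keeping their
within-trial timepoints (preserving the task-locked event-rate profile
exactly).  Significant excess probability is truncated, smoothed twice
with a 0.01 s boxcar, and its local maxima define the histogram modes;
the first-to-second mode latency estimates the attentional rhythm's
cycle length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend
from scipy.signal import find_peaks
from scipy.stats import norm

import statsmodels.api as sm

from .attention import AttentionTrace
from .design import POSITIONS, value_ranks

EVENT_COLUMNS = ["trial", "onset", "locus", "label", "source"]

DEFAULT_IEI_RANGE = (0.025, 0.5)


# ---------------------------------------------------------------------------
# Detection and labeling
# ---------------------------------------------------------------------------

def detect_events(
    trace: AttentionTrace,
    mas_pct: float = 90.0,
    len_pct: float = 90.0,
    refractory: float = 0.025,
    stim_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Detect attentional events by dual percentile thresholding.

    The MAS threshold is the ``mas_pct`` percentile over all stimulus-on
    samples of all trials; the length threshold is the ``len_pct``
    percentile within each trial.  ``stim_window`` restricts analysis to
    the stimulus-on period (defaults to the whole trace).  Onsets are
    reported in seconds relative to the trace's ``t0`` reference
    (i.e. on the trace's own time axis).
    """
    if not (0.0 < mas_pct < 100.0 and 0.0 < len_pct < 100.0):
        raise ValueError("percentiles must be in (0, 100)")
    if trace.n_samples == 0 or trace.n_trials == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    if stim_window is None:
        mask = np.ones(trace.n_samples, dtype=bool)
    else:
        mask = trace.time_mask(*stim_window)
    times = trace.times[mask]
    mas = trace.mas[:, mask]
    length = trace.length[:, mask]

    if not np.isfinite(mas).any():
        return pd.DataFrame(columns=EVENT_COLUMNS)
    mas_thr = np.nanpercentile(mas, mas_pct)
    len_thr = np.nanpercentile(length, len_pct, axis=1, keepdims=True)
    on = (mas >= mas_thr) & (length >= len_thr)
    on &= np.isfinite(mas)

    angles = trace.angle[:, mask]
    refr = refractory - 0.5 / trace.fs  # tolerate sample quantization
    centers = np.asarray(trace.centers, dtype=float)

    # Nearest-target locus per sample (threshold independent).  Exact
    # similarity ties resolve toward the previous sample's locus when it
    # attains the maximum (conservative against spurious switches),
    # otherwise toward the lower channel index.
    with np.errstate(invalid="ignore"):
        sims = np.cos(np.deg2rad(angles[..., np.newaxis] - centers))
    locus_idx = np.nanargmax(np.nan_to_num(sims, nan=-2.0), axis=-1)
    top = np.take_along_axis(sims, locus_idx[..., np.newaxis], axis=-1)[..., 0]
    tied = np.sum(np.isclose(sims, top[..., np.newaxis],
                             rtol=0.0, atol=1e-12), axis=-1) > 1
    if tied.any():
        for i, j in zip(*np.nonzero(tied)):
            if j > 0:
                prev = locus_idx[i, j - 1]
                if np.isclose(sims[i, j, prev], top[i, j], rtol=0.0, atol=1e-12):
                    locus_idx[i, j] = prev

    # Onset candidates: rising edge of the conjunction, or a locus
    # change while it remains true.
    prev_on = np.zeros_like(on)
    prev_on[:, 1:] = on[:, :-1]
    locus_change = np.zeros_like(on)
    locus_change[:, 1:] = locus_idx[:, 1:] != locus_idx[:, :-1]
    cand = on & (~prev_on | locus_change)

    rows = []
    for i in range(trace.n_trials):
        last = -np.inf
        for j in np.flatnonzero(cand[i]):
            t = times[j]
            if t - last >= refr:
                rows.append((i, float(t), float(centers[locus_idx[i, j]])))
                last = t
    if not rows:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    ev = pd.DataFrame(rows, columns=["trial", "onset", "locus"])
    ev["label"] = ""
    ev["source"] = "detected"
    return label_stay_switch(ev)


def label_stay_switch(events: pd.DataFrame) -> pd.DataFrame:
    """Label each event stay/switch relative to the previous event in
    the same trial; the first event per trial is 'first'."""
    ev = events.sort_values(["trial", "onset"]).reset_index(drop=True)
    labels = []
    for _, grp in ev.groupby("trial", sort=False):
        loci = grp["locus"].to_numpy()
        lab = ["first"]
        for a, b in zip(loci[:-1], loci[1:]):
            lab.append("stay" if b == a else "switch")
        labels.extend(lab)
    ev["label"] = labels
    return ev


# ---------------------------------------------------------------------------
# Matrix representation (shared by histograms and shuffle nulls)
# ---------------------------------------------------------------------------

def event_matrix(events: pd.DataFrame, n_trials: int, n_samples: int,
                 fs: float, t0: float = 0.0) -> np.ndarray:
    """Dense (trials, samples) int8 matrix of locus indices, -1 where no
    event.  Onsets are quantized to the nearest sample."""
    mat = np.full((n_trials, n_samples), -1, dtype=np.int8)
    pos = np.asarray(POSITIONS)
    tr = events["trial"].to_numpy(dtype=int)
    samp = np.round((events["onset"].to_numpy() - t0) * fs).astype(int)
    loci = np.argmin(np.abs(events["locus"].to_numpy()[:, None] - pos), axis=1)
    ok = (samp >= 0) & (samp < n_samples)
    mat[tr[ok], samp[ok]] = loci[ok]
    return mat


def _interval_table(mat: np.ndarray):
    """Vectorized interval extraction from a locus matrix.

    Returns (gaps, cur_is_switch, prev_is_switch) where ``gaps`` is in
    samples; ``prev_is_switch`` is NaN-coded as -1 when the earlier
    event of the pair is the first in its trial.
    """
    rows, cols = np.nonzero(mat >= 0)
    if rows.size < 2:
        return (np.empty(0, dtype=int), np.empty(0, dtype=int),
                np.empty(0, dtype=int))
    same = np.diff(rows) == 0
    gaps = np.diff(cols)[same]
    loci = mat[rows, cols]
    cur_sw = (np.diff(loci) != 0)[same].astype(int)
    # Label of the earlier event of each pair; -1 if it is first-in-trial
    # (cross-trial transitions never define a label).
    lab = (np.diff(loci) != 0).astype(int)          # label of event i+1
    prev_lab = np.r_[-1, lab]                       # label of event i
    prev_lab[np.r_[True, ~same]] = -1
    prev_sw = prev_lab[:-1][same]
    return gaps, cur_sw, prev_sw


@dataclass
class IEIHistogram:
    """Inter-event-interval histogram at per-sample resolution."""

    lags: np.ndarray             # seconds, k/fs over the displayed range
    prob: np.ndarray             # per-bin probability (denominator: all intervals)
    n_intervals: int             # total intervals, including those > range
    fs: float
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    modes: list[tuple[float, float]] = field(default_factory=list)
    cycle_length: float | None = None


def _hist_from_gaps(gaps: np.ndarray, n_total: int, fs: float,
                    rng_s: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    kmin = int(np.ceil(rng_s[0] * fs - 1e-9))
    kmax = int(np.floor(rng_s[1] * fs + 1e-9))
    counts = np.bincount(gaps, minlength=kmax + 1)[kmin:kmax + 1]
    lags = np.arange(kmin, kmax + 1) / fs
    prob = counts / max(n_total, 1)
    return lags, prob


def iei_histogram(events: pd.DataFrame, fs: float,
                  iei_range: tuple[float, float] = DEFAULT_IEI_RANGE) -> IEIHistogram:
    """IEI histogram over all events and trials.

    Intervals reaching over trials are excluded; intervals beyond the
    displayed range still count in the normalizing denominator.
    """
    ev = events.sort_values(["trial", "onset"])
    gaps_s = []
    for _, grp in ev.groupby("trial", sort=False):
        if len(grp) >= 2:
            gaps_s.append(np.diff(grp["onset"].to_numpy()))
    if not gaps_s:
        raise ValueError("no within-trial intervals")
    gaps_s = np.concatenate(gaps_s)
    gaps = np.round(gaps_s * fs).astype(int)
    lags, prob = _hist_from_gaps(gaps, len(gaps), fs, iei_range)
    return IEIHistogram(lags=lags, prob=prob, n_intervals=len(gaps), fs=fs)


def trial_shuffle_null(
    events: pd.DataFrame,
    n_trials: int,
    n_samples: int,
    fs: float,
    n_shuffles: int = 1000,
    seed: int = 0,
    t0: float = 0.0,
    iei_range: tuple[float, float] = DEFAULT_IEI_RANGE,
) -> np.ndarray:
    """Null distribution of IEI histograms under trial shuffling.

    At every timepoint the set of trials holding an event is resampled
    without replacement (each column of the trial x time event matrix is
    independently permuted over trials), preserving per-timepoint event
    counts exactly.  Returns the (n_shuffles, bins) array of null
    histogram probabilities.
    """
    if n_trials < 2:
        raise ValueError("trial shuffling needs at least 2 trials")
    rng = np.random.default_rng(seed)
    mat = event_matrix(events, n_trials, n_samples, fs, t0)
    kmin = int(np.ceil(iei_range[0] * fs - 1e-9))
    kmax = int(np.floor(iei_range[1] * fs + 1e-9))
    out = np.empty((n_shuffles, kmax - kmin + 1))
    for s in range(n_shuffles):
        perm = np.argsort(rng.random(mat.shape), axis=0)
        shuf = np.take_along_axis(mat, perm, axis=0)
        gaps, _, _ = _interval_table(shuf)
        _, prob = _hist_from_gaps(gaps, len(gaps), fs, (kmin / fs, kmax / fs))
        out[s] = prob
    return out


def attach_null(hist: IEIHistogram, null_probs: np.ndarray) -> IEIHistogram:
    hist.null_mean = null_probs.mean(axis=0)
    hist.null_sd = null_probs.std(axis=0)
    return hist


# ---------------------------------------------------------------------------
# Smoothing, maxima, modes
# ---------------------------------------------------------------------------

def boxcar_smooth(x: np.ndarray, width: int, passes: int = 1) -> np.ndarray:
    """Boxcar smoothing with edges padded to the first/last value."""
    y = np.asarray(x, dtype=float)
    if width <= 1:
        return y.copy()
    kern = np.ones(width) / width
    for _ in range(passes):
        pad = np.pad(y, (width, width), mode="edge")
        y = np.convolve(pad, kern, mode="same")[width:-width]
    return y


def local_maxima(y: np.ndarray) -> list[int]:
    """Strict local maxima; plateaus contribute their leftmost sample.
    Boundary runs are not maxima."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i > 0 and y[i - 1] < y[i]
        right_ok = j < n - 1 and y[j + 1] < y[i]
        if left_ok and right_ok:
            maxima.append(i)
        i = j + 1
    return maxima


def detect_histogram_modes(
    hist: IEIHistogram,
    alpha: float = 0.01,
    smooth_s: float = 0.01,
    smooth_passes: int = 2,
    min_prominence_frac: float = 0.1,
) -> IEIHistogram:
    """Truncate the null-corrected histogram at significance, smooth it,
    and extract its modes.

    The observed-minus-null difference is z-scored against the shuffle
    null per bin; non-significant bins (one-sided, at ``alpha``) are set
    to zero; the truncated difference is smoothed ``smooth_passes``
    times with a ``smooth_s`` boxcar (edge-padded); local maxima give
    the modes (latency, height); ``cycle_length`` is the latency from
    the first to the second mode, None with fewer than two modes.

    A mode must have topographic prominence of at least
    ``min_prominence_frac`` of the histogram's global maximum: with a
    single session the per-bin significance test admits ~alpha stray
    bins whose shoulders would otherwise masquerade as modes.
    """
    if hist.null_mean is None or hist.null_sd is None:
        raise ValueError("attach a shuffle null before mode detection")
    diff = hist.prob - hist.null_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(hist.null_sd > 0, diff / hist.null_sd,
                     np.where(diff > 0, np.inf, -np.inf))
    zcrit = norm.isf(alpha)
    trunc = np.where(z > zcrit, diff, 0.0)
    width = max(1, int(round(smooth_s * hist.fs)))
    sm_ = boxcar_smooth(trunc, width, passes=smooth_passes)
    if sm_.max() > 0:
        idx, _ = find_peaks(sm_, prominence=min_prominence_frac * sm_.max())
        idx = [i for i in idx if sm_[i] > 0]
    else:
        idx = []
    # Sub-bin refinement: parabolic interpolation around each peak keeps
    # mode latencies from carrying a full bin of quantization jitter.
    modes = []
    for i in idx:
        lat = float(hist.lags[i])
        if 0 < i < len(sm_) - 1:
            denom = sm_[i - 1] - 2 * sm_[i] + sm_[i + 1]
            if denom < 0:
                delta = 0.5 * (sm_[i - 1] - sm_[i + 1]) / denom
                lat += float(np.clip(delta, -0.5, 0.5)) / hist.fs
        modes.append((lat, float(sm_[i])))
    hist.modes = modes
    hist.cycle_length = (hist.modes[1][0] - hist.modes[0][0]
                         if len(hist.modes) >= 2 else None)
    return hist


def events_to_histogram_with_null(
    events: pd.DataFrame, n_trials: int, n_samples: int, fs: float,
    n_shuffles: int = 1000, seed: int = 0, t0: float = 0.0,
    alpha: float = 0.01,
    iei_range: tuple[float, float] = DEFAULT_IEI_RANGE,
) -> IEIHistogram:
    """Convenience chain: histogram + shuffle null + mode detection."""
    hist = iei_histogram(events, fs, iei_range)
    null = trial_shuffle_null(events, n_trials, n_samples, fs,
                              n_shuffles=n_shuffles, seed=seed, t0=t0,
                              iei_range=iei_range)
    attach_null(hist, null)
    return detect_histogram_modes(hist, alpha=alpha)


# ---------------------------------------------------------------------------
# Label-conditioned histograms (first and second order)
# ---------------------------------------------------------------------------

def _labeled_hists(mat: np.ndarray, fs: float, iei_range, second_order: bool):
    gaps, cur_sw, prev_sw = _interval_table(mat)
    out = {}
    if not second_order:
        for name, flag in (("stay", 0), ("switch", 1)):
            sel = cur_sw == flag
            lags, prob = _hist_from_gaps(gaps[sel], int(sel.sum()), fs, iei_range)
            out[name] = (lags, prob, int(sel.sum()))
    else:
        combos = {
            "stay_after_stay": (0, 0), "stay_after_switch": (1, 0),
            "switch_after_stay": (0, 1), "switch_after_switch": (1, 1),
        }
        for name, (pv, cu) in combos.items():
            sel = (prev_sw == pv) & (cur_sw == cu)
            lags, prob = _hist_from_gaps(gaps[sel], int(sel.sum()), fs, iei_range)
            out[name] = (lags, prob, int(sel.sum()))
    return out


def conditioned_iei(
    events: pd.DataFrame,
    n_trials: int,
    n_samples: int,
    fs: float,
    second_order: bool = False,
    n_shuffles: int = 0,
    seed: int = 0,
    t0: float = 0.0,
    iei_range: tuple[float, float] = DEFAULT_IEI_RANGE,
) -> dict[str, IEIHistogram]:
    """Stay/switch-conditioned IEI histograms.

    First order: intervals classified by the label of the terminating
    event (stay / switch).  Second order: by the (previous label,
    current label) pair — switch-after-stay etc.; pairs whose earlier
    event is first-in-trial are excluded.  With ``n_shuffles > 0`` a
    trial-shuffle null (with relabeling after each shuffle) is attached
    per class.
    """
    mat = event_matrix(events, n_trials, n_samples, fs, t0)
    obs = _labeled_hists(mat, fs, iei_range, second_order)
    hists = {
        name: IEIHistogram(lags=lags, prob=prob, n_intervals=n, fs=fs)
        for name, (lags, prob, n) in obs.items()
    }
    if n_shuffles > 0:
        rng = np.random.default_rng(seed)
        acc = {name: [] for name in hists}
        for _ in range(n_shuffles):
            perm = np.argsort(rng.random(mat.shape), axis=0)
            shuf = np.take_along_axis(mat, perm, axis=0)
            sh = _labeled_hists(shuf, fs, iei_range, second_order)
            for name, (_, prob, _n) in sh.items():
                acc[name].append(prob)
        for name in hists:
            attach_null(hists[name], np.asarray(acc[name]))
    return hists


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

SWEEP_PERCENTILES = (50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 97.5, 99)


def modulation_intensity(hist: IEIHistogram,
                         smooth_s: float = 0.025) -> float:
    """SD of the log-transformed, detrended, twice-smoothed interval
    probabilities between the first and second local maxima; NaN if the
    histogram shows fewer than two maxima.

    Zero-probability bins are floored to the smallest observed positive
    probability before the log transform.
    """
    prob = hist.prob
    pos = prob[prob > 0]
    if pos.size < 5:
        return np.nan
    logp = np.log10(np.clip(prob, pos.min(), None))
    det = _linear_detrend(logp)
    width = max(1, int(round(smooth_s * hist.fs)))
    sm_ = boxcar_smooth(det, width, passes=2)
    rng_ = sm_.max() - sm_.min()
    if rng_ <= 0:
        return np.nan
    idx, _ = find_peaks(sm_, prominence=0.1 * rng_)
    if len(idx) < 2:
        return np.nan
    i, j = idx[0], idx[1]
    return float(np.std(sm_[i:j + 1]))


def threshold_sweep(
    trace: AttentionTrace,
    mas_pcts=SWEEP_PERCENTILES,
    len_pcts=SWEEP_PERCENTILES,
    stim_window: tuple[float, float] | None = None,
    iei_range: tuple[float, float] = DEFAULT_IEI_RANGE,
) -> pd.DataFrame:
    """Modulation intensity over the grid of threshold combinations.

    Returns a DataFrame indexed by MAS percentile with length
    percentiles as columns (12 x 12 = 144 cells with the defaults);
    cells without two histogram maxima (or without events) are NaN.
    """
    grid = np.full((len(mas_pcts), len(len_pcts)), np.nan)
    for a, mp in enumerate(mas_pcts):
        for b, lp in enumerate(len_pcts):
            ev = detect_events(trace, mas_pct=mp, len_pct=lp,
                               stim_window=stim_window)
            try:
                hist = iei_histogram(ev, trace.fs, iei_range)
            except ValueError:
                continue
            grid[a, b] = modulation_intensity(hist)
    return pd.DataFrame(grid, index=list(mas_pcts), columns=list(len_pcts))


# ---------------------------------------------------------------------------
# Choice regression
# ---------------------------------------------------------------------------

def event_counts_by_value(events: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-trial event counts split by label (stay/switch) and the
    decision-value rank (H/M/L) of the event's locus."""
    cols = [f"{lab}_{rk}" for lab in ("stay", "switch") for rk in ("H", "M", "L")]
    counts = pd.DataFrame(0, index=np.arange(len(meta)), columns=cols)
    for _, ev in events.iterrows():
        if ev["label"] not in ("stay", "switch"):
            continue
        tr = int(ev["trial"])
        ranks = value_ranks(meta.loc[tr, "contrasts"], meta.loc[tr, "framing"])
        counts.loc[tr, f"{ev['label']}_{ranks[ev['locus']]}"] += 1
    return counts


def choice_regression(counts: pd.DataFrame, choices) -> dict[str, pd.DataFrame]:
    """Binomial-logit fit per outcome (chosen vs not) of choice on the
    six stay/switch x H/M/L event-count predictors.

    Constant predictors are dropped with a warning.  On (quasi-)complete
    separation or non-convergence a ridge-penalized fit is used and
    flagged (standard errors NaN).

    Returns a dict outcome -> DataFrame(coef, se, penalized).
    """
    choices = np.asarray(choices)
    if len(counts) < 30:
        raise ValueError("need at least 30 trials")
    X = counts.copy().astype(float)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    for c in X.columns:
        if c not in keep:
            warnings.warn(f"constant predictor {c!r} dropped", stacklevel=2)
    X = X[keep]
    Xc = sm.add_constant(X, has_constant="add")

    out = {}
    for outcome in ("H", "M", "L"):
        y = (choices == outcome).astype(float)
        penalized = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params, bse = res.params, res.bse
            if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > 50):
                raise RuntimeError("separation suspected")
        except Exception:
            penalized = True
            glm = sm.GLM(y, Xc, family=sm.families.Binomial())
            res = glm.fit_regularized(alpha=1e-3, L1_wt=0.0)
            params = res.params
            bse = pd.Series(np.nan, index=Xc.columns)
        out[outcome] = pd.DataFrame(
            {"coef": params, "se": bse, "penalized": penalized}
        )
    return out
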