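"""(Micro)saccade detection, rates, and coupling to attentional events.

Gaze velocity is the per-sample Euclidean norm of the first difference
of (x, y) times the sampling rate, smoothed with a causal Gaussian
kernel.  A saccade is recorded when velocity exceeds 6 times the
within-trial median, with a 0.025 s minimum delay between onsets.  The
gaze displacement from 0.01 s before to 0.03 s after onset classifies
the event as a microsaccade (< 1 degree) or larger saccade.

Coupling analyses align saccade rates to attentional-event onsets per
stay/switch label against a trial-shuffle null, count the proportion of
events preceded by a saccade, and compute saccade-triggered attention
strength normalized to the 0.4 s before saccade onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attention import AttentionTrace
from .containers import GazeRecord
from .events import IEIHistogram, _hist_from_gaps, event_matrix

SACCADE_COLUMNS = ["trial", "onset", "displacement", "is_micro"]


def _causal_gaussian_kernel(width_s: float, fs: float) -> np.ndarray:
    """One-sided (causal) Gaussian kernel of total width ``width_s``.

    The causal form keeps the first suprathreshold sample at the gaze
    step itself rather than ahead of it (a symmetric kernel leaks the
    velocity spike backwards in time).
    """
    sigma = width_s / 2.0
    n = max(1, int(round(3 * sigma * fs)))
    t = np.arange(n + 1) / fs
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def detect_microsaccades(
    gaze: GazeRecord,
    kernel_s: float = 0.02,
    k: float = 6.0,
    refractory: float = 0.025,
    displacement_window: tuple[float, float] = (-0.01, 0.03),
    velocity_norm: str = "euclidean",
) -> pd.DataFrame:
    """Detect (micro)saccades by the multiple-of-median velocity rule.

    ``velocity_norm`` selects the Euclidean norm over (dx, dy) (default)
    or the per-axis maximum ('max') behind a flag, since the printed
    rule is ambiguous.  Onsets are the first suprathreshold sample of
    each excursion, with the refractory rule applied; trials whose gaze
    is entirely missing are skipped with a warning.
    """
    if gaze.fs < 100:
        raise ValueError("gaze must be sampled at >= 100 Hz")
    if velocity_norm not in ("euclidean", "max"):
        raise ValueError(f"unknown velocity_norm {velocity_norm!r}")
    fs = gaze.fs
    kern = _causal_gaussian_kernel(kernel_s, fs)
    refr = refractory - 0.5 / fs
    d_pre = int(round(-displacement_window[0] * fs))
    d_post = int(round(displacement_window[1] * fs))

    rows = []
    for i in range(gaze.n_trials):
        x, y = gaze.x[i], gaze.y[i]
        if np.all(~np.isfinite(x)) or np.all(~np.isfinite(y)):
            warnings.warn(f"trial {i}: gaze entirely missing; skipped",
                          stacklevel=2)
            continue
        dx = np.diff(x) * fs
        dy = np.diff(y) * fs
        if velocity_norm == "euclidean":
            v = np.hypot(dx, dy)
        else:
            v = np.maximum(np.abs(dx), np.abs(dy))
        # causal smoothing: full kernel support lies in the past
        v_s = np.convolve(v, kern, mode="full")[:v.size]
        med = np.nanmedian(v_s)
        thr = k * med
        above = v_s > thr
        if not above.any():
            continue
        onsets = np.flatnonzero(above & ~np.r_[False, above[:-1]])
        last = -np.inf
        for j in onsets:
            # velocity sample j spans gaze samples j -> j+1; onset = j + 1
            s = j + 1
            t = gaze.t0 + s / fs
            if t - last < refr:
                continue
            last = t
            a = max(0, s - d_pre)
            b = min(gaze.n_samples - 1, s + d_post)
            disp = float(np.hypot(x[b] - x[a], y[b] - y[a]))
            rows.append((i, float(t), disp, disp < 1.0))
    return pd.DataFrame(rows, columns=SACCADE_COLUMNS)


def saccade_rate(saccades: pd.DataFrame, n_trials: int, n_samples: int,
                 fs: float, t0: float = 0.0) -> np.ndarray:
    """Per-sample saccade probability across trials times the sampling
    rate (Hz)."""
    counts = np.zeros(n_samples)
    if len(saccades):
        samp = np.round((saccades["onset"].to_numpy() - t0) * fs).astype(int)
        ok = (samp >= 0) & (samp < n_samples)
        np.add.at(counts, samp[ok], 1.0)
    return counts / max(n_trials, 1) * fs


def _saccade_bool(saccades: pd.DataFrame, n_trials: int, n_samples: int,
                  fs: float, t0: float) -> np.ndarray:
    b = np.zeros((n_trials, n_samples), dtype=bool)
    if len(saccades):
        tr = saccades["trial"].to_numpy(dtype=int)
        samp = np.round((saccades["onset"].to_numpy() - t0) * fs).astype(int)
        ok = (samp >= 0) & (samp < n_samples)
        b[tr[ok], samp[ok]] = True
    return b


def _triggered_rate(sacc_bool: np.ndarray, ev_mat: np.ndarray, label_flag: int,
                    labels: np.ndarray, n_lags: int, fs: float) -> np.ndarray:
    """Mean saccade indicator around event onsets of one label x fs."""
    rows, cols = np.nonzero(ev_mat >= 0)
    sel = labels == label_flag
    rows, cols = rows[sel], cols[sel]
    n_samples = sacc_bool.shape[1]
    acc = np.zeros(2 * n_lags + 1)
    cnt = np.zeros(2 * n_lags + 1)
    for r, c in zip(rows, cols):
        a = max(0, c - n_lags)
        b = min(n_samples, c + n_lags + 1)
        sl = slice(a - (c - n_lags), (2 * n_lags + 1) - ((c + n_lags + 1) - b))
        acc[sl] += sacc_bool[r, a:b]
        cnt[sl] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / cnt, np.nan) * fs


def _event_labels_from_matrix(mat: np.ndarray) -> np.ndarray:
    """Per-event label flags (row-major event order): 0 stay, 1 switch,
    -1 first-in-trial."""
    rows, cols = np.nonzero(mat >= 0)
    loci = mat[rows, cols]
    lab = np.full(rows.size, -1, dtype=int)
    if rows.size > 1:
        same = np.diff(rows) == 0
        lab[1:][same] = (np.diff(loci) != 0)[same].astype(int)
    return lab


def event_saccade_coupling(
    events: pd.DataFrame,
    saccades: pd.DataFrame,
    n_trials: int,
    n_samples: int,
    fs: float,
    trace: AttentionTrace | None = None,
    window: tuple[float, float] = (-0.3, 0.3),
    pre_window: tuple[float, float] = (-0.3, 0.0),
    strength_window: tuple[float, float] = (-0.4, 0.8),
    n_shuffles: int = 200,
    seed: int = 0,
    t0: float = 0.0,
) -> dict:
    """Couple (micro)saccades to attentional events.

    Returns a dict with, per stay/switch label: the event-triggered
    saccade rate minus its trial-shuffle null ('rate_change', with
    'lags'), and the proportion of events preceded by >= 1 saccade in
    ``pre_window`` ('preceded').  With ``trace`` given, also the
    saccade-triggered attention strength z-scored on the 0.4 s before
    saccade onset ('strength', with 'strength_lags').
    """
    if len(events) == 0 or len(saccades) == 0:
        raise ValueError("both event and saccade tables must be nonempty")
    rng = np.random.default_rng(seed)
    ev_mat = event_matrix(events, n_trials, n_samples, fs, t0)
    sb = _saccade_bool(saccades, n_trials, n_samples, fs, t0)
    n_lags = int(round(max(abs(window[0]), abs(window[1])) * fs))
    lags = np.arange(-n_lags, n_lags + 1) / fs

    labels = _event_labels_from_matrix(ev_mat)
    observed = {name: _triggered_rate(sb, ev_mat, flag, labels, n_lags, fs)
                for name, flag in (("stay", 0), ("switch", 1))}

    null_acc = {name: np.zeros_like(observed[name]) for name in observed}
    for _ in range(n_shuffles):
        perm = np.argsort(rng.random(ev_mat.shape), axis=0)
        shuf = np.take_along_axis(ev_mat, perm, axis=0)
        sl = _event_labels_from_matrix(shuf)
        for name, flag in (("stay", 0), ("switch", 1)):
            null_acc[name] += _triggered_rate(sb, shuf, flag, sl, n_lags, fs)

    out: dict = {"lags": lags, "rate_change": {}, "preceded": {}}
    for name in observed:
        out["rate_change"][name] = observed[name] - null_acc[name] / n_shuffles

    # proportion of events preceded by a saccade within pre_window
    pa = int(round(-pre_window[0] * fs))
    pb = int(round(-pre_window[1] * fs))
    rows, cols = np.nonzero(ev_mat >= 0)
    for name, flag in (("stay", 0), ("switch", 1)):
        sel = labels == flag
        hits, total = 0, 0
        for r, c in zip(rows[sel], cols[sel]):
            a, b = max(0, c - pa), max(0, c - pb)
            if b > a:
                total += 1
                hits += bool(sb[r, a:b].any())
        out["preceded"][name] = hits / total if total else np.nan

    if trace is not None:
        na = int(round(-strength_window[0] * fs))
        nb = int(round(strength_window[1] * fs))
        segs = []
        for _, sc in saccades.iterrows():
            s = int(round((sc["onset"] - trace.t0) * trace.fs))
            if s - na < 0 or s + nb >= trace.n_samples:
                continue
            seg = trace.length[int(sc["trial"]), s - na:s + nb + 1]
            mu, sd = seg[:na].mean(), seg[:na].std()
            if sd > 0:
                segs.append((seg - mu) / sd)
        if segs:
            out["strength"] = np.mean(segs, axis=0)
            out["strength_lags"] = np.arange(-na, nb + 1) / fs
    return out


def saccade_split_iei(
    events: pd.DataFrame,
    saccades: pd.DataFrame,
    fs: float,
    iei_range: tuple[float, float] = (0.025, 0.5),
) -> dict[str, IEIHistogram]:
    """IEI histograms split by whether any saccade onset falls strictly
    inside the interval."""
    ev = events.sort_values(["trial", "onset"])
    sacc_by_trial = {
        t: g["onset"].to_numpy() for t, g in saccades.groupby("trial")
    } if len(saccades) else {}
    gaps = {"with_saccade": [], "without_saccade": []}
    for t, grp in ev.groupby("trial", sort=False):
        on = grp["onset"].to_numpy()
        sc = sacc_by_trial.get(t, np.empty(0))
        for a, b in zip(on[:-1], on[1:]):
            key = ("with_saccade"
                   if np.any((sc > a) & (sc < b)) else "without_saccade")
            gaps[key].append(b - a)
    out = {}
    for key, g in gaps.items():
        gi = np.round(np.asarray(g) * fs).astype(int)
        lags, prob = _hist_from_gaps(gi, len(gi), fs, iei_range)
        out[key] = IEIHistogram(lags=lags, prob=prob, n_intervals=len(gi), fs=fs)
    return out


def normalize_pupil(pupil: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map the pooled 5th/95th pupil percentiles to 0/1 (values outside
    may exceed [0, 1]) and return the adjacent-frame derivative."""
    p = np.asarray(pupil, dtype=float)
    lo, hi = np.nanpercentile(p, [5, 95])
    if hi == lo:
        raise ValueError("degenerate pupil percentiles (constant trace)")
    norm = (p - lo) / (hi - lo)
    deriv = np.diff(norm, axis=-1)
    return norm, deriv
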