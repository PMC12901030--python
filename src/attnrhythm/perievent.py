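"""Event-triggered analysis of attention strength.

Strength traces are averaged in a window around each attentional event
(default -0.2 to +0.2 s), separately for stay and switch events.  The
averaged trace is z-scored against its own pre-event (-0.2 to -0.03 s)
and post-event (0.03 to 0.2 s) samples, excluding the +-0.03 s
peri-event zone whose by-construction extreme values would skew the
normalization.  Dominant peri-event fluctuation frequencies are the
inverse of the peak-to-peak latency of the two detrended/smoothed-trace
peaks closest to the event, separately pre and post.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

from .attention import AttentionTrace
from .events import boxcar_smooth, local_maxima


@dataclass
class PeriEventAverage:
    """Per-label event-triggered averages of attention strength."""

    times: np.ndarray                       # seconds relative to event onset
    avg: dict[str, np.ndarray]              # label -> z-scored average trace
    raw: dict[str, np.ndarray]              # label -> raw average trace
    n_events: dict[str, int]
    fs: float
    exclusion: float = 0.03


def _gather_segments(trace: AttentionTrace, events: pd.DataFrame,
                     window: tuple[float, float]) -> dict[str, np.ndarray]:
    """Stack per-event strength segments per label; events whose window
    leaves the trial are dropped."""
    n_pre = int(round(-window[0] * trace.fs))
    n_post = int(round(window[1] * trace.fs))
    segs: dict[str, list[np.ndarray]] = {}
    t0, fs = trace.t0, trace.fs
    for _, ev in events.iterrows():
        lab = ev["label"]
        if lab not in ("stay", "switch"):
            continue
        s = int(round((ev["onset"] - t0) * fs))
        if s - n_pre < 0 or s + n_post >= trace.n_samples:
            continue
        segs.setdefault(lab, []).append(
            trace.length[int(ev["trial"]), s - n_pre:s + n_post + 1]
        )
    return {lab: np.asarray(v) for lab, v in segs.items()}


def event_triggered_average(
    trace: AttentionTrace,
    events: pd.DataFrame,
    window: tuple[float, float] = (-0.2, 0.2),
    exclusion: float = 0.03,
) -> PeriEventAverage:
    """Average strength around event onsets per label and z-score the
    averages over the pooled pre+post samples outside the exclusion zone."""
    segs = _gather_segments(trace, events, window)
    if not segs:
        raise ValueError("no events with complete peri-event windows")
    n_pre = int(round(-window[0] * trace.fs))
    n_post = int(round(window[1] * trace.fs))
    times = np.arange(-n_pre, n_post + 1) / trace.fs
    # normalization uses samples strictly outside the +-exclusion zone
    norm_mask = np.abs(times) > exclusion + 0.25 / trace.fs
    avg, raw, n_events = {}, {}, {}
    for lab, seg in segs.items():
        m = seg.mean(axis=0)
        raw[lab] = m
        mu = m[norm_mask].mean()
        sd = m[norm_mask].std()
        if sd == 0.0:
            raise ValueError("zero variance in peri-event normalization window")
        avg[lab] = (m - mu) / sd
        n_events[lab] = seg.shape[0]
    return PeriEventAverage(times=times, avg=avg, raw=raw, n_events=n_events,
                            fs=trace.fs, exclusion=exclusion)


def _interval_peaks(y: np.ndarray, times: np.ndarray,
                    smooth_s: float, fs: float) -> np.ndarray:
    """Peak latencies of the detrended, boxcar-smoothed segment."""
    if y.size < 3:
        return np.array([])
    det = _linear_detrend(y)
    sm = boxcar_smooth(det, max(1, int(round(smooth_s * fs))), passes=1)
    idx = local_maxima(sm)
    return times[idx] if idx else np.array([])


def perievent_frequency(
    pea: PeriEventAverage,
    smooth_s: float = 0.025,
    pre: tuple[float, float] | None = None,
    post: tuple[float, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Dominant pre- and post-event fluctuation frequency per label.

    Each interval (default: pre = window start to -exclusion, post =
    +exclusion to window end) is detrended and smoothed with a
    ``smooth_s`` boxcar; the frequency is the inverse of the latency
    between the two peaks closest to the event, NaN with fewer than two
    peaks.
    """
    t = pea.times
    if pre is None:
        pre = (t[0], -pea.exclusion)
    if post is None:
        post = (pea.exclusion, t[-1])
    out: dict[str, dict[str, float]] = {}
    for lab, z in pea.avg.items():
        freqs = {}
        for name, (a, b) in (("f_pre", pre), ("f_post", post)):
            m = (t >= a) & (t <= b)
            peaks = _interval_peaks(z[m], t[m], smooth_s, pea.fs)
            if len(peaks) < 2:
                freqs[name] = np.nan
                continue
            # the two peaks closest to the event (lag 0)
            order = np.argsort(np.abs(peaks))[:2]
            p = np.sort(peaks[order])
            freqs[name] = 1.0 / (p[1] - p[0])
        out[lab] = freqs
    return out


def pre_post_ratio(
    trace: AttentionTrace,
    events: pd.DataFrame,
    pre: tuple[float, float] = (-0.15, -0.05),
    post: tuple[float, float] = (0.05, 0.15),
) -> dict[str, float]:
    """Switch/stay ratio of mean peri-event strength, pre and post.

    Returns {'pre': r_pre, 'post': r_post, 'delta': r_post - r_pre}.
    """
    window = (min(pre[0], post[0]), max(pre[1], post[1]))
    segs = _gather_segments(trace, events, window)
    if "stay" not in segs or "switch" not in segs:
        raise ValueError("both stay and switch events are required")
    n_pre = int(round(-window[0] * trace.fs))
    times = (np.arange(segs["stay"].shape[1]) - n_pre) / trace.fs
    out = {}
    for name, (a, b) in (("pre", pre), ("post", post)):
        m = (times >= a) & (times <= b)
        mean_switch = segs["switch"][:, m].mean()
        mean_stay = segs["stay"][:, m].mean()
        out[name] = float(mean_switch / mean_stay)
    out["delta"] = out["post"] - out["pre"]
    return out
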