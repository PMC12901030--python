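"""Attentional-vector readout: strength, locus angle, and MAS.

The momentary focus of covert attention is summarized as the planar
vector sum of the three decoded channel responses along their target
directions (0°, 120°, 240°; 0° up, counter-clockwise positive).  The
vector length indexes overall attention strength; the angle indexes the
attended locus; the maximum angular similarity (MAS) is the largest
cosine between the vector angle and the three targets and indexes how
selectively a single alternative is attended.  When all three responses
are nonnegative and not all zero, MAS is bounded below by 0.5, attained
exactly when the vector points midway between two targets.

Channel responses are used signed, without rectification: a negative
response pulls the vector away from that target.  A ``rectify`` flag is
provided for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import ChannelResponse, DEFAULT_CENTERS

#: Vector lengths below this are treated as direction-undefined.
LENGTH_EPS = 1e-12


@dataclass
class AttentionTrace:
    """Per-trial time series of the attentional-vector readout."""

    length: np.ndarray   # (trials, time), attention strength
    angle: np.ndarray    # (trials, time), degrees in [0, 360); NaN if undefined
    mas: np.ndarray      # (trials, time), max angular similarity; NaN if undefined
    fs: float
    t0: float = 0.0
    centers: tuple[float, ...] = DEFAULT_CENTERS

    @property
    def n_trials(self) -> int:
        return self.length.shape[0]

    @property
    def n_samples(self) -> int:
        return self.length.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def time_mask(self, t_start: float, t_stop: float) -> np.ndarray:
        t = self.times
        return (t >= t_start) & (t < t_stop)


def _unit_vectors(centers) -> tuple[np.ndarray, np.ndarray]:
    # 0° points up, angles grow counter-clockwise: u(theta) = (-sin, cos).
    th = np.deg2rad(np.asarray(centers, dtype=float))
    return -np.sin(th), np.cos(th)


def attentional_vector(resp: ChannelResponse | np.ndarray,
                       fs: float | None = None, t0: float = 0.0,
                       rectify: bool = False) -> AttentionTrace:
    """Vector sum of the three channel responses along their target
    directions.

    Accepts a ``ChannelResponse`` or a bare array with the channel axis
    second-to-last, ordered (top, left, right) = (0°, 120°, 240°).
    """
    if isinstance(resp, ChannelResponse):
        C, fs, t0, centers = resp.C, resp.fs, resp.t0, resp.centers
    else:
        C = np.asarray(resp, dtype=float)
        centers = DEFAULT_CENTERS
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if C.ndim == 2:
        C = C[np.newaxis]
    if C.shape[1] != 3:
        raise ValueError(f"expected 3 channels, got {C.shape[1]}")
    if rectify:
        C = np.clip(C, 0.0, None)
    ux, uy = _unit_vectors(centers)
    vx = np.einsum("k,tkn->tn", ux, C)
    vy = np.einsum("k,tkn->tn", uy, C)
    length = np.hypot(vx, vy)
    angle = np.degrees(np.arctan2(-vx, vy)) % 360.0
    angle = np.where(length < LENGTH_EPS, np.nan, angle)
    trace = AttentionTrace(length=length, angle=angle,
                           mas=np.empty_like(length), fs=fs, t0=t0,
                           centers=tuple(centers))
    trace.mas = max_angular_similarity(angle, centers)
    return trace


def max_angular_similarity(angle, centers=DEFAULT_CENTERS) -> np.ndarray:
    """Largest cosine between ``angle`` (degrees) and the target angles.

    NaN angles (undefined vector direction) propagate to NaN.
    """
    a = np.asarray(angle, dtype=float)
    diffs = np.deg2rad(a[..., np.newaxis] - np.asarray(centers))
    return np.max(np.cos(diffs), axis=-1)


def nearest_target(angle, centers=DEFAULT_CENTERS,
                   prefer=None) -> np.ndarray:
    """Target angle with the highest angular similarity to ``angle``.

    ``prefer`` optionally names a target used to break exact similarity
    ties (toward the previously attended locus).
    """
    a = np.atleast_1d(np.asarray(angle, dtype=float))
    cen = np.asarray(centers, dtype=float)
    sims = np.cos(np.deg2rad(a[..., np.newaxis] - cen))
    best = np.argmax(sims, axis=-1)
    if prefer is not None:
        k_pref = int(np.argmin(np.abs(cen - prefer)))
        tied = np.isclose(sims[..., k_pref], np.max(sims, axis=-1),
                          rtol=0.0, atol=1e-12)
        best = np.where(tied, k_pref, best)
    return cen[best]


def zscore_strength(trace: AttentionTrace,
                    window: tuple[float, float]) -> AttentionTrace:
    """Z-score the vector length using the pooled mean/SD of all trials'
    samples inside ``window`` (the stimulus-on period); the normalization
    is applied to the whole trace."""
    mask = trace.time_mask(*window)
    if not mask.any():
        raise ValueError("normalization window is empty")
    vals = trace.length[:, mask]
    mu = float(np.nanmean(vals))
    sd = float(np.nanstd(vals))
    if sd == 0.0:
        raise ValueError("zero variance in normalization window")
    return AttentionTrace(length=(trace.length - mu) / sd,
                          angle=trace.angle, mas=trace.mas,
                          fs=trace.fs, t0=trace.t0, centers=trace.centers)
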