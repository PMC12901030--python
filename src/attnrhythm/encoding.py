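"""Inverted encoding model for angular stimulus position.

The forward model assumes sensor data are a weighted sum of three
angular information channels plus noise, ``X = W C + N``.  Each channel
has a half-wave-rectified sinusoidal tuning curve

    f(theta, mu) = |cos^alpha(0.5 (theta - mu) pi / 180)|,  alpha = 5,

with preferred angles mu = 0°, 120°, 240° (top, left, right).  Weights
are estimated per channel by marginal least squares on localizer epochs
averaged over a training window,

    w_k = X c_k^T (c_k c_k^T)^(-1),

then pre-whitened with the channel's shrinkage-regularized residual
covariance E_k,

    g_k = E_k^(-1) w_k (w_k^T E_k^(-1) w_k)^(-1),

which makes g_k^T w_k = 1 an exact algebraic identity.  New epochs are
decoded as C = G^T X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet

DEFAULT_CENTERS = (0.0, 120.0, 240.0)


@dataclass(frozen=True)
class TuningBasis:
    """Half-wave-rectified sinusoidal tuning basis."""

    centers: tuple[float, ...] = DEFAULT_CENTERS
    alpha: int = 5

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")


def wrap_angle(delta: np.ndarray | float) -> np.ndarray:
    """Wrap angular differences (degrees) to (-180, 180]."""
    d = np.asarray(delta, dtype=float)
    return -((-d + 180.0) % 360.0 - 180.0)


def tuning_curve(theta, mu, alpha: int = 5):
    """Channel response in [0, 1] to angle ``theta`` for a channel
    preferring ``mu`` (both degrees)."""
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    d = wrap_angle(np.asarray(theta, dtype=float) - mu)
    return np.abs(np.cos(0.5 * d * np.pi / 180.0) ** alpha)


def build_design_matrix(angles, basis: TuningBasis = TuningBasis()) -> np.ndarray:
    """Design matrix C, shape (channels, observations); entry (k, n) is
    the tuning response of channel k to stimulus angle n."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one observation")
    return np.stack([tuning_curve(angles, mu, basis.alpha)
                     for mu in basis.centers])


@dataclass
class EncodingModel:
    """Fitted inverted encoding model."""

    basis: TuningBasis
    W: np.ndarray                     # (sensors, channels)
    G: np.ndarray                     # (sensors, channels), pre-whitened
    shrinkage: np.ndarray             # per-channel shrinkage intensity
    training_window: tuple[float, float] | None = None
    channel_names: list[str] | None = None

    @property
    def n_sensors(self) -> int:
        return self.W.shape[0]

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]


@dataclass
class ChannelResponse:
    """Decoded channel responses, shape (trials, channels, time)."""

    C: np.ndarray
    fs: float
    t0: float
    centers: tuple[float, ...] = DEFAULT_CENTERS

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.C.shape[2]) / self.fs


def fit_weights(X: np.ndarray, C: np.ndarray, joint: bool = False):
    """Estimate the weight matrix from training observations.

    Parameters
    ----------
    X : (sensors, observations) sensor data averaged over the training
        window, one column per observation.
    C : (channels, observations) design matrix.
    joint : if False (default), apply the marginal per-channel estimator
        ``w_k = X c_k^T (c_k c_k^T)^{-1}``; if True, solve the joint
        multichannel least squares ``W = X C^T (C C^T)^{-1}``.

    Returns
    -------
    W : (sensors, channels)
    residuals : list of per-channel residual matrices ``X - w_k c_k``
        (sensors, observations), as required for noise-covariance
        estimation.
    """
    X = np.asarray(X, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if X.shape[1] != C.shape[1]:
        raise ValueError("X and C must share the observation axis")
    if X.shape[1] < C.shape[0]:
        raise ValueError(
            "fewer observations than channels; provide more (or more "
            "varied) training trials"
        )
    if joint:
        gram = C @ C.T
        if np.linalg.cond(gram) > 1e12:
            raise np.linalg.LinAlgError(
                "singular design Gram matrix; provide more varied observations"
            )
        W = X @ C.T @ np.linalg.inv(gram)
    else:
        W = np.empty((X.shape[0], C.shape[0]))
        for k in range(C.shape[0]):
            c = C[k]
            norm = float(c @ c)
            if norm == 0.0:
                raise np.linalg.LinAlgError(
                    f"channel {k} has an all-zero tuning curve over the "
                    "training observations; provide more varied observations"
                )
            W[:, k] = X @ c / norm
    residuals = [X - np.outer(W[:, k], C[k]) for k in range(C.shape[0])]
    return W, residuals


def shrink_covariance_to_diagonal(samples: np.ndarray):
    """Sample covariance shrunk toward its diagonal with the analytic
    squared-loss-optimal intensity.

    ``samples`` is (observations, sensors).  The intensity follows the
    standard analytic estimator for a diagonal target: the summed
    sampling variance of the off-diagonal entries divided by their
    summed squared magnitude, clipped to [0, 1].

    Returns (covariance, gamma).
    """
    x = np.asarray(samples, dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean(axis=0)
    if np.any(xc.std(axis=0) == 0):
        raise np.linalg.LinAlgError("zero-variance sensor; covariance degenerate")
    s = xc.T @ xc / (n - 1)
    # Var-hat of each covariance entry without forming the n*p*p tensor.
    w_bar = s * (n - 1) / n
    w2_sum = (xc ** 2).T @ (xc ** 2)
    var_s = n / (n - 1) ** 3 * (w2_sum - n * w_bar ** 2)
    off = ~np.eye(p, dtype=bool)
    denom = float(np.sum(s[off] ** 2))
    gamma = 1.0 if denom == 0.0 else float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))
    sigma = (1.0 - gamma) * s + gamma * np.diag(np.diag(s))
    return sigma, gamma


def prewhiten_weights(W: np.ndarray, residuals: list[np.ndarray]):
    """Pre-whiten each channel's weights with its shrinkage-regularized
    residual covariance.

    Returns (G, shrinkage) with ``G[:, k]^T W[:, k] = 1`` exactly (up to
    floating point) for every channel.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] < 2:
        raise ValueError("need at least 2 sensors")
    if len(residuals) != W.shape[1]:
        raise ValueError("one residual matrix per channel required")
    G = np.empty_like(W)
    gammas = np.empty(W.shape[1])
    for k in range(W.shape[1]):
        E, gammas[k] = shrink_covariance_to_diagonal(residuals[k].T)
        g = np.linalg.solve(E, W[:, k])
        G[:, k] = g / float(W[:, k] @ g)
    return G, gammas


def invert_model(model: EncodingModel | np.ndarray,
                 epochs: EpochSet | np.ndarray,
                 fs: float | None = None, t0: float | None = None) -> ChannelResponse:
    """Decode channel responses from new epochs: C = G^T X per sample."""
    G = model.G if isinstance(model, EncodingModel) else np.asarray(model)
    centers = (model.basis.centers if isinstance(model, EncodingModel)
               else DEFAULT_CENTERS)
    if isinstance(epochs, EpochSet):
        data, fs, t0 = epochs.data, epochs.fs, epochs.t0
    else:
        data = np.asarray(epochs, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
        t0 = 0.0 if t0 is None else t0
    if data.shape[1] != G.shape[0]:
        raise ValueError(
            f"sensor mismatch: model was trained on {G.shape[0]} sensors, "
            f"epochs carry {data.shape[1]}"
        )
    C = np.einsum("sk,tsn->tkn", G, data)
    return ChannelResponse(C=C, fs=fs, t0=t0, centers=tuple(centers))


def train_encoding_model(
    localizer: EpochSet,
    training_window: tuple[float, float],
    basis: TuningBasis = TuningBasis(),
    exclude: np.ndarray | None = None,
    joint: bool = False,
) -> EncodingModel:
    """Fit W and G from localizer epochs averaged over a training window.

    ``exclude`` is an optional boolean per-trial mask of trials to drop
    (e.g. trials with saccades in the first 200 ms, or flicker trials).
    """
    keep = np.ones(localizer.n_trials, dtype=bool)
    if "flicker" in localizer.meta:
        keep &= ~localizer.meta["flicker"].to_numpy(dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    mask = localizer.time_mask(*training_window)
    if not mask.any():
        raise ValueError("training window lies outside the epoch")
    X = localizer.data[keep][:, :, mask].mean(axis=2).T  # sensors x obs
    C = build_design_matrix(
        localizer.meta.loc[keep, "position"].to_numpy(), basis
    )
    W, res = fit_weights(X, C, joint=joint)
    G, gammas = prewhiten_weights(W, res)
    return EncodingModel(basis=basis, W=W, G=G, shrinkage=gammas,
                         training_window=tuple(training_window))


def saccade_exclusion_mask(localizer: EpochSet, saccades,
                           window: tuple[float, float] = (0.0, 0.2)) -> np.ndarray:
    """Trials with (micro)saccadic activity inside ``window`` (seconds
    from stimulus onset), to be excluded from model training."""
    mask = np.zeros(localizer.n_trials, dtype=bool)
    if len(saccades) == 0:
        return mask
    sel = (saccades["onset"] >= window[0]) & (saccades["onset"] < window[1])
    bad = saccades.loc[sel, "trial"].unique()
    mask[np.asarray(bad, dtype=int)] = True
    return mask


def decoding_score(C_dec: np.ndarray, true_channel: np.ndarray) -> float:
    """Mean decoded response of the true channel minus the mean of the
    off-channels, averaged over trials (higher = better decoding)."""
    n_tr, n_ch = C_dec.shape
    idx = np.arange(n_tr)
    true_resp = C_dec[idx, true_channel]
    off_resp = (C_dec.sum(axis=1) - true_resp) / (n_ch - 1)
    return float(np.mean(true_resp - off_resp))


def select_training_epoch(
    localizer: EpochSet,
    candidate_windows: list[tuple[float, float]],
    basis: TuningBasis = TuningBasis(),
    exclude: np.ndarray | None = None,
) -> tuple[tuple[float, float], np.ndarray]:
    """Choose the training window by leave-one-block-out cross-validation.

    For each candidate window the model is trained on all blocks but
    one and scored on the held-out block (true-channel response minus
    mean off-channel response, with held-out epochs averaged over the
    same window).  Ties break toward the earlier window.

    Returns (best_window, per-window mean scores).
    """
    blocks = localizer.meta["block"].to_numpy()
    uniq = np.unique(blocks)
    if len(uniq) < 2:
        raise ValueError("leave-one-block-out needs at least 2 blocks")
    windows = sorted(candidate_windows, key=lambda w: w[0])
    centers = np.asarray(basis.centers)

    keep = np.ones(localizer.n_trials, dtype=bool)
    if "flicker" in localizer.meta:
        keep &= ~localizer.meta["flicker"].to_numpy(dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)

    scores = np.zeros(len(windows))
    for wi, win in enumerate(windows):
        mask = localizer.time_mask(*win)
        if not mask.any():
            raise ValueError(f"candidate window {win} lies outside the epoch")
        fold_scores = []
        for b in uniq:
            train = keep & (blocks != b)
            test = keep & (blocks == b)
            if not test.any():
                continue
            Xtr = localizer.data[train][:, :, mask].mean(axis=2).T
            Ctr = build_design_matrix(
                localizer.meta.loc[train, "position"].to_numpy(), basis
            )
            W, res = fit_weights(Xtr, Ctr)
            G, _ = prewhiten_weights(W, res)
            Xte = localizer.data[test][:, :, mask].mean(axis=2)  # obs x sensors
            C_dec = Xte @ G
            true_ch = np.argmin(np.abs(
                localizer.meta.loc[test, "position"].to_numpy()[:, None]
                - centers[None, :]
            ), axis=1)
            fold_scores.append(decoding_score(C_dec, true_ch))
        scores[wi] = float(np.mean(fold_scores))
    best = int(np.argmax(scores))  # first max -> earlier window on ties
    return windows[best], scores
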