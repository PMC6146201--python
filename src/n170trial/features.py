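"""Single-trial N170 feature construction.

Ranks the 12 occipitotemporal candidate electrodes by the strength of their
positive-vs-negative single-trial amplitude difference, keeps the top five,
extracts per-trial features from the analysis window (either the raw
filtered samples, concatenated across the selected channels, or one
window-mean amplitude per channel) and min-max scales each feature to
[0, 1].  Positive-emotion trials are encoded +1 and negative-emotion trials
-1; neutral trials are excluded from classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CANDIDATE_CHANNELS, EpochSet
from .erp import window_mean_amplitudes
from .stats import DegenerateDataError, paired_t, two_sample_t

__all__ = [
    "FeatureMatrix",
    "ChannelRanking",
    "select_channels",
    "extract_features",
    "minmax_scale",
    "apply_scaling",
    "DEFAULT_WINDOW",
]

#: default N170 quantification window, ms (component peaks near 170 ms)
DEFAULT_WINDOW = (150.0, 200.0)


@dataclass
class ChannelRanking:
    """Candidate channels ordered by ascending contrast p-value."""

    channels: list[str]        # all candidates, ranked
    statistics: np.ndarray
    p_values: np.ndarray
    k: int                     # number marked selected

    @property
    def selected(self) -> list[str]:
        return self.channels[: self.k]


@dataclass
class FeatureMatrix:
    """Trials x features matrix with class labels and provenance."""

    X: np.ndarray
    y: np.ndarray              # +1 positive-emotion, -1 negative-emotion
    trial_ids: np.ndarray
    channels: list[str]
    window: tuple[float, float]
    mode: str
    scale_min: np.ndarray | None = None
    scale_max: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows and y length differ")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def rows(self, index) -> "FeatureMatrix":
        index = np.asarray(index)
        return FeatureMatrix(
            X=self.X[index], y=self.y[index], trial_ids=self.trial_ids[index],
            channels=list(self.channels), window=self.window, mode=self.mode,
            scale_min=self.scale_min, scale_max=self.scale_max,
            meta=dict(self.meta),
        )


def select_channels(epochs: EpochSet,
                    candidates=CANDIDATE_CHANNELS,
                    window: tuple[float, float] = DEFAULT_WINDOW,
                    k: int = 5,
                    method: str = "welch") -> ChannelRanking:
    """Rank candidate channels by the positive-vs-negative contrast of
    per-trial window-mean amplitudes; the first ``k`` are selected.

    Ties in p are broken by the candidate (montage) order.  ``method`` is
    ``welch`` (two-sample over unpaired trials, default) or ``paired``
    (trial-order pairing).
    """
    candidates = list(candidates)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidates")
    amps = window_mean_amplitudes(epochs, candidates, window)
    pos = amps[epochs.labels == "positive"]
    neg = amps[epochs.labels == "negative"]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 positive and >= 2 negative trials")
    stats_, ps = [], []
    for j in range(len(candidates)):
        try:
            if method == "welch":
                res = two_sample_t(pos[:, j], neg[:, j], equal_var=False)
            elif method == "paired":
                m = min(len(pos), len(neg))
                res = paired_t(pos[:m, j], neg[:m, j])
            else:
                raise ValueError(f"unknown method {method!r}")
            stats_.append(res.statistic)
            ps.append(res.p_value)
        except DegenerateDataError:
            stats_.append(0.0)
            ps.append(1.0)
    ps = np.array(ps)
    # stable sort on p keeps candidate order for ties
    order = np.argsort(ps, kind="stable")
    return ChannelRanking(
        channels=[candidates[i] for i in order],
        statistics=np.array(stats_)[order],
        p_values=ps[order],
        k=k,
    )


def extract_features(epochs: EpochSet, channels,
                     window: tuple[float, float] = DEFAULT_WINDOW,
                     mode: str = "samples") -> FeatureMatrix:
    """Build the single-trial feature matrix from positive/negative trials.

    ``samples`` mode concatenates the window samples (endpoints inclusive)
    of each selected channel — k channels x w samples features per trial;
    ``window_mean`` mode keeps one mean amplitude per channel.  Neutral
    trials are dropped; y is +1 for positive- and -1 for negative-emotion
    trials.
    """
    channels = list(channels)
    keep = np.isin(epochs.labels, ("positive", "negative"))
    if not keep.any():
        raise ValueError("no positive/negative trials in epoch set")
    sub = epochs.select_trials(np.flatnonzero(keep))
    y = np.where(sub.labels == "positive", 1, -1)
    if mode == "samples":
        cidx = sub.channel_index(channels)
        mask = sub.time_mask(window, closed="both")
        if not mask.any():
            raise ValueError(f"window {window} contains no samples")
        X = sub.data[:, cidx][:, :, mask].reshape(sub.n_trials, -1)
    elif mode == "window_mean":
        X = window_mean_amplitudes(sub, channels, window)
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    return FeatureMatrix(
        X=X, y=y, trial_ids=sub.trial_ids.copy(),
        channels=channels, window=tuple(window), mode=mode,
    )


def minmax_scale(features: FeatureMatrix,
                 fit_rows: np.ndarray | None = None) -> FeatureMatrix:
    """Scale each feature to [0, 1] using bounds from ``fit_rows``.

    x' = (x - min_j) / (max_j - min_j) with the per-feature bounds computed
    on ``fit_rows`` (all rows by default) and stored in provenance; rows
    outside the fitting subset may legitimately fall outside [0, 1].
    Features constant on the fitting rows map to 0 (with a warning).
    """
    if fit_rows is None:
        fit_rows = np.arange(features.n_trials)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be non-empty")
    lo = features.X[fit_rows].min(axis=0)
    hi = features.X[fit_rows].max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        import warnings
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) on fitting rows mapped to 0"
        )
    safe_span = np.where(constant, 1.0, span)
    X = (features.X - lo) / safe_span
    X[:, constant] = 0.0
    out = FeatureMatrix(
        X=X, y=features.y.copy(), trial_ids=features.trial_ids.copy(),
        channels=list(features.channels), window=features.window,
        mode=features.mode, scale_min=lo, scale_max=hi,
        meta=dict(features.meta),
    )
    return out


def apply_scaling(features: FeatureMatrix, lo: np.ndarray,
                  hi: np.ndarray) -> FeatureMatrix:
    """Apply previously fitted min/max bounds to a feature matrix."""
    span = hi - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    X = (features.X - lo) / safe_span
    X[:, constant] = 0.0
    return FeatureMatrix(
        X=X, y=features.y.copy(), trial_ids=features.trial_ids.copy(),
        channels=list(features.channels), window=features.window,
        mode=features.mode, scale_min=lo, scale_max=hi, meta=dict(features.meta),
    )
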