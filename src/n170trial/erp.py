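"""Condition-average ERP waveforms, difference waves, and per-channel
significance maps for the positive-vs-negative N170 contrast."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CANDIDATE_CHANNELS, EpochSet
from .stats import DegenerateDataError, paired_t, two_sample_t

__all__ = [
    "ERPWaveforms",
    "ScalpPMap",
    "condition_average",
    "difference_wave",
    "channel_pvalue_map",
    "window_mean_amplitudes",
]


@dataclass
class ERPWaveforms:
    """Per-channel mean waveform for one condition (or a difference)."""

    data: np.ndarray           # channels x samples, microvolts
    channels: list[str]
    times: np.ndarray          # ms
    condition: str
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV-ready frame: channel, time_ms, condition, amplitude_uv."""
        rows = []
        for i, ch in enumerate(self.channels):
            rows.append(pd.DataFrame({
                "channel": ch,
                "time_ms": self.times,
                "condition": self.condition,
                "amplitude_uv": self.data[i],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class ScalpPMap:
    """Per-channel p-values for the positive-vs-negative contrast in a
    stated window."""

    channels: list[str]
    p_values: np.ndarray
    statistics: np.ndarray
    window: tuple[float, float]
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.channels,
            "t": self.statistics,
            "p": self.p_values,
            "window_lo_ms": self.window[0],
            "window_hi_ms": self.window[1],
            "method": self.method,
        })


def condition_average(epochs: EpochSet, label: str) -> ERPWaveforms:
    """Arithmetic mean across all trials carrying ``label``."""
    mask = epochs.labels == label
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no trials with label {label!r}")
    return ERPWaveforms(
        data=epochs.data[mask].mean(axis=0),
        channels=list(epochs.channels),
        times=epochs.times.copy(),
        condition=label,
        n_trials=n,
    )


def difference_wave(a: ERPWaveforms, b: ERPWaveforms) -> ERPWaveforms:
    """Elementwise a - b (e.g. positive minus negative)."""
    if a.channels != b.channels or not np.array_equal(a.times, b.times):
        raise ValueError("waveforms have mismatching channels or time axes")
    return ERPWaveforms(
        data=a.data - b.data,
        channels=list(a.channels),
        times=a.times.copy(),
        condition=f"{a.condition}-{b.condition}",
        n_trials=min(a.n_trials, b.n_trials),
    )


def window_mean_amplitudes(epochs: EpochSet, channels, window) -> np.ndarray:
    """Per-trial mean amplitude in the window (endpoints inclusive) for the
    given channels; shape (n_trials, n_channels_selected)."""
    cidx = epochs.channel_index(channels)
    mask = epochs.time_mask(window, closed="both")
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return epochs.data[:, cidx][:, :, mask].mean(axis=2)


def channel_pvalue_map(epochs: EpochSet,
                       channels=CANDIDATE_CHANNELS,
                       window: tuple[float, float] = (150.0, 200.0),
                       method: str = "welch") -> ScalpPMap:
    """Per-channel positive-vs-negative contrast of single-trial window-mean
    amplitudes.

    ``method='welch'`` contrasts the two (unpaired) trial sets with a Welch
    two-sample t test — the trial-level variant.  ``method='paired'`` pairs
    positive and negative trials in trial order (truncating to the shorter
    set), for group-style maps where a pairing is imposed by design.
    """
    channels = list(channels)
    amps = window_mean_amplitudes(epochs, channels, window)
    pos = amps[epochs.labels == "positive"]
    neg = amps[epochs.labels == "negative"]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 positive and >= 2 negative trials")
    stats_, ps = [], []
    for j in range(len(channels)):
        try:
            if method == "welch":
                res = two_sample_t(pos[:, j], neg[:, j], equal_var=False)
            elif method == "paired":
                m = min(len(pos), len(neg))
                res = paired_t(pos[:m, j], neg[:m, j])
            else:
                raise ValueError(f"unknown method {method!r}")
        except DegenerateDataError:
            # identical trial sets: no evidence against the null
            res = None
        stats_.append(0.0 if res is None else res.statistic)
        ps.append(1.0 if res is None else res.p_value)
    return ScalpPMap(
        channels=channels,
        p_values=np.array(ps),
        statistics=np.array(stats_),
        window=tuple(window),
        method=method,
    )
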