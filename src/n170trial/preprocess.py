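"""Epoch preprocessing: re-referencing, baseline correction, artifact
rejection and zero-phase band-pass filtering.

Each operation is pure (returns a new :class:`~n170trial.containers.EpochSet`)
and order-independent at the API level; :func:`run_preprocessing` applies a
configured sequence, defaulting to
re-reference -> baseline -> rejection -> filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import EpochSet, EpochSetError

__all__ = [
    "PreprocessConfig",
    "rereference",
    "baseline_correct",
    "bandpass_filter",
    "reject_artifacts",
    "run_preprocessing",
    "EmptyEpochSetError",
]


class EmptyEpochSetError(ValueError):
    """All trials were rejected."""


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    reference_mode
        ``none`` (leave as recorded), ``average`` (common average
        reference) or ``linear_matrix`` (arbitrary channels x channels
        operator, e.g. an externally computed infinity-reference matrix).
    baseline_window
        Pre-stimulus window in ms, half-open (default [-200, 0)).
    band
        Band-pass edges in Hz (default 0.5-45).
    artifact_threshold
        Absolute rejection threshold in microvolts (default 100); a trial
        is rejected when any channel sample strictly exceeds it.
    order
        Sequence of operation names applied by :func:`run_preprocessing`.
    """

    reference_mode: str = "none"
    reference_matrix: np.ndarray | None = None
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    band: tuple[float, float] = (0.5, 45.0)
    artifact_threshold: float = 100.0
    filter_order: int = 4
    order: tuple[str, ...] = (
        "rereference", "baseline_correct", "reject_artifacts", "bandpass_filter",
    )

    def validate(self, sampling_rate: float) -> None:
        lo, hi = self.band
        if not 0 <= lo < hi:
            raise ValueError("band must satisfy 0 <= low < high")
        if hi >= sampling_rate / 2.0:
            raise ValueError("band high edge must be below Nyquist")
        if self.artifact_threshold <= 0:
            raise ValueError("artifact_threshold must be positive")
        if self.reference_mode not in ("none", "average", "linear_matrix"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")


def rereference(epochs: EpochSet, config: PreprocessConfig) -> EpochSet:
    """Apply the configured linear re-reference operator M to every sample
    vector: ``average`` uses M = I - 11^T/n (common average reference);
    ``linear_matrix`` uses the supplied matrix; ``none`` is the identity."""
    if config.reference_mode == "none":
        return epochs
    n = epochs.n_channels
    if config.reference_mode == "average":
        matrix = np.eye(n) - np.ones((n, n)) / n
    else:
        matrix = np.asarray(config.reference_matrix, dtype=float)
        if matrix.shape != (n, n):
            raise EpochSetError(
                f"reference matrix shape {matrix.shape} != ({n}, {n})"
            )
    out = epochs.copy()
    out.data = np.einsum("ij,tjs->tis", matrix, epochs.data)
    return out


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract, per trial and channel, the mean over the half-open
    pre-stimulus window [window[0], window[1])."""
    mask = epochs.time_mask(window, closed="left")
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    out = epochs.copy()
    out.data = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def bandpass_filter(epochs: EpochSet,
                    band: tuple[float, float] = (0.5, 45.0),
                    order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass.

    A Butterworth filter of the given order is applied forward-backward
    (``sosfiltfilt``) so component peak latencies are not shifted; odd
    reflection padding of (almost) one epoch length handles the short-epoch
    edges.
    """
    lo, hi = band
    nyq = epochs.sampling_rate / 2.0
    if not 0 <= lo < hi:
        raise ValueError("band must satisfy 0 <= low < high")
    if hi >= nyq:
        raise ValueError(f"band high edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=epochs.sampling_rate,
                        output="sos")
    out = epochs.copy()
    out.data = signal.sosfiltfilt(
        sos, epochs.data, axis=2, padtype="odd", padlen=epochs.n_samples - 1,
    )
    return out


def reject_artifacts(epochs: EpochSet,
                     threshold: float = 100.0) -> tuple[EpochSet, int]:
    """Remove every trial in which any channel sample strictly exceeds
    ``threshold`` microvolts in absolute value (the +/- threshold read as
    the allowed range).  Returns the cleaned set and the rejected count."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = np.abs(epochs.data).max(axis=(1, 2)) > threshold
    if bad.all():
        raise EmptyEpochSetError("all trials exceeded the rejection threshold")
    kept = epochs.select_trials(~bad)
    return kept, int(bad.sum())


def run_preprocessing(epochs: EpochSet,
                      config: PreprocessConfig | None = None) -> tuple[EpochSet, dict]:
    """Apply the configured operation sequence; returns the processed
    epochs and a report dict (rejected trial count, applied order)."""
    config = config or PreprocessConfig()
    config.validate(epochs.sampling_rate)
    report: dict = {"order": list(config.order), "n_rejected": 0}
    for op in config.order:
        if op == "rereference":
            epochs = rereference(epochs, config)
        elif op == "baseline_correct":
            epochs = baseline_correct(epochs, config.baseline_window)
        elif op == "reject_artifacts":
            epochs, n_rej = reject_artifacts(epochs, config.artifact_threshold)
            report["n_rejected"] = n_rej
        elif op == "bandpass_filter":
            epochs = bandpass_filter(epochs, config.band, config.filter_order)
        else:
            raise ValueError(f"unknown preprocessing operation {op!r}")
    return epochs, report
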