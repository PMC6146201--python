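"""In-memory containers shared across the pipeline.

The central object is :class:`EpochSet`: a per-subject tensor of
stimulus-locked EEG epochs (trials x channels x samples, in microvolts)
together with per-trial emotion labels, an ordered channel list, the epoch
time axis in milliseconds relative to stimulus onset, and the sampling rate.
Trial identity is carried explicitly (``trial_ids``) so that label/data
alignment survives artifact rejection and reordering and can be asserted in
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

EMOTIONS = ("positive", "neutral", "negative")

#: the 12 occipitotemporal candidate electrodes screened for the N170
CANDIDATE_CHANNELS = (
    "P3", "P4", "P5", "P6", "P7", "P8",
    "PO3", "PO4", "PO5", "PO6", "PO7", "PO8",
)


class EpochSetError(ValueError):
    """Raised for malformed or inconsistent epoch containers."""


@dataclass
class EpochSet:
    """Stimulus-locked EEG epochs for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltages in microvolts.
    labels : ndarray of str, shape (n_trials,)
        Emotion label per trial (``positive`` / ``neutral`` / ``negative``).
    channels : sequence of str
        Ordered, unique channel names.
    times : ndarray, shape (n_samples,)
        Sample times in ms relative to stimulus onset (onset at 0 ms),
        strictly increasing with step ``1000 / sampling_rate``.
    sampling_rate : float
        Sampling rate in Hz.
    subject_id : str
        Subject identifier.
    trial_ids : ndarray of int, optional
        Stable per-trial identifiers; defaults to ``0..n_trials-1``.
    artifact_flags : ndarray of bool, optional
        Provenance flags set by the simulator for trials that received an
        injected artifact transient.
    """

    data: np.ndarray
    labels: np.ndarray
    channels: list[str]
    times: np.ndarray
    sampling_rate: float
    subject_id: str = "S0"
    trial_ids: np.ndarray | None = None
    artifact_flags: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.channels = list(self.channels)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise EpochSetError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if self.labels.shape != (n_trials,):
            raise EpochSetError(
                f"labels length {self.labels.shape} != trial count {n_trials}"
            )
        if len(self.channels) != n_channels:
            raise EpochSetError(
                f"{len(self.channels)} channel names for {n_channels} data channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise EpochSetError("channel names must be unique")
        if self.times.shape != (n_samples,):
            raise EpochSetError("times length must match sample count")
        if self.sampling_rate <= 0:
            raise EpochSetError("sampling_rate must be positive")
        step = 1000.0 / self.sampling_rate
        if n_samples > 1 and not np.allclose(np.diff(self.times), step):
            raise EpochSetError(
                "times must increase with step 1000/sampling_rate"
            )
        if self.trial_ids is None:
            self.trial_ids = np.arange(n_trials)
        else:
            self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
            if self.trial_ids.shape != (n_trials,):
                raise EpochSetError("trial_ids length must match trial count")
        if self.artifact_flags is not None:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
            if self.artifact_flags.shape != (n_trials,):
                raise EpochSetError("artifact_flags length must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        """Indices of ``names`` in the montage; unknown names raise."""
        lookup = {c: i for i, c in enumerate(self.channels)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise EpochSetError(f"channel {exc.args[0]!r} not in montage") from exc

    def time_mask(self, window: tuple[float, float], closed: str = "both") -> np.ndarray:
        """Boolean sample mask for a time window in ms.

        ``closed='both'`` includes both endpoints at sample resolution
        (the convention for analysis windows); ``closed='left'`` is the
        half-open convention used for the pre-stimulus baseline.
        """
        lo, hi = window
        if closed == "both":
            mask = (self.times >= lo) & (self.times <= hi)
        elif closed == "left":
            mask = (self.times >= lo) & (self.times < hi)
        else:  # pragma: no cover - internal misuse
            raise ValueError("closed must be 'both' or 'left'")
        return mask

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        """New EpochSet restricted to the given trial indices (labels,
        ids and flags stay aligned)."""
        index = np.asarray(index)
        return replace(
            self,
            data=self.data[index],
            labels=self.labels[index],
            trial_ids=self.trial_ids[index],
            artifact_flags=(
                None if self.artifact_flags is None else self.artifact_flags[index]
            ),
        )

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            labels=self.labels.copy(),
            trial_ids=self.trial_ids.copy(),
            artifact_flags=(
                None if self.artifact_flags is None else self.artifact_flags.copy()
            ),
            meta=dict(self.meta),
        )
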