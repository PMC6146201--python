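"""Synthetic per-subject EEG sessions with an emotion-modulated N170.

The generator emulates the statistical structure a single-trial N170
emotion-classification analysis assumes: each trial is a spatially weighted,
negative-going Gaussian-envelope component peaking near 170 ms after
stimulus onset, whose amplitude depends on the trial's emotion (negative
emotion trials are more negative than positive ones, neutral in between),
superimposed on 1/f^alpha background noise, with occasional high-amplitude
artifact transients and per-trial latency/amplitude variability.  A matching
behavioral table (reaction times and accuracies with a negative-emotion
speed advantage) is generated alongside.

Amplitude variability is multiplicative lognormal (unit mean) and latency
jitter is Gaussian, so the grand average stays an attenuated copy of the
single-trial template; with noise, jitter and artifacts switched off every
trial of a condition is an exact copy of its template.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CANDIDATE_CHANNELS, EMOTIONS, EpochSet

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "make_session",
    "make_behavior",
    "inject_artifacts",
    "DEFAULT_MONTAGE",
    "DEFAULT_SPATIAL_WEIGHTS",
    "DEFAULT_RT_MEANS",
    "DEFAULT_RT_SD",
    "DEFAULT_ACCURACY",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


#: default montage: 6 midline/occipital context channels plus the 12
#: occipitotemporal candidates screened for the N170
DEFAULT_MONTAGE = (
    "Fz", "Cz", "Pz", "Oz", "O1", "O2",
) + CANDIDATE_CHANNELS

#: unitless per-channel gain of the N170 source, maximal at the lateral
#: occipitotemporal sites where the component is classically largest
DEFAULT_SPATIAL_WEIGHTS = {
    "Fz": 0.0, "Cz": 0.1, "Pz": 0.2, "Oz": 0.3, "O1": 0.35, "O2": 0.35,
    "P3": 0.45, "P4": 0.45, "P5": 0.7, "P6": 0.7, "P7": 1.0, "P8": 1.0,
    "PO3": 0.5, "PO4": 0.5, "PO5": 0.75, "PO6": 0.75, "PO7": 0.95, "PO8": 0.95,
}

# behavioral defaults: negative-emotion speed/accuracy advantage
DEFAULT_RT_MEANS = {"positive": 650.0, "neutral": 655.0, "negative": 600.0}
DEFAULT_RT_SD = 80.0
DEFAULT_ACCURACY = {"positive": 0.92, "neutral": 0.93, "negative": 0.96}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic session generator.

    The defaults reproduce the study design this pipeline analyses:
    20 subjects x 480 trials (160 per emotion), epochs of -200..+280 ms at
    250 Hz, an N170 of nominal amplitude ``base_amplitude`` (microvolts,
    negative) whose positive-vs-negative amplitude difference is
    ``emotion_effect`` microvolts, concentrated on occipitotemporal
    channels by ``spatial_weights``.
    """

    n_subjects: int = 20
    n_trials_per_emotion: int = 160
    emotions: tuple[str, ...] = EMOTIONS
    sampling_rate: float = 250.0
    epoch_window: tuple[float, float] = (-200.0, 280.0)
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    n170_peak_latency: float = 170.0      # ms
    latency_jitter_sd: float = 10.0       # ms, per-trial Gaussian jitter
    n170_width: float = 25.0              # ms, Gaussian envelope SD
    base_amplitude: float = -6.0          # microvolts, positive-emotion trials
    emotion_effect: float = 5.0           # microvolts, positive minus negative
    amplitude_jitter_sd: float = 0.2      # lognormal sigma, unit-mean multiplier
    spatial_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_SPATIAL_WEIGHTS)
    )
    noise_sd: float = 2.0                 # microvolts, per channel
    noise_exponent: float = 1.0           # 1/f^alpha spectral exponent
    artifact_rate: float = 0.0            # probability per trial
    artifact_magnitude: float = 150.0     # microvolts
    rng_seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not self.montage:
            raise ConfigurationError("montage must not be empty")
        lo, hi = self.epoch_window
        if hi - lo <= 0:
            raise ConfigurationError("epoch window must have positive length")
        if self.n_trials_per_emotion <= 0:
            raise ConfigurationError("n_trials_per_emotion must be positive")
        if self.noise_sd < 0 or self.latency_jitter_sd < 0:
            raise ConfigurationError("noise_sd and jitter SD must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigurationError("artifact_rate must be in [0, 1]")
        if self.n170_width <= 0:
            raise ConfigurationError("n170_width must be positive")
        missing = [c for c in self.montage if c not in self.spatial_weights]
        if missing:
            raise ConfigurationError(
                f"spatial_weights missing entries for channels {missing}"
            )

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in ms; half-open [lo, hi) so the sample count is
        window-length / sample-period and onset (0 ms) starts the
        post-stimulus segment."""
        lo, hi = self.epoch_window
        step = 1000.0 / self.sampling_rate
        n = int(round((hi - lo) / step))
        return lo + step * np.arange(n)

    def amplitude_for(self, emotion: str) -> float:
        """Nominal component amplitude (microvolts) for one emotion."""
        if emotion == "positive":
            return self.base_amplitude
        if emotion == "negative":
            return self.base_amplitude - self.emotion_effect
        return self.base_amplitude - self.emotion_effect / 2.0


def _session_rng(config: SimulationConfig, subject_index: int, stream: int) -> np.random.Generator:
    # seed sequence keyed on (seed, subject, stream): reproducible per subject
    return np.random.default_rng([int(config.rng_seed), int(subject_index), stream])


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, alpha: float, sd: float) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha power spectrum and time-domain SD ``sd``.

    White Gaussian noise is shaped in the frequency domain (amplitude
    ~ f^(-alpha/2), DC removed) and rescaled so the expected per-epoch
    standard deviation equals ``sd``.
    """
    if sd == 0:
        return np.zeros(shape + (n_samples,))
    white = rng.standard_normal(shape + (n_samples,))
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-alpha / 2.0)
    shaped = np.fft.irfft(spectrum * gain, n=n_samples, axis=-1)
    # normalize on the realized ensemble so the batch SD equals sd exactly
    return shaped * (sd / shaped.std())


def make_session(config: SimulationConfig, subject_index: int = 0) -> EpochSet:
    """Generate one subject's epoch set.

    Each trial t with emotion e and channel c is

        w_c * A_t * exp(-(time - (peak + jitter_t))^2 / (2 width^2)) + noise

    with A_t = amplitude_for(e) * lognormal(sigma=amplitude_jitter_sd),
    1/f^alpha noise of SD ``noise_sd`` per channel, and (if
    ``artifact_rate`` > 0) injected high-amplitude transients.  Trial order
    is pseudo-randomized.  Bit-identical output for identical
    (config, subject_index).
    """
    config.validate()
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigurationError(
            f"subject_index {subject_index} outside 0..{config.n_subjects - 1}"
        )
    rng = _session_rng(config, subject_index, stream=0)
    times = config.times
    n_samples = times.size
    channels = list(config.montage)
    weights = np.array([config.spatial_weights[c] for c in channels])

    labels = np.repeat(list(config.emotions), config.n_trials_per_emotion)
    rng.shuffle(labels)
    n_trials = labels.size

    amp_nominal = np.array([config.amplitude_for(e) for e in labels])
    amp_mult = np.exp(
        rng.normal(-config.amplitude_jitter_sd ** 2 / 2.0,
                   config.amplitude_jitter_sd, n_trials)
    ) if config.amplitude_jitter_sd > 0 else np.ones(n_trials)
    jitter = rng.normal(0.0, config.latency_jitter_sd, n_trials) \
        if config.latency_jitter_sd > 0 else np.zeros(n_trials)

    # trials x samples component waveform, then spatial projection
    envelope = np.exp(
        -((times[None, :] - (config.n170_peak_latency + jitter[:, None])) ** 2)
        / (2.0 * config.n170_width ** 2)
    )
    component = (amp_nominal * amp_mult)[:, None] * envelope
    data = weights[None, :, None] * component[:, None, :]
    data = data + _pink_noise(
        rng, (n_trials, len(channels)), n_samples,
        config.noise_exponent, config.noise_sd,
    )

    epochs = EpochSet(
        data=data,
        labels=labels,
        channels=channels,
        times=times,
        sampling_rate=config.sampling_rate,
        subject_id=f"S{subject_index + 1}",
        artifact_flags=np.zeros(n_trials, dtype=bool),
        meta={"rng_seed": config.rng_seed, "subject_index": subject_index},
    )
    if config.artifact_rate > 0:
        epochs = inject_artifacts(
            epochs, config.artifact_rate, config.artifact_magnitude,
            seed=rng.integers(2 ** 31),
        )
    return epochs


def inject_artifacts(epochs: EpochSet, rate: float, magnitude: float,
                     seed: int = 0) -> EpochSet:
    """Add a high-amplitude transient to a random ``rate`` fraction of trials.

    Each affected trial gains a brief Gaussian bump (SD 3 samples) on one
    random channel, guaranteeing at least one sample with absolute value
    >= ``magnitude``; affected trials are flagged in ``artifact_flags`` so
    downstream rejection can be cross-checked against the injection.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("artifact rate must be in [0, 1]")
    if magnitude <= 0:
        raise ConfigurationError("artifact magnitude must be positive")
    if rate == 0:
        return epochs
    rng = np.random.default_rng(seed)
    out = epochs.copy()
    hit = rng.random(out.n_trials) < rate
    idx = np.arange(out.n_samples)
    for t in np.flatnonzero(hit):
        ch = rng.integers(out.n_channels)
        center = rng.integers(out.n_samples)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        bump = sign * 1.2 * magnitude * np.exp(-((idx - center) ** 2) / (2 * 3.0 ** 2))
        out.data[t, ch] += bump
        while np.max(np.abs(out.data[t, ch])) < magnitude:  # cancellation guard
            out.data[t, ch] += bump
    flags = out.artifact_flags if out.artifact_flags is not None \
        else np.zeros(out.n_trials, dtype=bool)
    out.artifact_flags = flags | hit
    return out


def make_behavior(config: SimulationConfig,
                  rt_means: dict[str, float] | None = None,
                  rt_sd: float = DEFAULT_RT_SD,
                  acc: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-trial behavioral table for all subjects.

    Reaction times are Gaussian per emotion (truncated below at 1 ms);
    correctness is Bernoulli per emotion.  Columns:
    ``subject, emotion, rt_ms, correct``.
    """
    config.validate()
    rt_means = dict(DEFAULT_RT_MEANS if rt_means is None else rt_means)
    acc = dict(DEFAULT_ACCURACY if acc is None else acc)
    if rt_sd < 0:
        raise ConfigurationError("rt_sd must be >= 0")
    for e in config.emotions:
        if e not in rt_means:
            raise ConfigurationError(f"rt_means missing emotion {e!r}")
        if not 0.0 <= acc.get(e, -1) <= 1.0:
            raise ConfigurationError(f"accuracy for {e!r} must be in [0, 1]")
    rows = []
    for s in range(config.n_subjects):
        rng = _session_rng(config, s, stream=1)
        for e in config.emotions:
            n = config.n_trials_per_emotion
            rts = np.maximum(rng.normal(rt_means[e], rt_sd, n), 1.0)
            correct = rng.random(n) < acc[e]
            rows.append(pd.DataFrame({
                "subject": f"S{s + 1}",
                "emotion": e,
                "rt_ms": rts,
                "correct": correct,
            }))
    return pd.concat(rows, ignore_index=True)
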