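"""Synthetic two-class oscillatory trial generators.

Trials are a class template — a sum of raised-cosine-windowed sinusoidal
components — plus per-trial latency/amplitude jitter and additive noise.
The raised-cosine window keeps component energy concentrated in time and
frequency so discriminative content can be placed inside (or outside) a
cone of influence deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ensembles import TrialEnsemble
from .wavelet import COIBoundary, FrequencyGrid

__all__ = [
    "Component",
    "ClassTemplateSpec",
    "generate_trials",
    "generate_dataset",
    "in_coi_only_specs",
]


@dataclass(frozen=True)
class Component:
    """One windowed oscillatory burst in a class template."""

    frequency: float  # Hz
    amplitude: float  # microvolts
    onset: float  # seconds
    duration: float  # seconds
    phase: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.duration <= 0:
            raise ValueError("frequency and duration must be positive")


@dataclass(frozen=True)
class ClassTemplateSpec:
    components: tuple[Component, ...]
    n_samples: int = 200
    fs: float = 200.0
    n_trials: int = 195
    latency_jitter: float = 0.0  # seconds, per-trial sd
    amplitude_jitter: float = 0.0  # multiplicative sd around 1
    noise_sigma: float = 0.0  # white noise sd (microvolts)
    pink_weight: float = 0.0  # optional 1/f noise mix-in weight

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_trials < 1 or self.fs <= 0:
            raise ValueError("invalid spec dimensions")
        if self.noise_sigma < 0 or self.pink_weight < 0:
            raise ValueError("noise parameters must be nonnegative")
        epoch = self.n_samples / self.fs
        for c in self.components:
            if c.frequency >= self.fs / 2:
                raise ValueError(
                    f"component at {c.frequency} Hz is at/above Nyquist"
                )
            if c.duration > epoch:
                raise ValueError("component duration exceeds the epoch")


def _raised_cosine(t: np.ndarray, onset: float, duration: float) -> np.ndarray:
    """Hann-shaped window supported on [onset, onset + duration]."""
    u = (t - onset) / duration
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(u, 0.0, 1.0)))
    w[(u < 0) | (u > 1)] = 0.0
    return w


def template(spec: ClassTemplateSpec) -> np.ndarray:
    """Noise-free, jitter-free class template."""
    t = np.arange(spec.n_samples) / spec.fs
    out = np.zeros(spec.n_samples)
    for c in spec.components:
        w = _raised_cosine(t, c.onset, c.duration)
        out += c.amplitude * w * np.sin(2 * np.pi * c.frequency * t + c.phase)
    return out


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]  # keep DC finite
    shaped = np.fft.irfft(spec / np.sqrt(freqs), n)
    return shaped / shaped.std()


def generate_trials(
    spec: ClassTemplateSpec,
    rng: np.random.Generator | int,
    subject: str = "",
    channel: str = "",
    label: str = "",
) -> TrialEnsemble:
    """Draw a full single-trial ensemble for one class template."""
    rng = np.random.default_rng(rng)
    t = np.arange(spec.n_samples) / spec.fs
    trials = np.zeros((spec.n_trials, spec.n_samples))
    for i in range(spec.n_trials):
        for c in spec.components:
            onset = c.onset
            if spec.latency_jitter > 0:
                onset = onset + rng.normal(0.0, spec.latency_jitter)
            amp = c.amplitude
            if spec.amplitude_jitter > 0:
                amp = amp * max(0.0, rng.normal(1.0, spec.amplitude_jitter))
            w = _raised_cosine(t, onset, c.duration)
            trials[i] += amp * w * np.sin(
                2 * np.pi * c.frequency * t + c.phase
            )
        if spec.noise_sigma > 0:
            noise = rng.standard_normal(spec.n_samples)
            if spec.pink_weight > 0:
                pink = _pink_noise(rng, spec.n_samples)
                mix = noise + spec.pink_weight * pink
                noise = mix / np.sqrt(1.0 + spec.pink_weight**2)
            trials[i] += spec.noise_sigma * noise
    return TrialEnsemble(trials, spec.fs, subject, channel, label)


def scale_class_gap(
    spec_a: ClassTemplateSpec, spec_b: ClassTemplateSpec, gain: float
) -> tuple[ClassTemplateSpec, ClassTemplateSpec]:
    """Scale the between-class amplitude difference by ``gain``.

    Component amplitudes are moved toward/away from the pairwise mean so a
    gain of 0 removes the class difference and larger gains widen it.
    Specs must have component lists of equal length.
    """
    if len(spec_a.components) != len(spec_b.components):
        raise ValueError("specs must have matching component lists")
    new_a, new_b = [], []
    for ca, cb in zip(spec_a.components, spec_b.components):
        mean_amp = 0.5 * (ca.amplitude + cb.amplitude)
        new_a.append(
            replace(ca, amplitude=mean_amp + gain * (ca.amplitude - mean_amp))
        )
        new_b.append(
            replace(cb, amplitude=mean_amp + gain * (cb.amplitude - mean_amp))
        )
    return (
        replace(spec_a, components=tuple(new_a)),
        replace(spec_b, components=tuple(new_b)),
    )


def generate_dataset(
    spec_a: ClassTemplateSpec,
    spec_b: ClassTemplateSpec,
    channel_gains: dict[str, float],
    subjects: list[str],
    seed: int,
) -> dict[str, dict[str, dict[str, TrialEnsemble]]]:
    """Multi-subject, multi-channel two-class dataset.

    Channel c's class difference is scaled by its gain, so the
    ground-truth discriminability ranking is the descending gain order.
    Returns {subject: {channel: {class label: TrialEnsemble}}}.
    """
    if len(channel_gains) < 2:
        raise ValueError("need >= 2 channels for ranking experiments")
    root = np.random.default_rng(seed)
    dataset: dict[str, dict[str, dict[str, TrialEnsemble]]] = {}
    for subject in subjects:
        dataset[subject] = {}
        for channel, gain in channel_gains.items():
            ch_a, ch_b = scale_class_gap(spec_a, spec_b, gain)
            rng = root.spawn(1)[0]
            dataset[subject][channel] = {
                "A": generate_trials(ch_a, rng, subject, channel, "A"),
                "B": generate_trials(ch_b, rng, subject, channel, "B"),
            }
    return dataset


def in_coi_only_specs(
    base: ClassTemplateSpec,
    coi: COIBoundary,
    grid: FrequencyGrid,
    gap_amplitude: float = 1.0,
) -> tuple[ClassTemplateSpec, ClassTemplateSpec]:
    """Two class specs whose only difference lives inside the COI.

    The discriminative component is centred mid-epoch at a mid-band grid
    frequency whose COI interval is widest, so its time-frequency support
    falls inside the COI; shared components from ``base`` are kept in both
    classes.  Class A carries the component, class B does not.
    """
    nf = coi.Nf
    if nf.sum() == 0:
        raise ValueError("COI is empty; cannot place an in-COI component")
    # widest-interval band, preferring higher frequencies (tighter support)
    candidates = np.flatnonzero(nf == nf.max())
    band = int(candidates[np.argmax(grid.frequencies[candidates])])
    f_disc = float(grid.frequencies[band])
    start_s = coi.n_start[band] / base.fs
    width_s = nf[band] / base.fs
    duration = min(0.5 * width_s, 4.0 / f_disc)
    if duration <= 0:
        raise ValueError("COI too small to host a component")
    onset = start_s + 0.5 * (width_s - duration)
    disc = Component(f_disc, gap_amplitude, onset, duration)
    spec_a = replace(base, components=base.components + (disc,))
    spec_b = base
    return spec_a, spec_b
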