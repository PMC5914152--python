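"""Event-locked multichannel EEG simulation with known ground truth.

The study this pipeline targets — decoding focused anticipation of a visual
cue versus the reaction to it from a 14-channel, 128 Hz headset worn during
hour-long simulator sessions — did not release its recordings, so every
downstream stage is exercised against a generative stand-in:

* Cue onsets arrive with inter-cue intervals drawn from a normal
  distribution with mean 2.5 min and SD 1 min (the cue schedule of the
  emulated experiment); draws below ``min_interval`` are rejected and
  redrawn, since a normal interval model admits nonpositive gaps.
* Sources are independent unit-variance band-limited Gaussian processes
  (white noise through an order-4 Butterworth band-pass), one per canonical
  EEG band.  The class effect is a variance change in source space: within
  the 1.5 s window after each cue onset the designated sources are scaled
  by ``effect_ratio`` (1.0 = null data, no class structure).
* Channels are a fixed random linear mixture of the sources (a Gaussian
  draw with its singular spectrum bounded to a configurable condition
  number, columns normalized) plus white sensor noise — a crude but
  standard volume-conduction model that keeps spatial-filter recovery
  testable against the known mixing matrix.

Amplitudes are arbitrary (unit-variance sources); real recordings carry
scale, drift, line noise and muscle artifacts that this generator does not
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .filterbank import default_bank
from .io import WINDOW_S, EventList, Recording

__all__ = ["SimulationConfig", "GroundTruth", "draw_event_schedule", "simulate_recording"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic recordings.

    Times are seconds, rates Hz; ``effect_ratio`` multiplies the amplitude
    of ``effect_sources`` inside the post-cue window (1.0 disables the
    effect), and ``sensor_noise_sd`` is the white-noise SD relative to the
    unit-variance sources.
    """

    n_channels: int = 14
    fs: float = 128.0
    duration: float = 3600.0
    interval_mean: float = 150.0
    interval_sd: float = 60.0
    min_interval: float = 10.0
    effect_band: tuple[float, float] = (8.0, 12.0)
    effect_sources: tuple[int, ...] = (0,)
    effect_ratio: float = 1.0
    sensor_noise_sd: float = 0.1
    #: condition-number cap of the source-to-channel mixing.  A raw Gaussian
    #: mixing is frequently near-singular, which makes the true unmixing
    #: directions unidentifiable under sensor noise and defeats the purpose
    #: of carrying them as ground truth; real volume conduction is not
    #: near-singular either.
    mixing_cond: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.min_interval < 2 * WINDOW_S:
            raise ValueError(
                f"min_interval must be >= {2 * WINDOW_S} s so the pre and post "
                "windows of consecutive events stay disjoint"
            )
        if self.effect_ratio <= 0:
            raise ValueError("effect_ratio must be positive")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be nonnegative")
        lo, hi = self.effect_band
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError(
                f"effect_band {self.effect_band} must lie inside (0, {self.fs / 2}) Hz"
            )
        if any(s < 0 or s >= self.n_channels for s in self.effect_sources):
            raise ValueError("effect_sources must index the simulated sources")
        if self.mixing_cond < 1:
            raise ValueError("mixing_cond must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and an analyst would not.

    ``mixing_matrix`` has shape (n_sources, n_channels); channel ``c`` is
    ``mixing_matrix[:, c] . sources``.  ``source_bands`` records the band
    confining each source.
    """

    mixing_matrix: np.ndarray
    event_samples: np.ndarray
    effect_band: tuple[float, float]
    effect_sources: tuple[int, ...]
    effect_ratio: float
    source_bands: tuple[tuple[float, float], ...]

    def unmixing_direction(self, source: int) -> np.ndarray:
        """Row of the pseudoinverse mixing: the spatial filter recovering a source."""
        return np.linalg.pinv(self.mixing_matrix.T)[source]


def draw_event_schedule(cfg: SimulationConfig,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw cue-onset times (seconds) for one session.

    Successive intervals are Normal(interval_mean, interval_sd) draws,
    rejected and redrawn while below ``min_interval``; the schedule is
    truncated so every onset admits both 1.5 s analysis windows.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    onsets = []
    t = 0.0
    limit = cfg.duration - WINDOW_S
    while True:
        interval = rng.normal(cfg.interval_mean, cfg.interval_sd)
        while interval < cfg.min_interval:
            interval = rng.normal(cfg.interval_mean, cfg.interval_sd)
        t += interval
        if t >= limit:
            break
        if t >= WINDOW_S:
            onsets.append(t)
    if len(onsets) < 2:
        needed = 3 * cfg.interval_mean
        raise ValueError(
            f"duration {cfg.duration} s admits fewer than 2 events; use at "
            f"least ~{needed:.0f} s for intervals of mean {cfg.interval_mean} s"
        )
    return np.asarray(onsets)


def _band_limited_noise(n: int, band: tuple[float, float], fs: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise confined to one band (order-4 Butterworth)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_recording(cfg: SimulationConfig,
                       mixing: np.ndarray | None = None
                       ) -> tuple[Recording, EventList, GroundTruth]:
    """Generate one session: recording, cue onsets, and the ground truth.

    Sources: ``n_channels`` independent band-limited processes.  Sources
    named in ``effect_sources`` occupy ``effect_band``; the rest cycle
    through the default analysis bands.  Within ``[onset, onset + 1.5 s)``
    the effect sources are scaled by ``effect_ratio``.  Identical seeds give
    bit-identical output.

    ``mixing`` overrides the random source-to-channel matrix (shape
    n_sources x n_channels), e.g. the identity to observe sources directly.
    """
    rng = np.random.default_rng(cfg.seed)
    onset_times = draw_event_schedule(cfg, rng)
    n_samples = int(round(cfg.duration * cfg.fs))
    window = int(round(WINDOW_S * cfg.fs))
    event_samples = np.round(onset_times * cfg.fs).astype(int)

    bank = [(b.low, b.high) for b in default_bank(cfg.fs)]
    other_bands = [b for b in bank if b != tuple(cfg.effect_band)] or bank
    source_bands: list[tuple[float, float]] = []
    cycle = 0
    for s in range(cfg.n_channels):
        if s in cfg.effect_sources:
            source_bands.append(tuple(cfg.effect_band))
        else:
            source_bands.append(other_bands[cycle % len(other_bands)])
            cycle += 1

    sources = np.empty((cfg.n_channels, n_samples))
    for s, band in enumerate(source_bands):
        sources[s] = _band_limited_noise(n_samples, band, cfg.fs, rng)

    if cfg.effect_ratio != 1.0:
        for onset in event_samples:
            sources[list(cfg.effect_sources), onset : onset + window] *= cfg.effect_ratio

    if mixing is None:
        # random mixing with bounded condition number: keep the singular
        # bases of a Gaussian draw, spread the spectrum over [1/mixing_cond, 1]
        g = rng.standard_normal((cfg.n_channels, cfg.n_channels))
        u_, _, vt_ = np.linalg.svd(g)
        spectrum = np.linspace(1.0, 1.0 / cfg.mixing_cond, cfg.n_channels)
        mixing = u_ @ np.diag(spectrum) @ vt_
        mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)
    else:
        mixing = np.asarray(mixing, dtype=float)
        if mixing.shape != (cfg.n_channels, cfg.n_channels):
            raise ValueError("mixing must be n_sources x n_channels")
    channels = mixing.T @ sources
    if cfg.sensor_noise_sd > 0:
        channels = channels + rng.normal(0.0, cfg.sensor_noise_sd, channels.shape)

    recording = Recording(
        samples=channels,
        fs=cfg.fs,
        channel_labels=[f"SIM{i:02d}" for i in range(cfg.n_channels)],
    )
    events = EventList(onsets=event_samples)
    truth = GroundTruth(
        mixing_matrix=mixing,
        event_samples=event_samples,
        effect_band=tuple(cfg.effect_band),
        effect_sources=tuple(cfg.effect_sources),
        effect_ratio=cfg.effect_ratio,
        source_bands=tuple(source_bands),
    )
    return recording, events, truth
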