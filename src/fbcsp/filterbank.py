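"""Band-pass filter bank with zero-phase forward-backward FIR filtering.

The decoding pipeline splits continuous EEG into ten canonical frequency
bands (delta through low gamma, plus the 8-30 Hz sensorimotor range) before
spatial filtering.  Each band filter is a linear-phase Kaiser-window FIR
band-pass applied forward and backward in time, so the effective magnitude
response is |H(w)|^2 and the effective phase is exactly zero -- the analysis
is offline, so noncausality is free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "BandSpec",
    "FIRFilter",
    "DEFAULT_N_TAPS",
    "DEFAULT_KAISER_BETA",
    "default_bank",
    "design_bandpass",
    "flip",
    "zero_phase_filter",
    "apply_bank",
]

#: Tap count of the band-pass prototype.
DEFAULT_N_TAPS = 466

#: Kaiser window shape parameter; ~60 dB sidelobe attenuation.
DEFAULT_KAISER_BETA = 5.653


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz is not below "
                f"the Nyquist frequency {fs / 2} Hz"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: The ten analysis bands: the classical EEG rhythms split into 4 Hz strips,
#: two low-gamma strips, and the broad sensorimotor band.
_DEFAULT_BANDS = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("low_beta", 12.0, 16.0),
    ("mid_beta", 16.0, 20.0),
    ("mid_high_beta", 20.0, 24.0),
    ("high_beta", 24.0, 28.0),
    ("gamma1", 32.0, 36.0),
    ("gamma2", 36.0, 40.0),
    ("motor", 8.0, 30.0),
)


def default_bank(fs: float) -> list[BandSpec]:
    """Return the ten default analysis bands, validated against ``fs``.

    Raises ``ValueError`` when the sampling rate cannot represent the
    highest band (upper edge 40 Hz requires fs > 80 Hz).
    """
    bands = [BandSpec(name, lo, hi) for name, lo, hi in _DEFAULT_BANDS]
    for band in bands:
        band.validate_for(fs)
    return bands


@dataclass(frozen=True)
class FIRFilter:
    """Linear-phase FIR band-pass filter: coefficients plus design metadata."""

    coefficients: np.ndarray
    band: BandSpec
    fs: float
    kaiser_beta: float = DEFAULT_KAISER_BETA

    @property
    def n_taps(self) -> int:
        return len(self.coefficients)

    def frequency_response(self, freqs: np.ndarray) -> np.ndarray:
        """Complex single-pass response H(f) at the given frequencies in Hz."""
        _, h = signal.freqz(self.coefficients, worN=np.asarray(freqs, float), fs=self.fs)
        return h


def design_bandpass(
    band: BandSpec,
    fs: float,
    n_taps: int = DEFAULT_N_TAPS,
    kaiser_beta: float = DEFAULT_KAISER_BETA,
) -> FIRFilter:
    """Design a Kaiser-window FIR band-pass filter for one band."""
    if n_taps < 3:
        raise ValueError(f"n_taps must be >= 3, got {n_taps}")
    band.validate_for(fs)
    h = signal.firwin(
        n_taps,
        [band.low, band.high],
        window=("kaiser", kaiser_beta),
        pass_zero=False,
        fs=fs,
    )
    return FIRFilter(coefficients=h, band=band, fs=fs, kaiser_beta=kaiser_beta)


def flip(x: np.ndarray) -> np.ndarray:
    """Reverse sample order along the time (last) axis."""
    return np.flip(np.asarray(x), axis=-1)


def zero_phase_filter(fir: FIRFilter, x: np.ndarray) -> np.ndarray:
    """Forward-backward filtering: ``y = flip(h * flip(h * x))``.

    Accepts a 1-D signal or a (channels, samples) array; filtering acts on
    the last axis and the output has the same shape as the input.  The ends
    are reflection-padded by ``3 * n_taps`` samples before the cascade and
    the pad is discarded afterwards, which suppresses boundary transients of
    the two passes.

    The input must be longer than ``3 * n_taps`` samples: epochs (192
    samples) are far shorter than the 466-tap filter, so filtering is meant
    for the continuous recording, before epoching.
    """
    x = np.asarray(x, dtype=float)
    h = fir.coefficients
    n = x.shape[-1]
    if n <= 3 * fir.n_taps:
        raise ValueError(
            f"signal length {n} must exceed 3 * n_taps = {3 * fir.n_taps}; "
            "filter the continuous recording, not individual epochs"
        )
    pad = 3 * fir.n_taps
    xp = np.concatenate(
        [flip(x[..., 1 : pad + 1]), x, flip(x[..., -pad - 1 : -1])], axis=-1
    )
    # Two full convolutions; the composite kernel is the autocorrelation of h
    # (zero phase).  Extract the samples aligned with the padded input, then
    # strip the pad.
    v = signal.fftconvolve(xp, h[np.newaxis, :] if xp.ndim == 2 else h, mode="full", axes=-1)
    v = flip(v)
    w = signal.fftconvolve(v, h[np.newaxis, :] if xp.ndim == 2 else h, mode="full", axes=-1)
    y = flip(w)
    start = fir.n_taps - 1 + pad
    return y[..., start : start + n]


def apply_bank(recording, bank=None, n_taps: int = DEFAULT_N_TAPS,
               kaiser_beta: float = DEFAULT_KAISER_BETA):
    """Filter a continuous recording into every band of the bank.

    Returns a list of filtered copies of the recording, one per band, each
    with the same shape and metadata as the input.  Epoching happens after
    this step.
    """
    from .io import Recording  # local import to avoid a cycle

    if bank is None:
        bank = default_bank(recording.fs)
    out = []
    for band in bank:
        fir = design_bandpass(band, recording.fs, n_taps=n_taps, kaiser_beta=kaiser_beta)
        filtered = zero_phase_filter(fir, recording.samples)
        out.append(
            Recording(
                samples=filtered,
                fs=recording.fs,
                channel_labels=list(recording.channel_labels),
            )
        )
    return out
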