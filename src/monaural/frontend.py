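"""Front-end signal path: middle ear, gammatone filterbank, compression.

The linear cochlear stage is a fourth-order all-pole gammatone
filterbank realized as a cascade of four identical first-order complex
resonators per channel.  Each channel is tuned to one ERB_N (broad
tuning convention) and its gain is normalized to 0 dB at CF, so an
on-CF tone passes at unity in the steady state.  The nonlinear chains
insert a broken-stick compressor after the filterbank: instantaneous
amplitudes are passed unchanged below a calibrated knee and grow with a
power-law exponent (default 0.3) above it.

The middle-ear stage is a minimum-phase Butterworth bandpass matched to
a chain's published passband gain and -3-dB cutoffs; only those three
numbers are contractual, the detailed magnitude between the cutoffs is
an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .maps import erb_n
from .stimuli import Stimulus, spl_to_pa

__all__ = [
    "MiddleEarSpec",
    "GammatoneSpec",
    "BrokenStickSpec",
    "middle_ear_filter",
    "gammatone_filterbank",
    "gammatone_gain",
    "gammatone_group_delay",
    "broken_stick_compress",
]

# ERB of an n-th order gammatone = b * pi * (2n-2)! * 2^-(2n-2) / ((n-1)!)^2
# where b is the one-sided resonator bandwidth parameter; for n = 4 the
# inverse factor is the familiar 1.019.
_GT_ORDER = 4
_BW_FACTOR = 1.0 / 0.98175  # b = 1.0186 * ERB for a 4th-order gammatone


@dataclass(frozen=True)
class MiddleEarSpec:
    """Bandpass approximation of a middle-ear transfer function."""

    passband_gain: float = 0.0  # dB
    f_lo: float = 474.8         # Hz, lower -3 dB point
    f_hi: float = 1230.2        # Hz, upper -3 dB point
    enabled: bool = True
    order: int = 2              # Butterworth order per skirt

    def __post_init__(self) -> None:
        if self.f_lo >= self.f_hi:
            raise ValueError("middle ear requires f_lo < f_hi")


@dataclass(frozen=True)
class GammatoneSpec:
    """Linear gammatone filterbank: one channel per CF, 1-ERB_N tuning."""

    cfs: tuple = ()
    fs: float = 48000.0
    order: int = _GT_ORDER
    gain_normalization: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "cfs", tuple(float(c) for c in self.cfs))
        if any(c <= 0 or c >= self.fs / 2 for c in self.cfs):
            raise ValueError("all CFs must lie in (0, fs/2)")


@dataclass(frozen=True)
class BrokenStickSpec:
    """Instantaneous broken-stick compression above a calibrated knee.

    The knee is the peak amplitude of a sinusoid at ``knee_db`` dB SPL
    after the chain's input scaling (x0.5 for the half-amplitude
    convention), i.e. knee = 0.5 * sqrt(2) * 20e-6 * 10^(knee_db/20).
    """

    knee_db: float = 30.0
    exponent: float = 0.3
    input_scale: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.exponent <= 1.0:
            raise ValueError("compression exponent must lie in (0, 1]")

    @property
    def knee_amplitude(self) -> float:
        return self.input_scale * np.sqrt(2.0) * spl_to_pa(self.knee_db)


def _complex_pole(cf: float, fs: float) -> complex:
    b = _BW_FACTOR * erb_n(cf)  # one-sided bandwidth parameter (Hz)
    return np.exp(-2.0 * np.pi * b / fs) * np.exp(2j * np.pi * cf / fs)


def _pole_cascade_response(pole: complex, order: int, f, fs: float):
    z = np.exp(2j * np.pi * np.asarray(f, dtype=float) / fs)
    return (1.0 / (1.0 - pole / z)) ** order


def gammatone_gain(cf: float, f, fs: float = 48000.0, order: int = _GT_ORDER):
    """Magnitude response at ``f`` of the CF-normalized gammatone channel."""
    pole = _complex_pole(cf, fs)
    h = np.abs(_pole_cascade_response(pole, order, f, fs))
    h0 = abs(_pole_cascade_response(pole, order, cf, fs))
    return h / h0


def gammatone_group_delay(cf: float, fs: float = 48000.0,
                          order: int = _GT_ORDER) -> float:
    """Group delay (s) of the channel at its CF.

    For the all-pole cascade the group delay at the pole frequency is
    order * r / ((1 - r) * fs) with r the pole radius; equivalently
    (order - 1)/(2 pi b) of the analog prototype up to discretization.
    """
    r = abs(_complex_pole(cf, fs))
    return order * r / ((1.0 - r) * fs)


def middle_ear_filter(stim: Stimulus, spec: MiddleEarSpec) -> Stimulus:
    """Bandpass the stimulus with the chain's middle-ear approximation."""
    if not spec.enabled:
        return stim
    if spec.f_hi >= stim.fs / 2:
        raise ValueError("middle-ear f_hi must be below Nyquist")
    sos = signal.butter(spec.order, [spec.f_lo, spec.f_hi],
                        btype="bandpass", fs=stim.fs, output="sos")
    y = signal.sosfilt(sos, stim.samples) * 10.0 ** (spec.passband_gain / 20.0)
    out = Stimulus(y, stim.fs, stim.level_db, stim.ramp_dur,
                   stim.label + "|me")
    out.scaled_for = stim.scaled_for
    return out


def gammatone_filterbank(stim: Stimulus, spec: GammatoneSpec,
                         compensate_group_delay: bool = False) -> np.ndarray:
    """Run the stimulus through the filterbank.

    Returns an array of shape (n_channels, n_samples): one real
    waveform per CF.  The path is linear and time-invariant.  With
    ``compensate_group_delay`` each channel is advanced by its own
    group delay at CF (rounded to samples, truncated at signal start),
    aligning channel envelopes at the cost of the first few samples.
    """
    if not spec.cfs:
        raise ValueError("gammatone spec lists no CFs")
    x = stim.samples
    out = np.empty((len(spec.cfs), len(x)))
    for i, cf in enumerate(spec.cfs):
        pole = _complex_pole(cf, stim.fs)
        y = x.astype(complex)
        for _ in range(spec.order):
            y = signal.lfilter([1.0], [1.0, -pole], y)
        # For a real input the analytic (positive-frequency) component
        # carries half the amplitude: 2*Re recovers it, and dividing by
        # the complex-cascade gain at CF pins the on-CF gain to 0 dB.
        g = 1.0
        if spec.gain_normalization:
            g = 1.0 / abs(_pole_cascade_response(pole, spec.order, cf, stim.fs))
        ch = 2.0 * np.real(y) * g
        if compensate_group_delay:
            adv = int(round(gammatone_group_delay(cf, stim.fs, spec.order)
                            * stim.fs))
            if adv:
                ch = np.concatenate([ch[adv:], np.zeros(adv)])
        out[i] = ch
    return out


def broken_stick_compress(x: np.ndarray, spec: BrokenStickSpec) -> np.ndarray:
    """Sign-preserving broken-stick compression, continuous at the knee."""
    knee = spec.knee_amplitude
    ax = np.abs(x)
    above = ax > knee
    y = x.copy()
    y[above] = np.sign(x[above]) * knee * (ax[above] / knee) ** spec.exponent
    return y
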