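"""Calibrated synthetic stimuli.

Every input waveform used by the evaluation battery is generated here:
pure tones, sinusoidally amplitude-modulated (AM) tones, a frozen
broadband noise, three-component complex tones, and click trains of
alternating polarity.  Sample values represent sound pressure in
pascals; a level of L dB SPL corresponds to an rms pressure of
20e-6 * 10^(L/20) Pa.

Level calibration is measured over the whole signal including the
raised-cosine ramps; for the default ramp lengths (<= 10% of the
duration) the difference from calibrating the steady portion alone is
a few hundredths of a dB and the steady portion stays within the
0.05-dB calibration contract.

Some effective model chains interpret pressures of +-1 Pa as internal
amplitudes of +-0.5, so their inputs are attenuated by 6 dB before
processing (:func:`apply_model_level_convention`).  The scaling is
recorded on the stimulus and applying it twice is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

P_REF = 20e-6  # Pa, reference pressure for dB SPL

#: chains whose internal amplitude convention is half the pressure in Pa
HALF_AMPLITUDE_MODELS = frozenset({"dau1997", "king2019", "osses2021"})

__all__ = [
    "Stimulus",
    "P_REF",
    "HALF_AMPLITUDE_MODELS",
    "spl_to_pa",
    "make_pure_tone",
    "make_am_tone",
    "make_frozen_noise",
    "make_click_train",
    "make_complex_tone",
    "apply_model_level_convention",
    "write_wav",
    "read_wav",
]


def spl_to_pa(level_db: float) -> float:
    """rms pressure (Pa) of a signal at ``level_db`` dB SPL."""
    return P_REF * 10.0 ** (level_db / 20.0)


@dataclass
class Stimulus:
    """A calibrated sound-pressure waveform.

    samples   -- pressure per sample (Pa)
    fs        -- sampling rate (Hz)
    level_db  -- nominal level (dB SPL re 20 uPa); peSPL for click trains
    ramp_dur  -- onset/offset ramp duration (s)
    label     -- free text
    scaled_for-- chain label if the model level convention was applied
    """

    samples: np.ndarray
    fs: float
    level_db: float
    ramp_dur: float = 0.0
    label: str = ""
    scaled_for: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stimulus samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def measured_spl(self) -> float:
        """Level (dB SPL) of the central, unramped portion."""
        n = int(round(self.ramp_dur * self.fs))
        core = self.samples[n: len(self.samples) - n] if n else self.samples
        return 20.0 * np.log10(np.sqrt(np.mean(core**2)) / P_REF)


def _validate(freq: float | None, dur: float, ramp_dur: float, fs: float) -> None:
    if dur <= 0:
        raise ValueError("duration must be positive")
    if freq is not None and not (0.0 < freq < fs / 2):
        raise ValueError(f"frequency {freq} Hz must lie in (0, fs/2)")
    if ramp_dur < 0 or 2 * ramp_dur > dur:
        raise ValueError("ramps must satisfy 0 <= 2*ramp_dur <= dur")


def _ramp(x: np.ndarray, ramp_dur: float, fs: float) -> np.ndarray:
    """Apply raised-cosine on/off ramps in place and return ``x``."""
    n = int(round(ramp_dur * fs))
    if n:
        w = 0.5 * (1.0 - np.cos(np.pi * (np.arange(n) + 0.5) / n))
        x[:n] *= w
        x[-n:] *= w[::-1]
    return x


def _calibrate(x: np.ndarray, level_db: float) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("cannot calibrate an all-zero signal")
    return x * (spl_to_pa(level_db) / rms)


def make_pure_tone(freq: float, dur: float, level_db: float,
                   ramp_dur: float = 0.005, fs: float = 48000.0,
                   start_phase: float = 0.0) -> Stimulus:
    """Calibrated pure tone with raised-cosine gating."""
    _validate(freq, dur, ramp_dur, fs)
    t = np.arange(int(round(dur * fs))) / fs
    x = np.sin(2 * np.pi * freq * t + start_phase)
    x = _calibrate(x, level_db)  # calibrate before ramping: rms of the
    x = _ramp(x, ramp_dur, fs)   # steady portion carries the level
    return Stimulus(x, fs, level_db, ramp_dur, f"tone_{freq:g}Hz_{level_db:g}dB")


def make_am_tone(fc: float, fmod: float, m: float, dur: float, level_db: float,
                 ramp_dur: float = 0.005, fs: float = 48000.0) -> Stimulus:
    """Sinusoidally amplitude-modulated tone, (1 + m sin(2 pi fmod t)) sin(2 pi fc t)."""
    _validate(fc, dur, ramp_dur, fs)
    if not 0.0 <= m <= 1.0:
        raise ValueError("modulation index m must lie in [0, 1]")
    if fmod >= fc:
        raise ValueError("fmod must be below the carrier frequency")
    t = np.arange(int(round(dur * fs))) / fs
    x = (1.0 + m * np.sin(2 * np.pi * fmod * t)) * np.sin(2 * np.pi * fc * t)
    x = _calibrate(x, level_db)
    x = _ramp(x, ramp_dur, fs)
    return Stimulus(x, fs, level_db, ramp_dur,
                    f"am_{fc:g}Hz_fm{fmod:g}Hz_m{m:g}_{level_db:g}dB")


def make_frozen_noise(dur: float = 3.0, level_db: float = 40.0,
                      band: tuple[float, float] = (20.0, 20000.0),
                      seed: int = 12345, fs: float = 48000.0,
                      ramp_dur: float = 0.010) -> Stimulus:
    """Frozen broadband noise with a flat magnitude spectrum in ``band``.

    Synthesized in the frequency domain: unit magnitude inside the band,
    phases drawn uniformly from a generator seeded with ``seed`` -- the
    spectrum is flat by construction and the waveform is bit-identical
    for identical arguments.  The default seed freezes the package's
    reference noise waveform.
    """
    lo, hi = band
    if not (0.0 < lo < hi):
        raise ValueError("band must satisfy 0 < lo < hi")
    if hi > fs / 2:
        hi = fs / 2  # the flat band is clipped at Nyquist
    n = int(round(dur * fs))
    _validate(None, dur, ramp_dur, fs)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mag = ((f >= lo) & (f <= hi)).astype(float)
    rng = np.random.default_rng(seed)
    spec = mag * np.exp(2j * np.pi * rng.random(len(f)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    x = _calibrate(x, level_db)
    x = _ramp(x, ramp_dur, fs)
    return Stimulus(x, fs, level_db, ramp_dur,
                    f"noise_{level_db:g}dB_seed{seed}")


def make_click_train(rate: float = 10.0, dur: float = 1.0,
                     click_dur: float = 100e-6, pe_spl: float = 70.0,
                     alternating: bool = True, fs: float = 48000.0) -> Stimulus:
    """Train of rectangular clicks at ``pe_spl`` dB peak-equivalent SPL.

    The click amplitude A = 20e-6 * 10^(peSPL/20) * 2*sqrt(2) Pa equals
    the peak-to-peak amplitude of a sinusoid whose SPL is ``pe_spl``
    (0.1789 Pa at 70 dB peSPL, the convention of auditory-brainstem
    response work).  The first click is positive; with ``alternating``
    the polarity flips click by click.
    """
    if click_dur >= 1.0 / rate:
        raise ValueError("click_dur must be shorter than the click period")
    n_click = int(round(click_dur * fs))
    if n_click < 1:
        raise ValueError(
            f"click_dur={click_dur}s is not representable at fs={fs} Hz "
            f"(shorter than one sample)")
    n = int(round(dur * fs))
    amp = spl_to_pa(pe_spl) * 2.0 * np.sqrt(2.0)
    x = np.zeros(n)
    k = 0
    while k / rate < dur - 0.5 / fs:
        i0 = int(round(k / rate * fs))
        sign = -1.0 if (alternating and k % 2) else 1.0
        x[i0:min(i0 + n_click, n)] = sign * amp
        k += 1
    return Stimulus(x, fs, pe_spl, 0.0,
                    f"clicks_{rate:g}Hz_{pe_spl:g}dBpe")


def make_complex_tone(freqs, level_db: float, dur: float,
                      ramp_dur: float = 0.005, fs: float = 48000.0) -> Stimulus:
    """Sum of equal-peak-amplitude sinusoids, total rms at ``level_db``."""
    freqs = list(freqs)
    if not freqs:
        raise ValueError("at least one component frequency is required")
    for f0 in freqs:
        _validate(f0, dur, ramp_dur, fs)
    t = np.arange(int(round(dur * fs))) / fs
    x = np.sum([np.sin(2 * np.pi * f0 * t) for f0 in freqs], axis=0)
    x = _calibrate(x, level_db)
    x = _ramp(x, ramp_dur, fs)
    return Stimulus(x, fs, level_db, ramp_dur,
                    "complex_" + "+".join(f"{f0:g}" for f0 in freqs))


def apply_model_level_convention(stim: Stimulus, model_label: str) -> Stimulus:
    """Rescale a stimulus to the internal amplitude convention of a chain.

    Chains in :data:`HALF_AMPLITUDE_MODELS` read +-1 Pa as internal
    +-0.5, so their inputs are multiplied by 0.5 (a 6-dB attenuation);
    all other labels leave the waveform untouched.  Returns a new
    Stimulus; a second application raises.
    """
    if stim.scaled_for is not None:
        raise ValueError(
            f"level convention already applied (for {stim.scaled_for!r})")
    factor = 0.5 if model_label in HALF_AMPLITUDE_MODELS else 1.0
    return replace(stim, samples=stim.samples * factor, scaled_for=model_label)


def write_wav(path, stim: Stimulus) -> None:
    """Write a stimulus as 32-bit float WAV (samples in Pa, unclipped)."""
    from scipy.io import wavfile

    wavfile.write(path, int(stim.fs), stim.samples.astype(np.float32))


def read_wav(path, level_db: float = float("nan"), label: str = "") -> Stimulus:
    """Read a 32-bit float WAV written by :func:`write_wav`."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    return Stimulus(np.asarray(data, dtype=float), float(fs), level_db,
                    0.0, label or str(path))
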