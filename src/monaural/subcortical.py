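"""Subcortical modulation processing: modulation filterbanks and SFIE.

Two families of midbrain approximations are provided.

Modulation filterbanks -- banks of resonators tuned to envelope
fluctuation rates.  The narrow-tuning bank (Q = 2) places its
resonators so that adjacent filters intersect at their -3-dB points,
which for constant Q fixes the center-frequency ratio at
(2Q+1)/(2Q-1); starting from a 10-Hz resonator this puts a filter at
77.16 Hz, the one closest to 80 Hz.  The wide-tuning bank (Q = 1)
spaces centers geometrically by half a bandwidth (50% overlap) up to a
maximum best modulation frequency (BMF).  Filters with BMF >= 10 Hz
return the magnitude of the complex resonator output (phase-insensitive
"venelope" processing, nonnegative by construction); lower filters
return the signed, phase-preserving output.

SFIE (same-frequency inhibition-excitation) -- cochlear-nucleus and
inferior-colliculus cells modelled as an excitatory alpha-kernel
convolution minus a delayed, scaled inhibitory alpha-kernel
convolution, optionally half-wave rectified.  The kernels
t*exp(-t/tau)/tau^2 have unit area so each excitatory branch has unit
DC gain; the cell's modulation tuning is then fully determined by the
time constants, delay and inhibition strength.  The cascade of a CN
and an IC cell behaves as a single widely tuned modulation filter
(Q about 1) whose BMF :func:`sfie_bmf` computes analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "ModFilter",
    "ModFilterbankSpec",
    "SFIEParams",
    "CN_DEFAULT",
    "IC_VERHULST",
    "IC_CARNEY",
    "build_modulation_filterbank",
    "apply_modulation_filter",
    "modulation_filter_near",
    "sfie_stage",
    "sfie_transfer",
    "sfie_bmf",
]

#: below this BMF the filters keep the signed (phase-preserving) output
VENELOPE_MIN_BMF = 10.0


@dataclass(frozen=True)
class ModFilter:
    """One modulation filter: center (BMF), -3-dB bandwidth, both Hz."""

    bmf: float
    bandwidth: float

    @property
    def q(self) -> float:
        return self.bmf / self.bandwidth


@dataclass(frozen=True)
class ModFilterbankSpec:
    """Construction recipe for a modulation filterbank.

    style 'dau':  resonators from ``f_first_resonator`` upward with the
    -3-dB-overlap ratio (2Q+1)/(2Q-1), while BMF <= ``max_bmf``.
    style 'king': geometric series ending at ``max_bmf`` with spacing of
    half a bandwidth (50% overlap), ``n_filters`` filters.
    ``lp150`` marks the variants that add a 150-Hz envelope lowpass;
    ``cf_quarter_rule`` drops filters whose BMF is not below a quarter
    of the audio-channel CF.
    """

    style: str = "dau"
    q: float = 2.0
    f_first_resonator: float = 10.0
    max_bmf: float = 1000.0
    n_filters: int = 10
    lp150: bool = False
    cf_quarter_rule: bool = False

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("modulation-filter Q must be positive")
        if self.style not in ("dau", "king"):
            raise ValueError(f"unknown filterbank style: {self.style!r}")


def build_modulation_filterbank(spec: ModFilterbankSpec,
                                cf: float | None = None) -> list[ModFilter]:
    """Center/bandwidth descriptors of the bank, lowest BMF first.

    ``cf`` is the audio-channel CF; it is only consulted when the
    quarter-CF rule is active.
    """
    if spec.style == "dau":
        ratio = (2.0 * spec.q + 1.0) / (2.0 * spec.q - 1.0)
        centers = []
        c = spec.f_first_resonator
        while c <= spec.max_bmf * (1.0 + 1e-9):
            centers.append(c)
            c *= ratio
    else:  # king: spacing of half a bandwidth, i.e. ratio 1 + 1/(2Q)
        ratio = 1.0 + 1.0 / (2.0 * spec.q)
        centers = [spec.max_bmf / ratio**k for k in range(spec.n_filters)]
        centers.reverse()
    if spec.cf_quarter_rule and cf is not None:
        centers = [c for c in centers if c < cf / 4.0]
    if not centers:
        raise ValueError("no modulation filters remain after the "
                         "quarter-CF rule")
    return [ModFilter(c, c / spec.q) for c in centers]


def modulation_filter_near(bank: list[ModFilter], bmf: float = 80.0) -> ModFilter:
    """The bank filter whose BMF is closest to ``bmf`` Hz."""
    return min(bank, key=lambda flt: abs(flt.bmf - bmf))


def apply_modulation_filter(x: np.ndarray, flt: ModFilter, fs: float,
                            lp150: bool = False) -> np.ndarray:
    """Bandpass ``x`` (waveform or channel matrix) around the filter BMF.

    The resonator is a single complex pole at the BMF with radius set
    by the -3-dB bandwidth, gain-normalized to unity at the BMF.  For
    BMF >= 10 Hz the output is the magnitude of the complex response
    (venelope); below that the real (signed) part is returned.
    """
    x = np.asarray(x, dtype=float)
    r = np.exp(-np.pi * flt.bandwidth / fs)
    pole = r * np.exp(2j * np.pi * flt.bmf / fs)
    zc = np.exp(2j * np.pi * flt.bmf / fs)
    norm = abs(1.0 - pole / zc)  # unity gain at the BMF
    if lp150:
        x = _lp150(x, fs)
    y = signal.lfilter([norm], [1.0, -pole], x, axis=-1)
    # the complex resonator carries half the amplitude of the real,
    # two-sided response; the factor 2 restores it in both output modes
    if flt.bmf >= VENELOPE_MIN_BMF:
        return 2.0 * np.abs(y)
    return 2.0 * np.real(y)


def _lp150(x: np.ndarray, fs: float) -> np.ndarray:
    b, a = signal.butter(1, 150.0, btype="lowpass", fs=fs)
    return signal.lfilter(b, a, x, axis=-1)


@dataclass(frozen=True)
class SFIEParams:
    """One SFIE cell: excitation/inhibition time constants (s), the
    inhibition delay (s) and the inhibition strength S."""

    tau_exc: float
    tau_inh: float
    delay: float
    strength: float

    def __post_init__(self) -> None:
        if min(self.tau_exc, self.tau_inh, self.delay) <= 0:
            raise ValueError("SFIE time constants and delay must be positive")
        if self.strength < 0:
            raise ValueError("inhibition strength must be nonnegative")


#: cochlear-nucleus cell shared by both published parameterizations
CN_DEFAULT = SFIEParams(tau_exc=0.5e-3, tau_inh=2e-3, delay=1e-3, strength=0.6)
#: IC cell with inhibition-dominated output (S > 1)
IC_VERHULST = SFIEParams(tau_exc=0.5e-3, tau_inh=2e-3, delay=2e-3, strength=1.5)
#: IC cell with excitation-dominated output (S < 1)
IC_CARNEY = SFIEParams(tau_exc=1.11e-3, tau_inh=1.67e-3, delay=1.1e-3,
                       strength=0.9)


def _alpha_ba(tau: float, fs: float):
    """Digital (b, a) of the unit-area alpha kernel t*exp(-t/tau)/tau^2,
    i.e. the double pole 1/(1 + s*tau)^2, via the bilinear transform."""
    return signal.bilinear([1.0], [tau * tau, 2.0 * tau, 1.0], fs)


def _one_sfie(x: np.ndarray, p: SFIEParams, fs: float,
              rectify: bool) -> np.ndarray:
    be, ae = _alpha_ba(p.tau_exc, fs)
    bi, ai = _alpha_ba(p.tau_inh, fs)
    exc = signal.lfilter(be, ae, x, axis=-1)
    inh = signal.lfilter(bi, ai, x, axis=-1)
    d = int(round(p.delay * fs))
    if d:
        inh = np.concatenate(
            [np.zeros(inh.shape[:-1] + (d,)), inh[..., :-d]], axis=-1)
    y = exc - p.strength * inh
    return np.maximum(y, 0.0) if rectify else y


def sfie_stage(rate: np.ndarray, cn: SFIEParams, ic: SFIEParams, fs: float,
               rectify: bool = True) -> np.ndarray:
    """CN and IC cells in cascade applied to a nonnegative drive.

    ``rectify`` applies half-wave rectification after the subtraction in
    each cell; chains that sum many cells into a population response
    run without it.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < -1e-12):
        raise ValueError("SFIE drive must be nonnegative")
    return _one_sfie(_one_sfie(rate, cn, fs, rectify), ic, fs, rectify)


def sfie_transfer(f, cn: SFIEParams, ic: SFIEParams) -> np.ndarray:
    """Analytic modulation transfer |H_CN(f) * H_IC(f)| of the cascade.

    Each cell contributes H(f) = E(f) - S * I(f) * exp(-j 2 pi f D)
    with E, I the alpha-kernel transfer functions 1/(1 + j 2 pi f tau)^2.
    """
    f = np.asarray(f, dtype=float)

    def h(p: SFIEParams):
        e = 1.0 / (1.0 + 2j * np.pi * f * p.tau_exc) ** 2
        i = 1.0 / (1.0 + 2j * np.pi * f * p.tau_inh) ** 2
        return e - p.strength * i * np.exp(-2j * np.pi * f * p.delay)

    return np.abs(h(cn) * h(ic))


def sfie_bmf(cn: SFIEParams, ic: SFIEParams,
             f_lo: float = 1.0, f_hi: float = 500.0) -> float:
    """BMF (Hz): argmax of the analytic cascade transfer magnitude,
    located by a 1-Hz grid search refined to a 0.1-Hz grid."""
    coarse = np.arange(f_lo, f_hi + 0.5, 1.0)
    f0 = coarse[np.argmax(sfie_transfer(coarse, cn, ic))]
    fine = np.arange(max(f_lo, f0 - 2.0), min(f_hi, f0 + 2.0) + 0.05, 0.1)
    return float(fine[np.argmax(sfie_transfer(fine, cn, ic))])
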