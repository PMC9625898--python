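"""Inner-hair-cell envelope extraction and auditory-nerve adaptation.

The IHC stage is a half-wave rectifier followed by a cascade of
identical lowpass sections (bilinear-transform digital realizations of
first- or second-order analog poles, unity DC gain).  Cascading
sections narrows the overall -3-dB point below the per-section cutoff;
:func:`lp_cascade_cutoff` measures it on the digital cascade, and for N
identical first-order sections it approaches the closed form
fc * sqrt(2^(1/N) - 1).

Adaptation is modelled either by the classic chain of five divisive
feedback loops (near-logarithmic compression of stationary inputs,
roughly linear transmission of fast fluctuations, output in model units
MU with silence at 0 MU) or, for chains that do without loops, by a
3-Hz first-order highpass.

The loop time constants, the overshoot-limit factor, the input floor
and the MU scaling are configuration fields with the canonical
defaults; none of them is a fitted quantity here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "LPCascadeSpec",
    "IHC_PRESETS",
    "IHCMetrics",
    "AdaptationLoopsSpec",
    "ihc_hwr_lp",
    "lp_cascade_cutoff",
    "ac_dc_metrics",
    "adaptation_loops",
    "highpass_adaptation",
]


@dataclass(frozen=True)
class LPCascadeSpec:
    """IHC lowpass cascade: ``n_sections`` sections of ``section_order``
    poles, each with analog cutoff ``section_fc`` Hz."""

    n_sections: int = 1
    section_order: int = 1
    section_fc: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_sections < 1 or self.section_order < 1:
            raise ValueError("cascade needs at least one first-order section")
        if self.section_fc <= 0:
            raise ValueError("section cutoff must be positive")


#: published lowpass configurations per chain (sections x order @ cutoff)
IHC_PRESETS = {
    "dau1997": LPCascadeSpec(1, 1, 1000.0),
    "zilany2014": LPCascadeSpec(7, 1, 3000.0),
    "bruce2018": LPCascadeSpec(7, 1, 3000.0),
    "verhulst2015": LPCascadeSpec(1, 2, 1000.0),
    "king2019": LPCascadeSpec(1, 1, 1000.0),
    "relanoiborra2019": LPCascadeSpec(1, 2, 1000.0),
    "osses2021": LPCascadeSpec(5, 1, 2000.0),
}


def _section_ba(spec: LPCascadeSpec, fs: float):
    """Digital (b, a) of one section: bilinear transform of the analog
    all-pole prototype 1/(1 + s/wc)^order, no frequency prewarping."""
    wc = 2.0 * np.pi * spec.section_fc
    a = np.array([1.0])
    for _ in range(spec.section_order):
        a = np.polymul(a, np.array([1.0 / wc, 1.0]))
    return signal.bilinear([1.0], a, fs)


def ihc_hwr_lp(x: np.ndarray, spec: LPCascadeSpec, fs: float) -> np.ndarray:
    """Half-wave rectify, then run the lowpass cascade (unity DC gain).

    ``x`` may be a single waveform or a (channels, samples) matrix.
    """
    if spec.section_fc >= fs / 2:
        raise ValueError("section cutoff must be below Nyquist")
    b, a = _section_ba(spec, fs)
    y = np.maximum(np.asarray(x, dtype=float), 0.0)
    for _ in range(spec.n_sections):
        y = signal.lfilter(b, a, y, axis=-1)
    return y


def lp_cascade_cutoff(spec: LPCascadeSpec, fs: float,
                      n_grid: int = 200_000) -> float:
    """-3-dB frequency (Hz) of the full cascade's amplitude response.

    Evaluated on a fine frequency grid and refined by linear
    interpolation of the magnitude between the bracketing grid points.
    """
    if spec.section_fc >= fs / 2:
        raise ValueError("section cutoff must be below Nyquist")
    b, a = _section_ba(spec, fs)
    f = np.linspace(0.0, fs / 2, n_grid)
    _, h = signal.freqz(b, a, worN=f, fs=fs)
    mag = np.abs(h) ** spec.n_sections
    mag /= mag[0]
    target = 1.0 / np.sqrt(2.0)  # half-power (-3.01 dB) point
    below = np.nonzero(mag < target)[0]
    if len(below) == 0:
        raise ValueError("cascade has no -3 dB point below Nyquist")
    i = below[0]
    return float(np.interp(target, [mag[i], mag[i - 1]], [f[i], f[i - 1]]))


@dataclass(frozen=True)
class IHCMetrics:
    """AC/DC decomposition of a steady-state IHC response.

    v_ac = v_peak_max - v_peak_min (peak-to-peak);
    v_dc = (v_peak_max + v_peak_min)/2 - v_rest (mean depolarization).
    ``ratio`` is None when v_dc <= 0.
    """

    v_peak_max: float
    v_peak_min: float
    v_rest: float

    @property
    def v_ac(self) -> float:
        return self.v_peak_max - self.v_peak_min

    @property
    def v_dc(self) -> float:
        return (self.v_peak_max + self.v_peak_min) / 2.0 - self.v_rest

    @property
    def ratio(self) -> float | None:
        return self.v_ac / self.v_dc if self.v_dc > 0 else None


def ac_dc_metrics(waveform: np.ndarray, fs: float, v_rest: float = 0.0,
                  analysis_window: tuple[float, float] | None = None) -> IHCMetrics:
    """Measure the AC and DC components over a steady-state window.

    ``analysis_window`` is (start, stop) in seconds; it should exclude
    the onset (the evaluation battery discards the first 20 ms past
    onset plus the ramp).
    """
    w = np.asarray(waveform, dtype=float)
    if analysis_window is not None:
        i0, i1 = (int(round(t * fs)) for t in analysis_window)
        if not (0 <= i0 < i1 <= len(w)):
            raise ValueError("analysis window outside the waveform")
        w = w[i0:i1]
    return IHCMetrics(float(w.max()), float(w.min()), v_rest)


@dataclass(frozen=True)
class AdaptationLoopsSpec:
    """Cascade of divisive feedback loops mapping IHC drive to model units.

    time_constants   -- loop lowpass time constants (s), increasing
    overshoot_limit  -- ceiling on each loop's output relative to its
                        steady-state value (> 1 enables limitation)
    min_input        -- amplitude floor; the rms of a 0-dB-SPL tone in
                        the half-amplitude convention (1e-5)
    The output is affinely scaled so silence sits at 0 MU and a
    stationary input of amplitude 1 maps to 100 MU.
    """

    time_constants: tuple = (0.005, 0.050, 0.129, 0.253, 0.500)
    overshoot_limit: float = 10.0
    min_input: float = 1e-5

    def __post_init__(self) -> None:
        tcs = tuple(self.time_constants)
        object.__setattr__(self, "time_constants", tcs)
        if any(t2 <= t1 for t1, t2 in zip(tcs, tcs[1:])):
            raise ValueError("time constants must increase strictly")
        if self.overshoot_limit <= 1.0:
            raise ValueError("overshoot_limit must exceed 1")


def _adapt_loops_kernel(x, a1, b0, state, maxvalue, factor, expfac, offset,
                        minlvl, limited):
    y = np.empty_like(x)
    nloops = state.size
    for i in range(x.size):
        tmp = x[i]
        if tmp < minlvl:
            tmp = minlvl
        for j in range(nloops):
            tmp = tmp / state[j]
            if limited and tmp > 1.0:
                tmp = factor[j] / (1.0 + np.exp(expfac[j] * (tmp - 1.0))) \
                    - offset[j]
            state[j] = a1[j] * state[j] + b0[j] * tmp
        y[i] = tmp
    return y


try:  # the sample loop is sequential; compile it when numba is present
    from numba import njit

    _adapt_loops_kernel = njit(cache=True)(_adapt_loops_kernel)
except ImportError:  # pragma: no cover
    pass


def adaptation_loops(x: np.ndarray, spec: AdaptationLoopsSpec,
                     fs: float) -> np.ndarray:
    """Run the adaptation-loop cascade; input must be nonnegative.

    Each loop divides the signal by a lowpass-filtered copy of its own
    output, so a stationary input of amplitude ``v`` settles at
    v^(1/2^n) for n loops -- a nearly logarithmic compression -- while
    fluctuations much faster than the loop time constants pass almost
    linearly.  Overshoots are softly limited to ``overshoot_limit``
    times the steady-state output of each loop.
    """
    arr = np.asarray(x, dtype=float)
    one_d = arr.ndim == 1
    x = np.atleast_2d(arr)
    if np.any(x < -1e-12):
        raise ValueError("adaptation loops require nonnegative input "
                         "(apply the IHC stage first)")
    tau = np.asarray(spec.time_constants)
    a1 = np.exp(-1.0 / (tau * fs))
    b0 = 1.0 - a1
    minlvl = spec.min_input
    state0 = minlvl ** (2.0 ** -np.arange(1, len(tau) + 1))
    maxvalue = (1.0 - state0**2) * spec.overshoot_limit - 1.0
    factor = maxvalue * 2.0
    expfac = -2.0 / maxvalue
    offset = maxvalue - 1.0
    corr = state0[-1]
    mult = 100.0 / (1.0 - corr)
    out = np.empty_like(x)
    for ch in range(x.shape[0]):
        y = _adapt_loops_kernel(np.ascontiguousarray(x[ch]), a1, b0,
                                state0.copy(), maxvalue, factor, expfac,
                                offset, minlvl, True)
        out[ch] = (y - corr) * mult
    return out[0] if one_d else out


def highpass_adaptation(x: np.ndarray, fc: float = 3.0,
                        fs: float = 48000.0) -> np.ndarray:
    """First-order highpass (exact -3 dB at ``fc``); removes DC in steady
    state.  The light-weight adaptation stage of chains without loops."""
    if fc >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    b, a = signal.butter(1, fc, btype="highpass", fs=fs)
    return signal.lfilter(b, a, np.asarray(x, dtype=float), axis=-1)
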