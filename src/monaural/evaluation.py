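"""The comparative evaluation battery.

Each function reproduces one measurement procedure on a configured
chain: cochlear I/O curves, Q-factor (frequency-selectivity) estimates
from a frozen noise, filter counting, excitation patterns, AC/DC
analysis of the IHC output, rate-level functions, synchrony-capture
envelope metrics, modulation transfer functions, and broadband
responses to click trains.

Conventions shared by the procedures:

* Output levels are rms levels in dB re the chain's internal amplitude
  unit, shifted by a reference gain that places the response to a
  1000-Hz, 100-dB-SPL tone at 100 dB.
* Steady-state windows exclude ramps plus 20 ms after onset.
* Q estimation averages output magnitude spectra over six non-overlapped
  500-ms windows of a 3-s frozen noise, smooths them with a
  1/16-octave moving average and interpolates the -3-dB points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chains import ChainConfig, run_chain
from .maps import cf_offsets_one_erb, erb_n, greenwood_cf
from .stimuli import (Stimulus, make_am_tone, make_complex_tone,
                      make_pure_tone, spl_to_pa)

__all__ = [
    "QEstimate", "IOCurve", "RateLevelResult", "MTFCurve",
    "EnvelopeFluctuationResult", "ClickResponseResult",
    "chain_reference_gain", "excitation_pattern", "io_curves",
    "estimate_q3db", "count_filters", "rate_level_curves",
    "synchrony_fluctuation", "mtf_experiment", "click_abr_response",
    "ACDC_SECTIONS", "SYNCHRONY_SECTIONS", "QFACTOR_SECTIONS",
]

#: cochlear sections of the 12 AC/DC test tones (150 Hz .. 4013 Hz)
ACDC_SECTIONS = tuple(range(387, 111, -25))
#: sections of the seven synchrony-capture channels (415 Hz .. 1007 Hz)
SYNCHRONY_SECTIONS = (320, 308, 295, 283, 270, 258, 245)
#: sections of the 32 Q-estimation channels (126 Hz .. 9587 Hz)
QFACTOR_SECTIONS = tuple(range(396, 23, -12))


@dataclass(frozen=True)
class QEstimate:
    cf: float
    bw_3db: float
    level_db: float

    @property
    def q(self) -> float:
        return self.cf / self.bw_3db

    @property
    def bw_erb(self) -> float:
        """Bandwidth expressed in ERB_N units."""
        return self.bw_3db / erb_n(self.cf)


@dataclass(frozen=True)
class IOCurve:
    levels: np.ndarray       # input levels, dB SPL
    out_levels: np.ndarray   # output levels, dB (reference-shifted)
    cf_offset: str           # 'on' | '-1erb' | '+1erb'
    cf: float

    def slopes(self) -> np.ndarray:
        """Local slope dB/dB between adjacent level points."""
        return np.diff(self.out_levels) / np.diff(self.levels)


@dataclass(frozen=True)
class RateLevelResult:
    levels: np.ndarray
    onset: np.ndarray    # max of the response
    steady: np.ndarray   # mean over the plateau window
    units: str


@dataclass(frozen=True)
class MTFCurve:
    fmods: np.ndarray
    gains: np.ndarray    # normalized; max == 1

    @property
    def bmf(self) -> float:
        return float(self.fmods[np.argmax(self.gains)])


@dataclass(frozen=True)
class EnvelopeFluctuationResult:
    cfs: np.ndarray
    metric: np.ndarray       # std(envelope) / (scale/30), dimensionless
    on_cf: np.ndarray        # boolean mask, True for on-frequency channels
    scale: float

    @property
    def mean_on(self) -> float:
        return float(np.mean(self.metric[self.on_cf]))

    @property
    def mean_off(self) -> float:
        return float(np.mean(self.metric[~self.on_cf]))


@dataclass(frozen=True)
class ClickResponseResult:
    waveform: np.ndarray     # broadband (CF-averaged) stage-6 response
    fs: float
    p2p_pos: float           # peak-to-peak after the 9th (+A) click
    p2p_neg: float           # peak-to-peak after the 10th (-A) click


def _steady_rms_db(y: np.ndarray, fs: float, dur: float,
                   ramp: float) -> np.ndarray:
    """rms level (dB re 1) over the final half of the tone, excluding
    the offset ramp."""
    i0 = int(round((dur - ramp) / 2.0 * fs))
    i1 = int(round((dur - ramp) * fs))
    seg = np.atleast_2d(y)[:, i0:i1]
    return 20.0 * np.log10(np.sqrt(np.mean(seg**2, axis=1)))


def chain_reference_gain(cfg: ChainConfig, ref_freq: float = 1000.0,
                         ref_level: float = 100.0) -> float:
    """Gain (dB) shifting the chain's cochlear output scale so the on-CF
    response to a 1000-Hz, 100-dB-SPL reference tone sits at 100 dB."""
    tone = make_pure_tone(ref_freq, 0.1, ref_level, 0.01, cfg.fs)
    y = run_chain(tone, cfg.with_cfs([ref_freq]), tap="cochlea")
    lvl = _steady_rms_db(y, cfg.fs, 0.1, 0.01)[0]
    return ref_level - lvl


def excitation_pattern(cfg: ChainConfig, stim: Stimulus, cfs,
                       ref_gain: float | None = None) -> np.ndarray:
    """Per-CF rms level (dB, reference-shifted) of the cochlear tap."""
    if ref_gain is None:
        ref_gain = chain_reference_gain(cfg)
    y = run_chain(stim, cfg.with_cfs(cfs), tap="cochlea")
    return _steady_rms_db(y, cfg.fs, stim.duration, stim.ramp_dur) + ref_gain


def io_curves(cfg: ChainConfig, freq: float, levels=None,
              tone_dur: float = 0.1, ramp: float = 0.01) -> dict[str, IOCurve]:
    """Cochlear input/output curves at the on-CF channel and one ERB_N
    below and above, for tone levels 0..100 dB SPL by default."""
    if levels is None:
        levels = np.arange(0.0, 100.1, 10.0)
    levels = np.asarray(levels, dtype=float)
    below, above = cf_offsets_one_erb(freq)
    cfs = [freq, below, above]
    ref_gain = chain_reference_gain(cfg)
    outs = np.empty((len(levels), 3))
    for i, lev in enumerate(levels):
        tone = make_pure_tone(freq, tone_dur, lev, ramp, cfg.fs)
        y = run_chain(tone, cfg.with_cfs(cfs), tap="cochlea")
        outs[i] = _steady_rms_db(y, cfg.fs, tone_dur, ramp) + ref_gain
    return {
        "on": IOCurve(levels, outs[:, 0], "on", freq),
        "-1erb": IOCurve(levels, outs[:, 1], "-1erb", below),
        "+1erb": IOCurve(levels, outs[:, 2], "+1erb", above),
    }


def _smooth_log_octave(f: np.ndarray, mag: np.ndarray,
                       width_oct: float) -> np.ndarray:
    """Moving average of ``mag`` over a ``width_oct``-octave window in
    log-frequency (cumulative-sum implementation)."""
    lf = np.log2(np.maximum(f, f[1] if len(f) > 1 else 1.0))
    half = width_oct / 2.0
    lo = np.searchsorted(lf, lf - half)
    hi = np.searchsorted(lf, lf + half)
    c = np.concatenate([[0.0], np.cumsum(mag)])
    return (c[hi] - c[lo]) / np.maximum(hi - lo, 1)


def estimate_q3db(cfg: ChainConfig, cfs, noise: Stimulus,
                  window_dur: float = 0.5,
                  smooth_oct: float = 1.0 / 16.0) -> list[QEstimate]:
    """Q_-3dB = CF/BW per channel from the response to a frozen noise.

    The per-channel output magnitude spectrum is averaged over
    consecutive non-overlapped ``window_dur`` windows (six for the 3-s
    noise), smoothed over ``smooth_oct`` octaves, and the -3-dB points
    on either side of the peak are linearly interpolated.  Channels
    without a -3-dB crossing are skipped.
    """
    if noise.duration < 2 * window_dur:
        raise ValueError("noise too short for spectrum averaging")
    cfs = np.asarray(cfs, dtype=float)
    y = run_chain(noise, cfg.with_cfs(cfs), tap="cochlea")
    wlen = int(round(window_dur * cfg.fs))
    n_win = y.shape[1] // wlen
    f = np.fft.rfftfreq(wlen, 1.0 / cfg.fs)
    out: list[QEstimate] = []
    for i, cf in enumerate(cfs):
        segs = y[i, : n_win * wlen].reshape(n_win, wlen)
        mag = np.mean(np.abs(np.fft.rfft(segs, axis=1)), axis=0)
        if smooth_oct:
            mag = _smooth_log_octave(f, mag, smooth_oct)
        pk = int(np.argmax(mag))
        target = mag[pk] / np.sqrt(2.0)  # half-power point
        up = np.nonzero(mag[pk:] < target)[0]
        down = np.nonzero(mag[: pk + 1][::-1] < target)[0]
        if len(up) == 0 or len(down) == 0:
            continue  # flagged: no -3 dB crossing for this channel
        iu = pk + up[0]
        f_hi = np.interp(target, [mag[iu], mag[iu - 1]], [f[iu], f[iu - 1]])
        il = pk - down[0]
        f_lo = np.interp(target, [mag[il], mag[il + 1]], [f[il], f[il + 1]])
        out.append(QEstimate(float(cf), float(f_hi - f_lo), noise.level_db))
    return out


def count_filters(q_estimates: list[QEstimate], f_start: float = 126.0,
                  f_stop: float = 8000.0) -> tuple[int, float]:
    """Number of -3-dB-overlapped filters covering [f_start, f_stop].

    The first filter is centered at ``f_start``; every next center is
    placed so that its lower -3-dB edge meets the previous filter's
    upper edge, interpolating Q log-log between the measured CFs; the
    count includes the first filter whose upper edge reaches
    ``f_stop``.  Also returns the mean bandwidth of the placed filters
    in ERB_N units.
    """
    cfs = np.array([q.cf for q in q_estimates])
    qs = np.array([q.q for q in q_estimates])
    order = np.argsort(cfs)
    lc, lq = np.log(cfs[order]), np.log(qs[order])

    def q_of(cf: float) -> float:
        return float(np.exp(np.interp(np.log(cf), lc, lq)))

    cf = f_start
    count = 0
    bw_erb = []
    while True:
        bw = cf / q_of(cf)
        count += 1
        bw_erb.append(bw / erb_n(cf))
        edge = cf + bw / 2.0
        if edge >= f_stop or count > 10_000:
            break
        nxt = edge * 1.05
        for _ in range(100):  # fixed point: lower edge of next == edge
            new = edge + nxt / q_of(nxt) / 2.0
            if abs(new - nxt) < 1e-9:
                break
            nxt = new
        cf = nxt
    return count, float(np.mean(bw_erb))


def rate_level_curves(cfg: ChainConfig, freq: float = 4000.0, levels=None,
                      tone_dur: float = 0.3, ramp: float = 0.0025,
                      pre_silence: float = 0.05,
                      post_silence: float = 0.1) -> RateLevelResult:
    """Onset (max) and steady-state (plateau mean) response versus level.

    The tone starts after ``pre_silence`` seconds; the plateau window is
    300-340 ms on the trace, i.e. the final portion of the 300-ms tone.
    """
    if levels is None:
        levels = np.arange(0.0, 100.1, 10.0)
    levels = np.asarray(levels, dtype=float)
    fs = cfg.fs
    i0, i1 = int(round(0.300 * fs)), int(round(0.340 * fs))
    onset = np.empty(len(levels))
    steady = np.empty(len(levels))
    for i, lev in enumerate(levels):
        tone = make_pure_tone(freq, tone_dur, lev, ramp, fs)
        x = np.concatenate([np.zeros(int(round(pre_silence * fs))),
                            tone.samples,
                            np.zeros(int(round(post_silence * fs)))])
        stim = Stimulus(x, fs, lev, ramp, tone.label + "|padded")
        y = run_chain(stim, cfg.with_cfs([freq]), tap="an")[0]
        onset[i] = y.max()
        steady[i] = y[i0:i1].mean()
    units = "MU" if cfg.adaptation == "loops" else "a.u."
    return RateLevelResult(levels, onset, steady, units)


def synchrony_fluctuation(cfg: ChainConfig, stim: Stimulus | None = None,
                          cfs=None, scale: float = 800.0,
                          component_freqs=(414.0, 650.0, 1000.0),
                          window: tuple[float, float] = (0.220, 0.250),
                          ) -> EnvelopeFluctuationResult:
    """Envelope-fluctuation metric of the AN response to a complex tone.

    Per channel, an envelope is traced by connecting consecutive local
    maxima whose amplitude exceeds the channel's mean response (onset
    excluded), sampled on the original time grid over the analysis
    window; the metric is std(envelope) / (scale/30).  Channels with
    fewer than two qualifying maxima report 0.
    """
    fs = cfg.fs
    if stim is None:
        stim = make_complex_tone(component_freqs, 50.0, 0.3, 0.005, fs)
    if cfs is None:
        cfs = [greenwood_cf(n) for n in SYNCHRONY_SECTIONS]
    cfs = np.asarray(cfs, dtype=float)
    y = run_chain(stim, cfg.with_cfs(cfs), tap="an")
    i0, i1 = (int(round(t * fs)) for t in window)
    onset_skip = int(round((stim.ramp_dur + 0.02) * fs))
    metric = np.empty(len(cfs))
    for i in range(len(cfs)):
        w = y[i]
        mean_resp = w[onset_skip:].mean()
        seg = w[i0:i1]
        pk = np.nonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])
                        & (seg[1:-1] > mean_resp))[0] + 1
        if len(pk) < 2:
            metric[i] = 0.0
            continue
        env = np.interp(np.arange(len(seg)), pk, seg[pk])
        metric[i] = np.std(env) / (scale / 30.0)
    on = np.zeros(len(cfs), dtype=bool)
    for f0 in component_freqs:
        on[int(np.argmin(np.abs(cfs - f0)))] = True
    return EnvelopeFluctuationResult(cfs, metric, on, scale)


def mtf_experiment(cfg: ChainConfig, carrier: float = 1000.0,
                   level_db: float = 30.0, fmods=None,
                   tone_dur: float = 0.3, ramp: float = 0.005,
                   window: tuple[float, float] = (0.190, 0.290)) -> MTFCurve:
    """Modulation transfer function of the chain's subcortical output.

    100%-modulated AM tones at the carrier are swept over ``fmods``
    (10-130 Hz in 5-Hz steps by default); the response metric per rate
    is the maximum of the on-CF stage-6 output inside the analysis
    window, normalized to the overall maximum.
    """
    if fmods is None:
        fmods = np.arange(10.0, 130.1, 5.0)
    fmods = np.asarray(fmods, dtype=float)
    fs = cfg.fs
    i0, i1 = (int(round(t * fs)) for t in window)
    resp = np.empty(len(fmods))
    for i, fm in enumerate(fmods):
        am = make_am_tone(carrier, fm, 1.0, tone_dur, level_db, ramp, fs)
        y = run_chain(am, cfg.with_cfs([carrier]), tap="subcortical")[0]
        resp[i] = np.max(y[i0:i1])
    if np.all(resp == 0):
        raise ValueError("all-zero modulation responses; check the chain")
    return MTFCurve(fmods, resp / resp.max())


def click_abr_response(cfg: ChainConfig, train: Stimulus,
                       click_rate: float = 10.0,
                       response_window: float = 0.05) -> ClickResponseResult:
    """Broadband subcortical response to an alternating click train.

    The stage-6 outputs are averaged (unweighted) across the chain's CF
    grid; peak-to-peak amplitudes are measured in a 50-ms window after
    the onsets of the 9th (+A) and 10th (-A) clicks.
    """
    y = run_chain(train, cfg, tap="subcortical")
    broadband = y.mean(axis=0)
    fs = cfg.fs
    nwin = int(round(response_window * fs))

    def p2p(click_index: int) -> float:
        i0 = int(round(click_index / click_rate * fs))
        seg = broadband[i0: i0 + nwin]
        return float(seg.max() - seg.min())

    return ClickResponseResult(broadband, fs, p2p_pos=p2p(8), p2p_neg=p2p(9))
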