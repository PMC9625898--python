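"""Model chains: configuration, presets, and stage-by-stage execution.

A chain is an ordered stage list -- middle ear (optional), gammatone
cochlea, broken-stick compression (optional), IHC envelope extraction,
adaptation (loops or 3-Hz highpass), subcortical modulation filter --
with per-stage parameters.  Three effective-model presets are built in:

``dau1997``   gammatone -> HWR + 1st-order 1-kHz lowpass -> adaptation
              loops (overshoot limit 10) -> Q=2 modulation filterbank.
``osses2021`` adds a 0-dB middle-ear bandpass (474.8-1230.2 Hz) and
              channel group-delay compensation, uses a 5x1st-order
              2-kHz IHC cascade, loops with overshoot limit 5, and the
              Q=2 bank with a 150-Hz envelope lowpass and the
              quarter-CF rule.
``king2019``  inserts broken-stick compression (knee 30 dB, exponent
              0.3, all channels) after the gammatone stage, uses the
              1-kHz IHC lowpass, a 3-Hz highpass for adaptation, and a
              wide (Q=1) modulation filterbank up to 120 Hz.

All three interpret +-1 Pa as internal +-0.5, so stimuli are attenuated
by 6 dB on entry (applied exactly once, tracked on the stimulus).

:func:`run_chain` evaluates a chain up to a requested tap: ``cochlea``
(after filterbank and compression), ``ihc``, ``an`` (after adaptation),
or ``subcortical`` (one modulation filter, BMF nearest 80 Hz by
default).  Outputs are (n_channels, n_samples) matrices and are fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Optional

import numpy as np

from . import frontend, ihc, subcortical
from .maps import erbspace
from .stimuli import Stimulus, apply_model_level_convention

__all__ = ["ChainConfig", "preset", "PRESET_LABELS", "run_chain", "TAPS"]

TAPS = ("cochlea", "ihc", "an", "subcortical")

#: default audio CF grid of the effective chains: 1-ERB_N spacing, 31 channels
DEFAULT_CF_RANGE = (80.0, 8000.0)


@dataclass
class ChainConfig:
    label: str
    fs: float = 48000.0
    cf_grid: tuple = ()
    middle_ear: Optional[frontend.MiddleEarSpec] = None
    compression: Optional[frontend.BrokenStickSpec] = None
    group_delay_compensation: bool = False
    ihc_lp: ihc.LPCascadeSpec = field(
        default_factory=lambda: ihc.IHC_PRESETS["dau1997"])
    adaptation: str = "loops"  # 'loops' | 'highpass' | 'none'
    adaptation_loops: ihc.AdaptationLoopsSpec = field(
        default_factory=ihc.AdaptationLoopsSpec)
    adaptation_hp_fc: float = 3.0
    modfb: subcortical.ModFilterbankSpec = field(
        default_factory=subcortical.ModFilterbankSpec)
    target_bmf: float = 80.0  # single-filter mode picks the BMF nearest this

    def __post_init__(self) -> None:
        if not self.cf_grid:
            self.cf_grid = tuple(erbspace(*DEFAULT_CF_RANGE))
        self.cf_grid = tuple(float(c) for c in self.cf_grid)
        if self.adaptation not in ("loops", "highpass", "none"):
            raise ValueError(f"unknown adaptation variant {self.adaptation!r}")

    def with_cfs(self, cfs) -> "ChainConfig":
        """A copy of this configuration on a different CF grid."""
        return _dc_replace(self, cf_grid=tuple(float(c) for c in cfs))


def preset(label: str, fs: float = 48000.0, cf_grid=()) -> ChainConfig:
    """Built-in chain configuration for a model label."""
    if label == "dau1997":
        return ChainConfig(
            label=label, fs=fs, cf_grid=tuple(cf_grid),
            ihc_lp=ihc.IHC_PRESETS["dau1997"],
            adaptation="loops",
            adaptation_loops=ihc.AdaptationLoopsSpec(overshoot_limit=10.0),
            modfb=subcortical.ModFilterbankSpec(style="dau", q=2.0),
        )
    if label == "osses2021":
        return ChainConfig(
            label=label, fs=fs, cf_grid=tuple(cf_grid),
            middle_ear=frontend.MiddleEarSpec(0.0, 474.8, 1230.2),
            group_delay_compensation=True,
            ihc_lp=ihc.IHC_PRESETS["osses2021"],
            adaptation="loops",
            adaptation_loops=ihc.AdaptationLoopsSpec(overshoot_limit=5.0),
            modfb=subcortical.ModFilterbankSpec(style="dau", q=2.0,
                                                lp150=True,
                                                cf_quarter_rule=True),
        )
    if label == "king2019":
        return ChainConfig(
            label=label, fs=fs, cf_grid=tuple(cf_grid),
            compression=frontend.BrokenStickSpec(knee_db=30.0, exponent=0.3),
            ihc_lp=ihc.IHC_PRESETS["king2019"],
            adaptation="highpass",
            modfb=subcortical.ModFilterbankSpec(style="king", q=1.0,
                                                max_bmf=120.0, n_filters=10),
        )
    raise ValueError(f"unknown chain preset {label!r}; "
                     f"choose from {sorted(PRESET_LABELS)}")


PRESET_LABELS = ("dau1997", "osses2021", "king2019")


def run_chain(stim: Stimulus, cfg: ChainConfig, tap: str = "an") -> np.ndarray:
    """Process a stimulus through the chain up to ``tap``.

    Returns a (n_channels, n_samples) matrix.  The model level
    convention is applied here exactly once; passing a stimulus that
    was already rescaled for another chain is an error.
    """
    if tap not in TAPS:
        raise ValueError(f"unknown tap {tap!r}; choose from {TAPS}")
    if stim.scaled_for is None:
        stim = apply_model_level_convention(stim, cfg.label)
    elif stim.scaled_for != cfg.label:
        raise ValueError(
            f"stimulus was scaled for {stim.scaled_for!r}, not {cfg.label!r}")
    if cfg.middle_ear is not None:
        stim = frontend.middle_ear_filter(stim, cfg.middle_ear)
    gt = frontend.GammatoneSpec(cfs=cfg.cf_grid, fs=cfg.fs)
    x = frontend.gammatone_filterbank(
        stim, gt, compensate_group_delay=cfg.group_delay_compensation)
    if cfg.compression is not None:
        x = frontend.broken_stick_compress(x, cfg.compression)
    if tap == "cochlea":
        return x
    x = ihc.ihc_hwr_lp(x, cfg.ihc_lp, cfg.fs)
    if tap == "ihc":
        return x
    if cfg.adaptation == "loops":
        x = ihc.adaptation_loops(x, cfg.adaptation_loops, cfg.fs)
    elif cfg.adaptation == "highpass":
        x = ihc.highpass_adaptation(x, cfg.adaptation_hp_fc, cfg.fs)
    if tap == "an":
        return x
    out = np.empty_like(x)
    for i, cf in enumerate(cfg.cf_grid):
        bank = subcortical.build_modulation_filterbank(cfg.modfb, cf=cf)
        flt = subcortical.modulation_filter_near(bank, cfg.target_bmf)
        out[i] = subcortical.apply_modulation_filter(
            x[i], flt, cfg.fs, lp150=cfg.modfb.lp150)
    return out
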