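"""Cochlear frequency-place maps and auditory-filter tuning formulas.

Pure functions shared by every analysis in the package: the human
base-to-apex (Greenwood-type) map from cochlear section index to
characteristic frequency (CF), the two Q_ERB tuning conventions
("sharp" physiological tuning and "broad" Glasberg-Moore tuning), the
equivalent-rectangular-bandwidth scale ERB_N, and conversions on the
ERB-number (Cam) scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CochlearMapParams",
    "greenwood_cf",
    "q_erb",
    "erb_n",
    "erb_number",
    "erb_number_to_freq",
    "cf_offsets_one_erb",
    "erbspace",
]


@dataclass(frozen=True)
class CochlearMapParams:
    """Constants of the human base-to-apex frequency-position map.

    CF_n = A0 * 10^(-a * x_n / 1000) - A * k   with  x_n = x1 + dx*(n-1),
    x in mm, a in 1/m.  The defaults discretize the map into 401
    sections running from the base (n=1, high CF) to the apex (n=401).
    """

    A0: float = 20682.0
    a: float = 61.765
    k: float = 0.85
    A: float = 165.4188
    dx: float = 0.068
    x1: float = 3.74
    n_sections: int = 401


def greenwood_cf(n, params: CochlearMapParams | None = None):
    """Characteristic frequency (Hz) of cochlear section ``n`` (1-based).

    Accepts a scalar or array of section indices.  CF decreases strictly
    with ``n`` (base to apex); with the default constants CF_1 = 12010 Hz
    and CF_401 = 113 Hz when rounded to integer Hz.
    """
    p = params or CochlearMapParams()
    n = np.asarray(n)
    if np.any(n < 1) or np.any(n > p.n_sections):
        raise ValueError(f"section index must lie in 1..{p.n_sections}")
    x = p.x1 + p.dx * (n - 1)  # mm
    cf = p.A0 * 10.0 ** (-p.a * x / 1000.0) - p.A * p.k
    return float(cf) if cf.ndim == 0 else cf


def q_erb(cf, flavor: str):
    """Q_ERB = CF / ERB of an auditory filter at ``cf`` Hz.

    ``flavor='sharp'`` uses the power-law fit to otoacoustic/behavioural
    estimates of sharp human cochlear tuning, Q = 12.7*(CF/1000)^0.3.
    ``flavor='broad'`` uses the Glasberg-Moore convention,
    Q = CF / ERB_N(CF).
    """
    cf = np.asarray(cf, dtype=float)
    if np.any(cf <= 0):
        raise ValueError("cf must be positive")
    if flavor == "sharp":
        q = 12.7 * (cf / 1000.0) ** 0.3
    elif flavor == "broad":
        q = cf / erb_n(cf)
    else:
        raise ValueError(f"unknown tuning flavor: {flavor!r}")
    return float(q) if q.ndim == 0 else q


def erb_n(cf):
    """Equivalent rectangular bandwidth (Hz) of a normal auditory filter.

    ERB_N = 24.7 * (4.37*CF/1000 + 1), the Glasberg-Moore fit.
    """
    cf = np.asarray(cf, dtype=float)
    if np.any(cf < 0):
        raise ValueError("cf must be nonnegative")
    out = 24.7 * (4.37 * cf / 1000.0 + 1.0)
    return float(out) if out.ndim == 0 else out


def erb_number(f):
    """ERB-number (Cam) of frequency ``f`` Hz: 21.4*log10(1+0.00437*f)."""
    f = np.asarray(f, dtype=float)
    out = 21.4 * np.log10(1.0 + 0.00437 * f)
    return float(out) if out.ndim == 0 else out


def erb_number_to_freq(cam):
    """Inverse of :func:`erb_number`."""
    cam = np.asarray(cam, dtype=float)
    out = (10.0 ** (cam / 21.4) - 1.0) / 0.00437
    return float(out) if out.ndim == 0 else out


def cf_offsets_one_erb(cf: float) -> tuple[float, float]:
    """CFs one ERB-number step below and above ``cf``.

    The offsets are taken on the ERB-number scale (not linear Hz), so
    the returned pair is asymmetric around ``cf`` in Hz.
    """
    if cf <= 0:
        raise ValueError("cf must be positive")
    cam = erb_number(cf)
    below = erb_number_to_freq(cam - 1.0)
    if below <= 0:
        raise ValueError(f"cf={cf} Hz is less than one ERB above 0 Hz")
    return below, erb_number_to_freq(cam + 1.0)


def erbspace(f_lo: float, f_hi: float, step_cam: float = 1.0) -> np.ndarray:
    """Frequencies spaced ``step_cam`` Cams apart covering [f_lo, f_hi]."""
    lo, hi = erb_number(f_lo), erb_number(f_hi)
    n = int(np.floor((hi - lo) / step_cam + 1e-9)) + 1
    return erb_number_to_freq(lo + step_cam * np.arange(n))
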