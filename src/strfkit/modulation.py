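"""Ripple transfer functions, MTFs and best modulation frequencies.

The ripple transfer function (RTF) is the folded 2D Fourier magnitude of an
STRF: the full transform spans spectral modulations in cycles/octave and
temporal modulations from -Nyquist (upward sweeps) to +Nyquist Hz (downward
sweeps); folding along the temporal midline combines the two sweep
directions onto the quarter-plane 0..Nyquist x 0..Nyquist.  Folding here is
energy-preserving: each quarter-plane cell carries the root-sum-square of
the FFT magnitudes over its symmetry-equivalent full-plane cells, so total
RTF power equals total FFT power exactly.

Summing the RTF down columns gives the temporal MTF, across rows the
spectral MTF.  An MTF is band-pass when it falls at least 3 dB (in power)
on both sides of its peak, low-pass otherwise; the best modulation frequency
(BMF) is the peak for band-pass MTFs and the midpoint between zero and the
interpolated upper 3-dB cutoff for low-pass MTFs.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .exceptions import InvalidParameterError, StrfkitError
from .sta import StrfEstimate

__all__ = [
    "ModulationProfile",
    "compute_rtf",
    "classify_mtf",
    "best_modulation_frequency",
    "bmf_percent_change",
    "modulation_profile",
]


@dataclass
class ModulationProfile:
    """Folded RTF with its marginals, classifications and BMFs."""

    rtf: np.ndarray  # (n_spectral, n_temporal), nonnegative
    temporal_freqs: np.ndarray  # Hz, 0..Nyquist
    spectral_freqs: np.ndarray  # cycles/octave, 0..Nyquist
    tmtf: np.ndarray
    smtf: np.ndarray
    t_class: str | None = None  # band-pass | low-pass
    s_class: str | None = None
    t_bmf: float | None = None  # Hz
    s_bmf: float | None = None  # cycles/octave


def _fold_axis_index(n: int) -> np.ndarray:
    """Map FFT bin index to its folded (absolute-frequency) index."""
    idx = np.arange(n)
    return np.minimum(idx, n - idx)


def compute_rtf(strf: StrfEstimate) -> ModulationProfile:
    """Folded 2D Fourier magnitude of an STRF with physical axes.

    All-zero STRFs yield an all-zero RTF; classification of such profiles is
    undefined and raises downstream.
    """
    v = strf.values
    power = np.abs(np.fft.fft2(v)) ** 2
    n_f, n_l = v.shape
    freq_step = float(strf.freq_axis[1] - strf.freq_axis[0])
    dt = strf.dt
    fold_s = _fold_axis_index(n_f)
    fold_t = _fold_axis_index(n_l)
    n_s = n_f // 2 + 1
    n_t = n_l // 2 + 1
    acc = np.zeros((n_s, n_t))
    np.add.at(acc, (fold_s[:, None], fold_t[None, :]), power)
    rtf = np.sqrt(acc)
    spectral_freqs = np.arange(n_s) / (n_f * freq_step)
    temporal_freqs = np.arange(n_t) / (n_l * dt)
    return ModulationProfile(
        rtf=rtf,
        temporal_freqs=temporal_freqs,
        spectral_freqs=spectral_freqs,
        tmtf=rtf.sum(axis=0),
        smtf=rtf.sum(axis=1),
    )


def _mtf_db(mtf: np.ndarray) -> np.ndarray:
    """Peak-normalized MTF in dB of power (10*log10 of squared magnitude)."""
    peak = mtf.max()
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10((mtf / peak) ** 2)


def classify_mtf(mtf: np.ndarray) -> str:
    """Classify an MTF as "band-pass" or "low-pass" by the 3-dB rule.

    Band-pass requires a fall of at least 3 dB (power) both below and above
    the peak.  High-pass shapes (3-dB fall only below the peak) are folded
    into low-pass with a warning; they are not expected for causal STRFs.
    """
    mtf = np.asarray(mtf, dtype=np.float64)
    if mtf.size == 0 or not np.any(mtf > 0):
        raise StrfkitError("MTF is zero everywhere; classification undefined")
    db = _mtf_db(mtf)
    k = int(np.argmax(db))
    falls_below = k > 0 and db[:k].min() <= -3.0
    falls_above = k < len(db) - 1 and db[k + 1 :].min() <= -3.0
    if falls_below and falls_above:
        return "band-pass"
    if falls_below and not falls_above:
        warnings.warn("high-pass MTF encountered; classifying as low-pass")
    return "low-pass"


def _upper_3db_cutoff(freqs: np.ndarray, db: np.ndarray, peak_idx: int) -> float:
    """First -3 dB crossing above the peak, linearly interpolated in dB."""
    for i in range(peak_idx, len(db) - 1):
        if db[i + 1] <= -3.0:
            frac = (-3.0 - db[i]) / (db[i + 1] - db[i])
            return float(freqs[i] + frac * (freqs[i + 1] - freqs[i]))
    return float(freqs[-1])  # never crosses: cutoff at Nyquist


def best_modulation_frequency(
    mtf: np.ndarray, freqs: np.ndarray, mtf_class: str | None = None
) -> float:
    """BMF of an MTF: peak (band-pass) or half the upper 3-dB cutoff (low-pass)."""
    mtf = np.asarray(mtf, dtype=np.float64)
    if mtf_class is None:
        mtf_class = classify_mtf(mtf)
    db = _mtf_db(mtf)
    k = int(np.argmax(db))
    if mtf_class == "band-pass":
        return float(freqs[k])
    cutoff = _upper_3db_cutoff(np.asarray(freqs), db, k)
    return 0.5 * cutoff


def bmf_percent_change(bmf_corrected: float, bmf_conventional: float) -> float:
    """Absolute percent change in BMF relative to the conventional estimate."""
    if bmf_conventional == 0:
        raise InvalidParameterError("conventional BMF is zero; percent change undefined")
    return abs(bmf_corrected - bmf_conventional) / bmf_conventional * 100.0


def modulation_profile(strf: StrfEstimate) -> ModulationProfile:
    """RTF plus MTF classifications and BMFs for one corrected STRF."""
    prof = compute_rtf(strf)
    prof.t_class = classify_mtf(prof.tmtf)
    prof.s_class = classify_mtf(prof.smtf)
    prof.t_bmf = best_modulation_frequency(prof.tmtf, prof.temporal_freqs, prof.t_class)
    prof.s_bmf = best_modulation_frequency(prof.smtf, prof.spectral_freqs, prof.s_class)
    return prof
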