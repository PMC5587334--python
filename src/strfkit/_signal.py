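"""Shared low-level signal helpers: causal filter drives and rebinning."""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len

__all__ = ["linear_drive", "pixel_drive", "block_mean"]


def linear_drive(filter_values: np.ndarray, env_values: np.ndarray) -> np.ndarray:
    """Causal linear response of a frequency x lag filter to an envelope.

    ``u(t) = sum_f sum_tau filter(f, tau) * env(f, t - tau)`` with the
    envelope treated as zero before t = 0 (zero-padded history).  The sum
    over frequency rows is taken in the Fourier domain so only one inverse
    transform is needed.  Returns a float64 series, one sample per envelope
    time bin.
    """
    if filter_values.shape[0] != env_values.shape[0]:
        raise ValueError(
            "filter and envelope frequency axes differ: "
            f"{filter_values.shape[0]} vs {env_values.shape[0]}"
        )
    n_time = env_values.shape[1]
    n_lag = filter_values.shape[1]
    nfft = next_fast_len(n_time + n_lag - 1)
    spec = np.zeros(nfft // 2 + 1, dtype=np.complex128)
    block = 32
    for lo in range(0, env_values.shape[0], block):
        hi = lo + block
        E = np.fft.rfft(env_values[lo:hi].astype(np.float64), n=nfft, axis=1)
        F = np.fft.rfft(filter_values[lo:hi].astype(np.float64), n=nfft, axis=1)
        spec += np.einsum("ij,ij->j", E, F)
    return np.fft.irfft(spec, n=nfft)[:n_time]


def pixel_drive(
    weights: np.ndarray,
    rows: np.ndarray,
    lags: np.ndarray,
    env_values: np.ndarray,
    out: np.ndarray | None = None,
    sign: float = 1.0,
) -> np.ndarray:
    """Accumulate the drive contributed by an explicit set of filter pixels.

    Each pixel (row f, lag m, weight w) contributes ``w * env(f, t - m)``.
    Pixels are grouped by lag so each group costs one row-combination and one
    shifted addition.  With ``out`` given, accumulates ``sign * drive`` into
    it in place (used for incremental threshold sweeps).
    """
    n_time = env_values.shape[1]
    if out is None:
        out = np.zeros(n_time, dtype=np.float64)
    if len(weights) == 0:
        return out
    order = np.argsort(lags, kind="stable")
    lags = np.asarray(lags)[order]
    rows_s = np.asarray(rows)[order]
    w_s = np.asarray(weights, dtype=np.float64)[order] * sign
    boundaries = np.flatnonzero(np.diff(lags)) + 1
    for chunk_rows, chunk_w, m in zip(
        np.split(rows_s, boundaries),
        np.split(w_s, boundaries),
        lags[np.concatenate(([0], boundaries))],
    ):
        contrib = chunk_w @ env_values[chunk_rows, : n_time - m]
        out[m:] += contrib
    return out


def block_mean(x: np.ndarray, factor: int) -> np.ndarray:
    """Mean over consecutive blocks of ``factor`` samples (tail truncated)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)
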