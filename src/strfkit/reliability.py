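"""Unit screening: reliability index (RI), trial similarity (TS), and
chance-level screens.

RI measures STRF stability: the estimation segment is cut into equal
segments (30 one-minute segments at full scale), STRFs are computed from two
random disjoint halves of the segments (each gain-corrected at p < 0.05),
and RI is the mean pixel-vector correlation across iterations.  TS measures
response reliability: PSTHs from two random disjoint halves of the
validation trials (10-ms bins) are correlated, averaged across iterations.
Both metrics are screened against their own circular-shift null: a unit
passes when the observed metric exceeds the empirical (1 - alpha) null
quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import apply_gain_threshold
from .dmr import StimulusEnvelope
from .exceptions import InvalidParameterError, StrfkitError
from .nulls import GainNullFit, build_null_ensemble, fit_gain_null, gain_cutoff
from .sta import _mean_subtracted, compute_psth, compute_sta

__all__ = [
    "ReliabilityReport",
    "ScreenResult",
    "reliability_index",
    "trial_similarity",
    "chance_screen",
    "screen_unit",
]


@dataclass
class ScreenResult:
    observed: float
    null_sample: np.ndarray
    threshold: float
    passed: bool


@dataclass
class ReliabilityReport:
    ri: float
    ts: float
    ri_screen: ScreenResult
    ts_screen: ScreenResult

    @property
    def passed(self) -> bool:
        return self.ri_screen.passed and self.ts_screen.passed


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def reliability_index(
    spikes: np.ndarray,
    env: StimulusEnvelope,
    n_iter: int = 200,
    n_segments: int = 30,
    p_gain: float = 0.05,
    window: float = 0.200,
    seed: int = 0,
    gain_fit: GainNullFit | None = None,
    n_null_for_fit: int = 20,
) -> float:
    """Mean split-half STRF correlation over random segment halves.

    Each iteration assigns half the segments to STRF A and the rest to STRF
    B; both are gain-corrected at ``p_gain`` before correlating their full
    pixel vectors (zeros included).  Cutoffs for a half-STRF are obtained by
    rescaling the full-data null fit to the half's spike count.  Iterations
    with an empty half or a constant corrected STRF are skipped.
    """
    spikes = np.asarray(spikes, dtype=np.float64)
    if n_segments % 2 != 0:
        raise InvalidParameterError("n_segments must be even")
    T = env.duration
    seg_len = T / n_segments
    z = _mean_subtracted(env)
    if gain_fit is None:
        ens = build_null_ensemble(
            spikes, env, n_null=n_null_for_fit, seed=seed + 1, window=window
        )
        gain_fit = fit_gain_null(ens)
    n_fit_spikes = int(np.sum(spikes >= window))
    seg_of_spike = np.minimum(
        np.floor(spikes / seg_len).astype(int), n_segments - 1
    )
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_iter):
        perm = rng.permutation(n_segments)
        half_a = set(perm[: n_segments // 2].tolist())
        in_a = np.fromiter((s in half_a for s in seg_of_spike), dtype=bool)
        vecs = []
        for sel in (in_a, ~in_a):
            sub = spikes[sel]
            if np.sum(sub >= window) == 0:
                vecs = []
                break
            sta = compute_sta(sub, env, window=window, z=z)
            fit_n = gain_fit.rescaled(n_fit_spikes, sta.n_spikes_used)
            lo, hi = gain_cutoff(fit_n, p_gain)
            corrected = apply_gain_threshold(sta, lo, hi)
            vecs.append(corrected.values.ravel())
        if len(vecs) != 2:
            continue
        r = _pearson(vecs[0], vecs[1])
        if np.isfinite(r):
            rs.append(r)
    if not rs:
        raise StrfkitError("every RI iteration was degenerate (no usable halves)")
    return float(np.mean(rs))


def trial_similarity(
    trials: list[np.ndarray],
    T_val: float,
    bin_s: float = 0.010,
    n_iter: int = 100,
    seed: int = 0,
) -> float:
    """Mean split-half PSTH correlation over random trial halves.

    Halves are disjoint; with an odd trial count one trial is dropped at
    random each iteration.
    """
    if len(trials) < 2:
        raise InvalidParameterError("trial similarity requires >= 2 trials")
    rng = np.random.default_rng(seed)
    n = len(trials)
    usable = n - (n % 2)
    rs = []
    for _ in range(n_iter):
        perm = rng.permutation(n)[:usable]
        half = usable // 2
        psth_a = compute_psth([trials[i] for i in perm[:half]], bin_s, T_val)
        psth_b = compute_psth([trials[i] for i in perm[half:]], bin_s, T_val)
        r = _pearson(psth_a.rate, psth_b.rate)
        if np.isfinite(r):
            rs.append(r)
    if not rs:
        raise StrfkitError("every TS iteration was degenerate")
    return float(np.mean(rs))


def _shift_input(data, T: float, rng: np.random.Generator):
    """Circularly shift a spike train, or each trial independently."""
    if isinstance(data, (list, tuple)):
        return [
            np.sort(np.mod(np.asarray(t) + rng.uniform(0, T), T)) for t in data
        ]
    return np.sort(np.mod(np.asarray(data) + rng.uniform(0, T), T))


def chance_screen(
    metric_fn,
    data,
    T: float,
    n_null: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
) -> ScreenResult:
    """Empirical chance screen for a reliability metric.

    ``metric_fn(data)`` maps the spike input (a spike-time array, or a list
    of trials) to a scalar; the null sample recomputes it on circularly
    shifted spike times.  The unit passes when the observed value strictly
    exceeds the empirical (1 - alpha) null quantile; ``alpha >= 1`` passes
    vacuously.
    """
    rng = np.random.default_rng(seed)
    observed = float(metric_fn(data))
    nulls = np.array(
        [float(metric_fn(_shift_input(data, T, rng))) for _ in range(n_null)]
    )
    if alpha >= 1.0:
        return ScreenResult(observed, nulls, float("-inf"), True)
    threshold = float(np.quantile(nulls[np.isfinite(nulls)], 1.0 - alpha))
    return ScreenResult(observed, nulls, threshold, bool(observed > threshold))


def screen_unit(
    spikes: np.ndarray,
    trials: list[np.ndarray],
    env: StimulusEnvelope,
    T_val: float,
    n_iter_ri: int = 200,
    n_iter_ts: int = 100,
    n_segments: int = 30,
    n_null: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
) -> ReliabilityReport:
    """Compute RI and TS and screen both against chance at level ``alpha``."""
    ens = build_null_ensemble(spikes, env, n_null=20, seed=seed + 1)
    gain_fit = fit_gain_null(ens)

    def ri_fn(sp):
        return reliability_index(
            sp, env, n_iter=n_iter_ri, n_segments=n_segments,
            seed=seed, gain_fit=gain_fit,
        )

    def ts_fn(tr):
        return trial_similarity(tr, T_val, n_iter=n_iter_ts, seed=seed)

    ri_screen = chance_screen(
        ri_fn, np.asarray(spikes), env.duration, n_null=n_null, alpha=alpha,
        seed=seed + 2,
    )
    ts_screen = chance_screen(
        ts_fn, list(trials), T_val, n_null=n_null, alpha=alpha, seed=seed + 3
    )
    return ReliabilityReport(
        ri=ri_screen.observed, ts=ts_screen.observed,
        ri_screen=ri_screen, ts_screen=ts_screen,
    )
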