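"""Circular-shift null ensembles and significance grids.

Chance structure in an STA is estimated by recomputing it after circularly
shifting all spike times by a common random offset: spike count and
inter-spike-interval structure are preserved exactly while stimulus alignment
is destroyed.  Pixel-gain cutoffs come from a normal distribution fitted to
the pooled null STA pixels; cluster-mass cutoffs come from gamma
distributions fitted, per gain level, to the masses of clusters that survive
gain thresholding of the null STAs themselves.

Significance levels live on a 30-point log-spaced grid from p = 1 (the
uncorrected STA) down to p = 1e-9; the 20 interior levels (p ~ 0.24 down to
~1e-6.5) are the gain levels retained for cluster analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cluster import label_clusters
from .dmr import StimulusEnvelope
from .exceptions import (
    DegenerateFitError,
    InvalidParameterError,
    TooFewClustersError,
    UnavailableSettingError,
)
from .sta import StrfEstimate, _mean_subtracted, compute_sta

__all__ = [
    "PGrid",
    "NullEnsemble",
    "GainNullFit",
    "ClusterNullFit",
    "SignificanceGrid",
    "make_p_grid",
    "circular_shift",
    "build_null_ensemble",
    "fit_gain_null",
    "gain_cutoff",
    "sample_null_cluster_masses",
    "fit_cluster_null",
    "cluster_cutoff",
    "build_significance_grid",
]

N_P_LEVELS = 30
RETAINED_SLICE = slice(2, 22)  # drop raw (p=1), most liberal (p~0.49), 8 most conservative


@dataclass(frozen=True)
class PGrid:
    """The 30-point significance grid and its cluster-analysis subset."""

    p_values: np.ndarray  # descending, p[k] = 10**(-9k/29)
    retained_gain_levels: np.ndarray  # 20 levels used for cluster analysis

    def retained_index(self, gain_level: float) -> int:
        idx = np.flatnonzero(np.isclose(self.retained_gain_levels, gain_level, rtol=1e-9))
        if idx.size == 0:
            raise UnavailableSettingError(
                f"gain level {gain_level!r} is not on the retained grid"
            )
        return int(idx[0])


def make_p_grid() -> PGrid:
    """Construct the significance grid in exponent space (no drift)."""
    k = np.arange(N_P_LEVELS)
    p_values = 10.0 ** (-9.0 * k / (N_P_LEVELS - 1))
    return PGrid(p_values=p_values, retained_gain_levels=p_values[RETAINED_SLICE].copy())


def circular_shift(
    spikes: np.ndarray,
    T: float,
    seed: int | np.random.Generator = 0,
    delta: float | None = None,
) -> np.ndarray:
    """Rotate all spike times by one random offset, modulo ``T``.

    ``delta`` overrides the Uniform[0, T) draw with a fixed offset.
    """
    if T <= 0:
        raise InvalidParameterError("T must be positive")
    if delta is None:
        rng = (
            np.random.default_rng(seed)
            if not isinstance(seed, np.random.Generator)
            else seed
        )
        delta = rng.uniform(0.0, T)
    return np.sort(np.mod(np.asarray(spikes, dtype=np.float64) + delta, T))


@dataclass
class NullEnsemble:
    """Null STAs from circularly shifted spike trains."""

    null_stas: list[StrfEstimate]
    shifts: np.ndarray  # seconds
    seed: int

    def __len__(self) -> int:
        return len(self.null_stas)

    def pixel_matrix(self) -> np.ndarray:
        """(n_null, n_pixels) array of flattened null STA values."""
        return np.stack([s.values.ravel() for s in self.null_stas])


@dataclass(frozen=True)
class GainNullFit:
    """Normal distribution fitted to pooled null STA pixel gains."""

    mu: float
    sigma: float
    n_samples: int

    def rescaled(self, n_spikes_fit: int, n_spikes_target: int) -> "GainNullFit":
        """Analytic rescaling to a different spike count.

        A null STA pixel is a mean over N independent pre-spike stimulus
        samples, so its SD scales as 1/sqrt(N) while its mean (the per-spike
        stimulus average, ~0) is count-invariant; the fit for a sub-sampled
        train follows from the full-data fit.
        """
        return GainNullFit(
            mu=self.mu,
            sigma=self.sigma * float(np.sqrt(n_spikes_fit / n_spikes_target)),
            n_samples=self.n_samples,
        )


@dataclass(frozen=True)
class ClusterNullFit:
    """Gamma distribution fitted to null cluster masses at one gain level."""

    gain_level: float
    shape: float
    scale: float
    n_clusters_sampled: int
    sign_scope: str = "both"  # both | exc | inh


def _fft_shift_core(
    spikes: np.ndarray, env: StimulusEnvelope, window: float, z: np.ndarray
):
    """Precompute the circular spike-triggered sum for all shifts.

    Returns ``(G, bins, n_lag)`` where ``G[f, s] = sum_i z[f, (b_i + s) mod T]``
    so that the null STA for an integer bin shift D is a column gather of G,
    corrected for the few shifted spikes that land inside the dropped initial
    window.
    """
    dt = env.dt
    n_lag = int(round(window / dt))
    n_time = env.n_time
    bins = np.floor(np.asarray(spikes, dtype=np.float64) / dt).astype(np.intp)
    np.minimum(bins, n_time - 1, out=bins)
    counts = np.bincount(bins, minlength=n_time).astype(np.float64)
    c_hat = np.conj(np.fft.rfft(counts))
    big = n_time * env.n_freq > 2e7
    G = np.empty((env.n_freq, n_time), dtype=np.float32 if big else np.float64)
    block = 32
    for lo in range(0, env.n_freq, block):
        hi = min(lo + block, env.n_freq)
        zb = np.fft.rfft(z[lo:hi].astype(np.float64), axis=1)
        zb *= c_hat[None, :]
        G[lo:hi] = np.fft.irfft(zb, n=n_time, axis=1)
    return G, bins, n_lag


def _null_sta_from_core(
    G: np.ndarray,
    bins: np.ndarray,
    z: np.ndarray,
    env: StimulusEnvelope,
    D: int,
    n_lag: int,
    template: StrfEstimate,
) -> StrfEstimate:
    n_time = env.n_time
    lag = np.arange(n_lag)
    cols = np.mod(D - lag, n_time)
    values = G[:, cols].astype(np.float64)
    shifted_bins = np.mod(bins + D, n_time)
    dropped = shifted_bins[shifted_bins < n_lag]
    for b in dropped:
        values -= z[:, np.mod(b - lag, n_time)]
    values /= len(bins) - len(dropped)
    return StrfEstimate(
        values=values,
        freq_axis=template.freq_axis,
        lag_axis=template.lag_axis,
        n_spikes_used=int(len(bins) - len(dropped)),
        correction_tag="null",
        p_settings={},
    )


def build_null_ensemble(
    spikes: np.ndarray,
    env: StimulusEnvelope,
    n_null: int = 200,
    seed: int = 0,
    window: float = 0.200,
    method: str = "fft",
) -> NullEnsemble:
    """Build ``n_null`` circular-shift null STAs.

    Shifts are drawn uniformly on the stimulus sample grid (integer multiples
    of ``env.dt``); since the STA itself is computed on that grid, sub-sample
    shift components would not alter the alignment destruction.  The "fft"
    method evaluates all shifts from one circular cross-correlation and is
    exactly equivalent to the "direct" method (shift followed by
    :func:`~strfkit.sta.compute_sta`) up to floating-point roundoff.
    """
    if n_null < 1:
        raise InvalidParameterError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    n_time = env.n_time
    D_shifts = rng.integers(0, n_time, size=n_null)
    shifts = D_shifts * env.dt
    z = _mean_subtracted(env)
    spikes = np.asarray(spikes, dtype=np.float64)
    stas: list[StrfEstimate] = []
    if method == "direct":
        for delta in shifts:
            shifted = np.sort(np.mod(spikes + delta, env.duration))
            stas.append(compute_sta(shifted, env, window=window, z=z))
    elif method == "fft":
        G, bins, n_lag = _fft_shift_core(spikes, env, window, z)
        template = StrfEstimate(
            values=np.empty((0, 0)),
            freq_axis=env.freq_axis.copy(),
            lag_axis=np.arange(n_lag) * env.dt,
        )
        for D in D_shifts:
            stas.append(
                _null_sta_from_core(G, bins, z, env, int(D), n_lag, template)
            )
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    return NullEnsemble(null_stas=stas, shifts=shifts, seed=seed)


def fit_gain_null(ens: NullEnsemble) -> GainNullFit:
    """Maximum-likelihood normal fit over all pixels of all null STAs."""
    if len(ens) == 0:
        raise InvalidParameterError("empty null ensemble")
    pooled = ens.pixel_matrix()
    mu = float(pooled.mean())
    sigma = float(pooled.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateFitError("null pixel sample is constant; cannot fit a normal")
    return GainNullFit(mu=mu, sigma=sigma, n_samples=pooled.size)


def gain_cutoff(fit: GainNullFit, p: float) -> tuple[float, float]:
    """Two-sided gain cutoffs (lo, hi) with total tail mass ``p``.

    The two-sided convention (p/2 per tail) makes the expected number of
    false-positive pixels in an N-pixel null STA equal N * p.
    """
    if not (0.0 < p <= 1.0):
        raise InvalidParameterError("p must be in (0, 1]")
    lo = float(stats.norm.ppf(p / 2.0, loc=fit.mu, scale=fit.sigma))
    hi = float(stats.norm.ppf(1.0 - p / 2.0, loc=fit.mu, scale=fit.sigma))
    return lo, hi


def _fit_excluding(pooled_sum: float, pooled_sq: float, n_total: int,
                   row: np.ndarray) -> GainNullFit:
    """Pooled normal fit over all null pixels except one STA's."""
    n = n_total - row.size
    s = pooled_sum - row.sum()
    sq = pooled_sq - (row * row).sum()
    mu = s / n
    var = sq / n - mu * mu
    if var <= 0:
        raise DegenerateFitError("degenerate leave-one-out null fit")
    return GainNullFit(mu=float(mu), sigma=float(np.sqrt(var)), n_samples=n)


def sample_null_cluster_masses(
    ens: NullEnsemble,
    gain_level: float,
    stride_i: int = 1,
    stride_j: int = 1,
    sign_scope: str = "both",
    scheme: str = "pooled",
    connectivity: int = 8,
) -> np.ndarray:
    """Masses of clusters surviving gain thresholding of null STAs.

    For every selected null STA i, gain cutoffs at ``gain_level`` are
    computed from null data excluding STA i and applied to STA i; the
    surviving sign-pure clusters are labeled and their masses collected.
    ``scheme="pooled"`` fits the cutoffs on all nulls except i (low variance,
    one fit per i); ``scheme="pairwise"`` fits them on every j-th single null
    STA separately, yielding one sample per ordered (i, j) pair, i != j.
    ``sign_scope`` restricts the sample to excitatory ("exc") or inhibitory
    ("inh") clusters for the independently thresholded variants.
    """
    if not (0.0 < gain_level < 1.0):
        raise InvalidParameterError("gain_level must be in (0, 1)")
    if sign_scope not in ("both", "exc", "inh"):
        raise InvalidParameterError(f"unknown sign_scope {sign_scope!r}")
    n = len(ens)
    masses: list[float] = []

    def collect(sta: StrfEstimate, lo: float, hi: float) -> None:
        v = sta.values
        survivors = np.where((v <= lo) | (v >= hi), v, 0.0)
        thr = sta.copy_with(survivors, "gain", {"p_gain": gain_level})
        for cl in label_clusters(thr, connectivity=connectivity).clusters:
            if sign_scope == "both" or cl.sign == sign_scope:
                masses.append(cl.mass)

    if scheme == "pooled":
        rows = [s.values.ravel() for s in ens.null_stas]
        pooled_sum = float(np.sum([r.sum() for r in rows]))
        pooled_sq = float(np.sum([(r * r).sum() for r in rows]))
        n_total = sum(r.size for r in rows)
        for i in range(0, n, stride_i):
            fit = _fit_excluding(pooled_sum, pooled_sq, n_total, rows[i])
            lo, hi = gain_cutoff(fit, gain_level)
            collect(ens.null_stas[i], lo, hi)
    elif scheme == "pairwise":
        for i in range(0, n, stride_i):
            for j in range(0, n, stride_j):
                if i == j:
                    continue
                row = ens.null_stas[j].values.ravel()
                fit = GainNullFit(
                    mu=float(row.mean()), sigma=float(row.std(ddof=0)),
                    n_samples=row.size,
                )
                lo, hi = gain_cutoff(fit, gain_level)
                collect(ens.null_stas[i], lo, hi)
    else:
        raise InvalidParameterError(f"unknown scheme {scheme!r}")
    return np.asarray(masses, dtype=np.float64)


def fit_cluster_null(
    masses: np.ndarray,
    gain_level: float = float("nan"),
    sign_scope: str = "both",
    min_masses: int = 20,
) -> ClusterNullFit:
    """Maximum-likelihood gamma fit to null cluster masses (location 0)."""
    masses = np.asarray(masses, dtype=np.float64)
    if masses.size < min_masses:
        raise TooFewClustersError(
            f"only {masses.size} null cluster masses at gain level "
            f"{gain_level:g} (need >= {min_masses})",
            gain_level=gain_level,
        )
    shape, _, scale = stats.gamma.fit(masses, floc=0.0)
    return ClusterNullFit(
        gain_level=gain_level,
        shape=float(shape),
        scale=float(scale),
        n_clusters_sampled=int(masses.size),
        sign_scope=sign_scope,
    )


def cluster_cutoff(fit: ClusterNullFit, p: float) -> float:
    """One-sided cluster-mass cutoff: the fitted (1 - p) gamma quantile."""
    if not (0.0 < p <= 1.0):
        raise InvalidParameterError("p must be in (0, 1]")
    return float(stats.gamma.ppf(1.0 - p, fit.shape, scale=fit.scale))


@dataclass
class SignificanceGrid:
    """Fitted null parameters and cutoff lookups for one unit.

    Holds the p grid, the pooled normal gain fit, and gamma cluster-mass
    fits per (gain level, sign scope).  A missing (None) cluster fit marks a
    grid cell where the nulls yielded too few clusters; requesting a cutoff
    there raises :class:`UnavailableSettingError`.
    """

    p_grid: PGrid
    gain_fit: GainNullFit
    cluster_fits: dict = field(default_factory=dict)  # (key, scope) -> fit | None
    n_null: int = 0

    @staticmethod
    def _key(gain_level: float) -> float:
        return round(float(gain_level), 12)

    def gain_cutoffs(self, p: float) -> tuple[float, float]:
        return gain_cutoff(self.gain_fit, p)

    def set_cluster_fit(self, gain_level: float, scope: str, fit) -> None:
        self.cluster_fits[(self._key(gain_level), scope)] = fit

    def has_cluster_fit(self, gain_level: float, scope: str = "both") -> bool:
        return self.cluster_fits.get((self._key(gain_level), scope)) is not None

    def get_cluster_fit(self, gain_level: float, scope: str = "both") -> ClusterNullFit:
        key = (self._key(gain_level), scope)
        if key not in self.cluster_fits or self.cluster_fits[key] is None:
            raise UnavailableSettingError(
                f"no cluster-mass fit at gain level {gain_level:g} (scope {scope})"
            )
        return self.cluster_fits[key]

    def cluster_mass_cutoff(self, gain_level: float, p: float, scope: str = "both") -> float:
        return cluster_cutoff(self.get_cluster_fit(gain_level, scope), p)


def build_significance_grid(
    ens: NullEnsemble,
    gain_levels: np.ndarray | None = None,
    sign_scopes: tuple[str, ...] = ("both",),
    stride_i: int = 1,
    stride_j: int = 1,
    scheme: str = "pooled",
    connectivity: int = 8,
    min_masses: int = 20,
) -> SignificanceGrid:
    """Fit the full significance grid from a null ensemble.

    By default cluster-mass gammas are fitted at the 20 retained gain levels
    for the joint ("both") scope; pass additional ``gain_levels`` /
    ``sign_scopes`` for fixed-policy or independently thresholded analyses.
    Grid cells with fewer than ``min_masses`` null clusters are marked
    unavailable rather than fitted.
    """
    p_grid = make_p_grid()
    if gain_levels is None:
        gain_levels = p_grid.retained_gain_levels
    grid = SignificanceGrid(p_grid=p_grid, gain_fit=fit_gain_null(ens), n_null=len(ens))
    for level in gain_levels:
        level = float(level)
        for scope in sign_scopes:
            masses = sample_null_cluster_masses(
                ens, level, stride_i=stride_i, stride_j=stride_j,
                sign_scope=scope, scheme=scheme, connectivity=connectivity,
            )
            try:
                fit = fit_cluster_null(masses, level, scope, min_masses=min_masses)
            except TooFewClustersError:
                fit = None
            grid.set_cluster_fit(level, scope, fit)
    return grid
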