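"""Dynamic-moving-ripple (DMR) stimulus envelopes.

The DMR is a broadband stimulus whose spectrotemporal envelope at any instant
is a single ripple: sinusoidal in log-frequency (spectral modulation, in
cycles/octave) and drifting in time (temporal modulation, in Hz).  Both
modulation parameters wander randomly and independently within their ranges,
so that over minutes the stimulus samples the modulation plane without bias.
This balance is what makes the plain spike-triggered average an unbiased
receptive-field estimator for this stimulus class, with no need for a
stimulus-covariance correction.

Only the envelope (the time-frequency representation on the analysis grid) is
synthesized here; the estimation machinery never consumes the audio waveform,
so no carrier-level synthesis is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "DmrParams",
    "StimulusEnvelope",
    "ModulationTrajectory",
    "modulation_trajectory",
    "generate_envelope",
]


@dataclass(frozen=True)
class DmrParams:
    """Parameters of a dynamic-moving-ripple envelope.

    Parameters
    ----------
    duration:
        Stimulus duration in seconds.
    f_low, f_high:
        Lower and upper carrier frequencies in Hz.  The frequency axis spans
        ``log2(f_high / f_low)`` octaves above ``f_low``.
    freq_step:
        Frequency resolution of the analysis grid in octaves.  With the
        defaults (50 Hz to 40 kHz, 0.05 oct) the grid has 193 bins.
    dt:
        Temporal resolution in seconds (default 1 ms).
    sm_max:
        Maximum spectral modulation in cycles/octave; the spectral modulation
        trajectory is drawn from [0, sm_max].
    tm_max:
        Maximum temporal modulation magnitude in Hz; the temporal modulation
        trajectory is drawn from [-tm_max, +tm_max] (negative = upward sweep).
    mod_depth:
        Peak-to-peak modulation depth in dB; envelope values lie in
        [-mod_depth/2, +mod_depth/2].
    sm_knot_rate, tm_knot_rate:
        Rates (Hz) at which new random modulation values are drawn; the
        trajectories interpolate linearly between these knots.
    seed:
        Seed for the single random generator driving the trajectory draws.
    """

    duration: float
    f_low: float = 50.0
    f_high: float = 40000.0
    freq_step: float = 0.05
    dt: float = 0.001
    sm_max: float = 4.0
    tm_max: float = 150.0
    mod_depth: float = 40.0
    sm_knot_rate: float = 1.0
    tm_knot_rate: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        if not (self.f_low < self.f_high):
            raise InvalidParameterError("f_low must be < f_high")
        if self.freq_step <= 0 or self.dt <= 0:
            raise InvalidParameterError("freq_step and dt must be positive")
        if self.sm_max < 0 or self.tm_max < 0:
            raise InvalidParameterError("sm_max and tm_max must be >= 0")
        if self.mod_depth < 0:
            raise InvalidParameterError("mod_depth must be >= 0")
        if self.sm_knot_rate <= 0 or self.tm_knot_rate <= 0:
            raise InvalidParameterError("knot rates must be positive")

    @property
    def span_octaves(self) -> float:
        return float(np.log2(self.f_high / self.f_low))

    @property
    def n_freq(self) -> int:
        return int(np.ceil(self.span_octaves / self.freq_step))

    @property
    def n_time(self) -> int:
        return int(round(self.duration / self.dt))

    def freq_axis(self) -> np.ndarray:
        """Bin-center frequency positions in octaves above ``f_low``."""
        n = self.n_freq
        return (np.arange(n) + 0.5) * (self.span_octaves / n)


@dataclass
class StimulusEnvelope:
    """Frequency-by-time log-amplitude matrix on the analysis grid.

    ``values`` holds dB deviations from the carrier mean level, bounded by
    +/- half the modulation depth.  ``freq_axis`` gives bin centers in
    octaves above ``f_low`` (strictly increasing, uniform step).
    """

    values: np.ndarray  # (n_freq, n_time), float32
    freq_axis: np.ndarray  # octaves above f_low
    dt: float
    f_low: float = 50.0
    mod_depth: float = 40.0
    seed: int | None = None

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_time * self.dt

    @property
    def freq_step(self) -> float:
        return float(self.freq_axis[1] - self.freq_axis[0])


@dataclass
class ModulationTrajectory:
    """Sampled spectral/temporal modulation trajectories and ripple phase.

    ``omega`` (cycles/octave) and ``f_temp`` (Hz) are piecewise-linear
    interpolations of independent uniform knot draws; ``phase`` is the
    cumulative phase 2*pi*integral(f_temp dt), left-Riemann, so that the
    ripple drifts at the instantaneous temporal modulation rate.
    """

    omega: np.ndarray
    f_temp: np.ndarray
    phase: np.ndarray
    dt: float


def _knot_interp(
    rng: np.random.Generator,
    duration: float,
    dt: float,
    knot_rate: float,
    lo: float,
    hi: float,
    n: int,
) -> np.ndarray:
    """Piecewise-linear interpolation of iid Uniform[lo, hi] knots."""
    n_knots = max(2, int(np.ceil(duration * knot_rate)) + 1)
    knot_t = np.linspace(0.0, duration, n_knots)
    knot_v = rng.uniform(lo, hi, size=n_knots)
    t = np.arange(n) * dt
    return np.interp(t, knot_t, knot_v)


def modulation_trajectory(params: DmrParams) -> ModulationTrajectory:
    """Draw the random modulation trajectories for one DMR realization.

    All randomness (spectral knots, temporal knots, initial phase) flows from
    a single generator seeded with ``params.seed``, so a fixed seed yields a
    byte-identical trajectory.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_time
    omega = _knot_interp(
        rng, params.duration, params.dt, params.sm_knot_rate, 0.0, params.sm_max, n
    )
    f_temp = _knot_interp(
        rng, params.duration, params.dt, params.tm_knot_rate,
        -params.tm_max, params.tm_max, n,
    )
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    # exclusive cumulative sum: phase[k] integrates f_temp over samples < k
    phase = phase0 + 2.0 * np.pi * params.dt * (np.cumsum(f_temp) - f_temp)
    return ModulationTrajectory(omega=omega, f_temp=f_temp, phase=phase, dt=params.dt)


def generate_envelope(
    params: DmrParams, trajectory: ModulationTrajectory | None = None
) -> StimulusEnvelope:
    """Generate the DMR envelope matrix for ``params``.

    The envelope at frequency position ``x`` (octaves above ``f_low``) and
    time ``t`` is ``(mod_depth / 2) * sin(2*pi*omega(t)*x + phase(t))`` --
    a single ripple whose density and drift follow the random trajectories.
    """
    if trajectory is None:
        trajectory = modulation_trajectory(params)
    x = params.freq_axis()
    n_time = params.n_time
    values = np.empty((params.n_freq, n_time), dtype=np.float32)
    half_depth = params.mod_depth / 2.0
    # chunked evaluation keeps the float64 phase argument out of memory
    chunk = max(1, int(4e6 // max(params.n_freq, 1)))
    two_pi = 2.0 * np.pi
    for start in range(0, n_time, chunk):
        stop = min(start + chunk, n_time)
        arg = (
            two_pi * np.outer(x, trajectory.omega[start:stop])
            + trajectory.phase[start:stop][None, :]
        )
        values[:, start:stop] = (half_depth * np.sin(arg)).astype(np.float32)
    return StimulusEnvelope(
        values=values,
        freq_axis=x,
        dt=params.dt,
        f_low=params.f_low,
        mod_depth=params.mod_depth,
        seed=params.seed,
    )
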