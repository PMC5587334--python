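"""LN predictions, prediction accuracy, and stimulus-driven variance slope.

A corrected STRF predicts the validation response by causal convolution with
the mean-subtracted validation envelope followed by half-wave rectification
(the LN model with a fixed output nonlinearity).  Accuracy is the Pearson
correlation between the prediction, block-averaged to a chosen bin size, and
the trial-averaged PSTH computed natively at that bin size.  The first
analysis-window length of the validation segment reflects zero-padded
stimulus history and is excluded from correlations by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._signal import block_mean, linear_drive
from .dmr import StimulusEnvelope
from .exceptions import InvalidParameterError
from .sta import Psth, StrfEstimate, _mean_subtracted, compute_psth

__all__ = [
    "BIN_SIZES",
    "PredictionResult",
    "VarianceSlope",
    "predict_response",
    "prediction_accuracy",
    "evaluate_prediction",
    "variance_slope",
]

BIN_SIZES = (0.001, 0.002, 0.005, 0.010, 0.020, 0.050, 0.100)


@dataclass
class PredictionResult:
    """Prediction series and its accuracy across bin sizes for one setting."""

    predicted_rate: np.ndarray  # rectified, at envelope dt
    dt: float
    transient_s: float
    accuracy_by_bin: dict  # bin_s -> Pearson r (np.nan when undefined)
    correction_tag: str = "raw"
    p_settings: dict = field(default_factory=dict)


@dataclass
class VarianceSlope:
    """OLS slope of prediction vs response correlations across units.

    A slope near 0.5 means predictions track response reliability but
    capture only about half of the stimulus-driven response variance.
    """

    slope: float
    intercept: float
    n_units: int
    response_corr: np.ndarray
    prediction_corr: np.ndarray


def predict_response(
    strf: StrfEstimate,
    env: StimulusEnvelope,
    z: np.ndarray | None = None,
) -> np.ndarray:
    """Rectified LN prediction of the response to ``env``.

    ``pred(t) = max(0, sum_f sum_tau strf(f, tau) * z(f, t - tau))`` where z
    is the mean-subtracted validation envelope (zero before t = 0).  The
    first ``strf.window`` seconds are a convolution transient.
    """
    if strf.n_freq != env.n_freq:
        raise InvalidParameterError(
            f"STRF has {strf.n_freq} frequency rows, envelope has {env.n_freq}"
        )
    if z is None:
        z = _mean_subtracted(env)
    drive = linear_drive(strf.values, z)
    return np.maximum(drive, 0.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, or NaN (flagged undefined) when either series is constant."""
    if len(a) != len(b):
        raise InvalidParameterError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def prediction_accuracy(
    pred: np.ndarray,
    psth: Psth,
    bin_s: float | None = None,
    dt: float = 0.001,
    transient_s: float = 0.0,
    exclude_transient: bool = True,
) -> float:
    """Pearson correlation between a rebinned prediction and a PSTH.

    The dt-resolution prediction is block-averaged to the PSTH bin size; an
    undefined correlation (either series constant, e.g. an all-zero
    prediction from an over-thresholded STRF) returns NaN, never silently 0.
    """
    bin_s = psth.bin_s if bin_s is None else bin_s
    if abs(bin_s - psth.bin_s) > 1e-12:
        raise InvalidParameterError("bin_s does not match the PSTH bin size")
    factor = int(round(bin_s / dt))
    if abs(factor * dt - bin_s) > 1e-9:
        raise InvalidParameterError("bin_s must be an integer multiple of dt")
    pred_b = block_mean(np.asarray(pred, dtype=np.float64), factor)
    n = min(len(pred_b), len(psth.rate))
    pred_b, resp = pred_b[:n], psth.rate[:n]
    if exclude_transient and transient_s > 0:
        skip = int(np.ceil(transient_s / bin_s - 1e-9))
        pred_b, resp = pred_b[skip:], resp[skip:]
    return _pearson(pred_b, resp)


def evaluate_prediction(
    strf: StrfEstimate,
    env: StimulusEnvelope,
    trials: list[np.ndarray],
    bin_sizes: tuple[float, ...] = BIN_SIZES,
    exclude_transient: bool = True,
    z: np.ndarray | None = None,
) -> PredictionResult:
    """Predict the validation response and score it at each bin size."""
    pred = predict_response(strf, env, z=z)
    acc: dict[float, float] = {}
    for b in bin_sizes:
        psth = compute_psth(trials, b, env.duration)
        acc[b] = prediction_accuracy(
            pred, psth, dt=env.dt, transient_s=strf.window,
            exclude_transient=exclude_transient,
        )
    return PredictionResult(
        predicted_rate=pred,
        dt=env.dt,
        transient_s=strf.window,
        accuracy_by_bin=acc,
        correction_tag=strf.correction_tag,
        p_settings=dict(strf.p_settings),
    )


def variance_slope(units: list[tuple[float, float]]) -> VarianceSlope:
    """Least-squares slope of prediction correlation on response correlation.

    ``units`` holds (response_corr, prediction_corr) pairs; pairs with an
    undefined member are dropped, and at least 3 defined pairs are required.
    """
    arr = np.asarray(units, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidParameterError("units must be (response_corr, prediction_corr) pairs")
    ok = np.isfinite(arr).all(axis=1)
    arr = arr[ok]
    if arr.shape[0] < 3:
        raise InvalidParameterError("need >= 3 units with defined correlations")
    res = stats.linregress(arr[:, 0], arr[:, 1])
    return VarianceSlope(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_units=int(arr.shape[0]),
        response_corr=arr[:, 0].copy(),
        prediction_corr=arr[:, 1].copy(),
    )
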