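"""Grid search over correction settings and cross-validated selection.

For each unit the full significance grid is searched: 30 settings for gain
thresholding, 30 x 30 for independent excitatory/inhibitory gain, 20 x 30
for gain-plus-cluster, and 20 x 30 x 30 for independent excitatory/
inhibitory cluster thresholding.  Best settings are chosen on a validation
half of the repeated segment and evaluated on the held-out test half;
halves are equal-duration random assignments of 1-s chunks, re-drawn over
ten iterations, and reported accuracies are test-half means across
iterations.  Settings are never chosen with access to test-half responses.

The search exploits linearity of the LN prediction in the STRF pixels:
thresholds only remove pixels, and survivor sets are nested along each
p-axis, so each setting's (pre-rectification) drive is obtained from its
more liberal neighbor by subtracting the removed pixels' contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._signal import block_mean, linear_drive, pixel_drive
from .cluster import CorrectionSetting, apply_gain_threshold, label_clusters
from .dmr import StimulusEnvelope
from .exceptions import InvalidParameterError, NoValidSettingError
from .nulls import SignificanceGrid, cluster_cutoff, gain_cutoff
from .sta import Psth, StrfEstimate, _mean_subtracted, compute_psth

__all__ = [
    "CvSplit",
    "SettingTable",
    "SelectionResult",
    "make_cv_splits",
    "setting_predictions",
    "accuracy_table",
    "grid_search",
    "select_best",
    "analyze_unit",
    "evaluate_population",
    "percent_improvement",
]


@dataclass(frozen=True)
class CvSplit:
    """One random assignment of validation-segment chunks to two halves."""

    validation_chunks: np.ndarray
    test_chunks: np.ndarray
    chunk_s: float
    index: int


def make_cv_splits(
    T_val: float, n_iter: int = 10, chunk_s: float = 1.0, seed: int = 0
) -> list[CvSplit]:
    """Randomly split the validation span into equal-duration halves.

    The span is divided into ``T_val / chunk_s`` chunks (the count must be
    even); each iteration assigns half of them to the validation role and
    half to the test role.  ``chunk_s = T_val / 2`` reproduces a literal
    two-segment split.
    """
    n_chunks = int(round(T_val / chunk_s))
    if abs(n_chunks * chunk_s - T_val) > 1e-9 or n_chunks < 2:
        raise InvalidParameterError("T_val must divide into >= 2 whole chunks")
    if n_chunks % 2 != 0:
        raise InvalidParameterError("chunk count must be even for equal halves")
    rng = np.random.default_rng(seed)
    splits = []
    for it in range(n_iter):
        perm = rng.permutation(n_chunks)
        half = n_chunks // 2
        splits.append(
            CvSplit(
                validation_chunks=np.sort(perm[:half]),
                test_chunks=np.sort(perm[half:]),
                chunk_s=chunk_s,
                index=it,
            )
        )
    return splits


@dataclass
class SettingTable:
    """Binned LN predictions for every setting of one correction variant."""

    variant: str
    settings: list[CorrectionSetting]
    shape: tuple  # logical grid shape, e.g. (30,), (20, 30)
    binned_pred: np.ndarray  # (n_settings, n_bins), NaN rows = unavailable
    bin_s: float
    transient_bins: int
    accuracy: np.ndarray | None = None  # filled by grid_search


def _rebin_rect(drive: np.ndarray, factor: int) -> np.ndarray:
    return block_mean(np.maximum(drive, 0.0), factor)


def _nested_gain_drives(
    sta: StrfEstimate,
    grids: SignificanceGrid,
    z: np.ndarray,
    p_values: np.ndarray,
    sign: str,
) -> np.ndarray:
    """Drives of the sign-restricted survivors along a descending p axis.

    ``sign`` is "both", "pos" or "neg"; for "pos"/"neg" only the matching
    tail's cutoff is applied (the independent-variant rule).  Row k holds
    the pre-rectification drive of pixels surviving at ``p_values[k]``.
    """
    v = sta.values
    n_time = z.shape[1]
    if sign == "both":
        base_mask = v != 0
    elif sign == "pos":
        base_mask = v > 0
    else:
        base_mask = v < 0
    u = linear_drive(np.where(base_mask, v, 0.0), z)
    out = np.empty((len(p_values), n_time))
    prev_mask = base_mask.copy()
    for k, p in enumerate(p_values):
        if p >= 1.0:
            mask = base_mask
        else:
            lo, hi = grids.gain_cutoffs(p)
            if sign == "both":
                mask = base_mask & ((v <= lo) | (v >= hi))
            elif sign == "pos":
                mask = base_mask & (v >= hi)
            else:
                mask = base_mask & (v <= lo)
        removed = prev_mask & ~mask
        n_removed = int(removed.sum())
        if n_removed:
            # subtract few removed pixels, or re-convolve when cheaper
            if n_removed <= max(512, v.size // 16):
                r, c = np.nonzero(removed)
                pixel_drive(v[r, c], r, c, z, out=u, sign=-1.0)
            else:
                u = linear_drive(np.where(mask, v, 0.0), z)
        out[k] = u
        prev_mask = mask
    return out


def _cluster_level_drives(
    sta: StrfEstimate,
    grids: SignificanceGrid,
    z: np.ndarray,
    gain_level: float,
    p_values: np.ndarray,
    scope: str,
    connectivity: int,
) -> np.ndarray | None:
    """Drives along the cluster-p axis at one gain level (scope-restricted).

    Returns None when the (gain level, scope) cluster fit is unavailable.
    """
    if not grids.has_cluster_fit(gain_level, scope if scope != "both" else "both"):
        return None
    fit = grids.get_cluster_fit(gain_level, scope if scope != "both" else "both")
    lo, hi = grids.gain_cutoffs(gain_level)
    thr = apply_gain_threshold(sta, lo, hi)
    clusters = label_clusters(thr, connectivity=connectivity).clusters
    if scope in ("exc", "inh"):
        clusters = [c for c in clusters if c.sign == scope]
    n_time = z.shape[1]
    masked = np.zeros_like(thr.values)
    for cl in clusters:
        masked[cl.rows, cl.cols] = thr.values[cl.rows, cl.cols]
    u = linear_drive(masked, z)
    order = np.argsort([c.mass for c in clusters])
    clusters = [clusters[i] for i in order]
    out = np.empty((len(p_values), n_time))
    alive_from = 0  # clusters below this index have been subtracted
    for k, p in enumerate(p_values):
        cutoff = cluster_cutoff(fit, p)
        while alive_from < len(clusters) and clusters[alive_from].mass < cutoff:
            cl = clusters[alive_from]
            pixel_drive(
                thr.values[cl.rows, cl.cols], cl.rows, cl.cols, z, out=u, sign=-1.0
            )
            alive_from += 1
        out[k] = u
    return out


def setting_predictions(
    sta: StrfEstimate,
    grids: SignificanceGrid,
    variant: str,
    env_val: StimulusEnvelope,
    bin_s: float = 0.010,
    connectivity: int = 8,
    z: np.ndarray | None = None,
) -> SettingTable:
    """Binned rectified LN predictions for every setting of ``variant``.

    Predictions depend only on the stimulus, never on the response split, so
    this table is computed once per unit and reused across all
    cross-validation iterations.
    """
    if z is None:
        z = _mean_subtracted(env_val)
    p_all = grids.p_grid.p_values
    p_ret = grids.p_grid.retained_gain_levels
    factor = int(round(bin_s / env_val.dt))
    if abs(factor * env_val.dt - bin_s) > 1e-9:
        raise InvalidParameterError("bin_s must be an integer multiple of env dt")
    transient_bins = int(np.ceil(sta.window / bin_s - 1e-9))
    n_bins = env_val.n_time // factor

    settings: list[CorrectionSetting] = []
    rows: list[np.ndarray] = []

    def emit(drive: np.ndarray | None, setting: CorrectionSetting) -> None:
        settings.append(setting)
        if drive is None:
            rows.append(np.full(n_bins, np.nan))
        else:
            rows.append(_rebin_rect(drive, factor))

    if variant == "gain":
        drives = _nested_gain_drives(sta, grids, z, p_all, "both")
        for k, p in enumerate(p_all):
            emit(drives[k], CorrectionSetting(variant="gain", p_gain=float(p)))
        shape: tuple = (len(p_all),)
    elif variant == "gain_ei":
        pos = _nested_gain_drives(sta, grids, z, p_all, "pos")
        neg = _nested_gain_drives(sta, grids, z, p_all, "neg")
        for ke, pe in enumerate(p_all):
            for ki, pi in enumerate(p_all):
                emit(
                    pos[ke] + neg[ki],
                    CorrectionSetting(
                        variant="gain_ei", p_gain_exc=float(pe), p_gain_inh=float(pi)
                    ),
                )
        shape = (len(p_all), len(p_all))
    elif variant == "cluster":
        for level in p_ret:
            drives = _cluster_level_drives(
                sta, grids, z, float(level), p_all, "both", connectivity
            )
            for k, p in enumerate(p_all):
                emit(
                    None if drives is None else drives[k],
                    CorrectionSetting(
                        variant="cluster", p_gain=float(level), p_clst=float(p)
                    ),
                )
        shape = (len(p_ret), len(p_all))
    elif variant == "cluster_ei":
        for level in p_ret:
            exc = _cluster_level_drives(
                sta, grids, z, float(level), p_all, "exc", connectivity
            )
            inh = _cluster_level_drives(
                sta, grids, z, float(level), p_all, "inh", connectivity
            )
            for ke, pe in enumerate(p_all):
                for ki, pi in enumerate(p_all):
                    drive = None if (exc is None or inh is None) else exc[ke] + inh[ki]
                    emit(
                        drive,
                        CorrectionSetting(
                            variant="cluster_ei",
                            p_gain=float(level),
                            p_clst_exc=float(pe),
                            p_clst_inh=float(pi),
                        ),
                    )
        shape = (len(p_ret), len(p_all), len(p_all))
    else:
        raise InvalidParameterError(f"unknown variant {variant!r}")

    return SettingTable(
        variant=variant,
        settings=settings,
        shape=shape,
        binned_pred=np.asarray(rows),
        bin_s=bin_s,
        transient_bins=transient_bins,
    )


def _bin_mask(
    n_bins: int, bin_s: float, transient_bins: int, split: CvSplit | None, half: str
) -> np.ndarray:
    mask = np.ones(n_bins, dtype=bool)
    mask[:transient_bins] = False
    if split is not None:
        chunks = split.validation_chunks if half == "validation" else split.test_chunks
        chunk_of_bin = np.floor(np.arange(n_bins) * bin_s / split.chunk_s + 1e-9).astype(int)
        mask &= np.isin(chunk_of_bin, chunks)
    return mask


def _rowwise_pearson(preds: np.ndarray, resp: np.ndarray) -> np.ndarray:
    """Pearson r of each prediction row against the response (NaN-safe)."""
    out = np.full(preds.shape[0], np.nan)
    sy = resp.std()
    if sy == 0 or len(resp) < 2:
        return out
    yc = resp - resp.mean()
    pc = preds - preds.mean(axis=1, keepdims=True)
    sx = pc.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc @ yc) / (len(resp) * sx * sy)
    ok = np.isfinite(r) & (sx > 0)
    out[ok] = r[ok]
    return out


def accuracy_table(
    table: SettingTable, psth: Psth, split: CvSplit | None = None,
    half: str = "validation",
) -> np.ndarray:
    """Per-setting prediction accuracy on one half of the validation span."""
    if abs(psth.bin_s - table.bin_s) > 1e-12:
        raise InvalidParameterError("PSTH bin size does not match the table")
    n = min(table.binned_pred.shape[1], len(psth.rate))
    mask = _bin_mask(n, table.bin_s, table.transient_bins, split, half)
    return _rowwise_pearson(table.binned_pred[:, :n][:, mask], psth.rate[:n][mask])


def grid_search(
    sta: StrfEstimate,
    grids: SignificanceGrid,
    variant: str,
    env_val: StimulusEnvelope,
    trials: list[np.ndarray],
    split: CvSplit | None = None,
    bin_s: float = 0.010,
    connectivity: int = 8,
) -> SettingTable:
    """Accuracy over every setting of a variant on the validation half.

    With ``split=None`` the full (post-transient) validation span is scored.
    """
    table = setting_predictions(
        sta, grids, variant, env_val, bin_s=bin_s, connectivity=connectivity
    )
    psth = compute_psth(trials, bin_s, env_val.duration)
    table.accuracy = accuracy_table(table, psth, split, half="validation")
    return table


_P_ORDER_FIELDS = (
    "p_gain", "p_gain_exc", "p_gain_inh", "p_clst", "p_clst_exc", "p_clst_inh"
)


def select_best(
    table: SettingTable, accuracy: np.ndarray | None = None
) -> CorrectionSetting:
    """Argmax setting; exact ties go to the most conservative (smallest p,
    gain levels compared before cluster levels)."""
    acc = table.accuracy if accuracy is None else accuracy
    if acc is None:
        raise InvalidParameterError("table has no accuracies; run grid_search")
    finite = np.isfinite(acc)
    if not finite.any():
        raise NoValidSettingError("all settings have undefined accuracy")
    best = np.nanmax(acc[finite])
    tied = np.flatnonzero(finite & (acc == best))

    def conservativeness(i: int):
        s = table.settings[i]
        return tuple(
            getattr(s, f) if getattr(s, f) is not None else np.inf
            for f in _P_ORDER_FIELDS
        )

    return table.settings[min(tied, key=conservativeness)]


def percent_improvement(r_corrected: float, r_raw: float) -> float:
    """(r_corrected - r_raw) / r_raw * 100."""
    return (r_corrected - r_raw) / r_raw * 100.0


DEFAULT_POLICIES = (
    "raw",
    "fixed_gain",
    "best_gain",
    "fixed_cluster",
    "best_cluster",
    "fixed_gain_ei",
    "fixed_cluster_ei",
)

FIXED_P = {
    "fixed_gain": {"p_gain": 0.01},
    "fixed_gain_ei": {"p_gain_exc": 0.01, "p_gain_inh": 0.01},
    "fixed_cluster": {"p_gain": 0.05, "p_clst": 1e-5},
    "fixed_cluster_ei": {"p_gain": 0.05, "p_clst_exc": 1e-5, "p_clst_inh": 1e-5},
}


def _fixed_setting(policy: str) -> CorrectionSetting:
    p = FIXED_P[policy]
    variant = {
        "fixed_gain": "gain",
        "fixed_gain_ei": "gain_ei",
        "fixed_cluster": "cluster",
        "fixed_cluster_ei": "cluster_ei",
    }[policy]
    return CorrectionSetting(variant=variant, **p)


@dataclass
class SelectionResult:
    """Per-policy test-half accuracies for one unit (mean over iterations)."""

    unit_id: str
    mean_accuracy: dict  # policy -> float
    per_iteration: dict  # policy -> (n_iter,) array
    best_settings: dict  # policy -> list[CorrectionSetting] per iteration


def _single_setting_prediction(
    sta: StrfEstimate,
    grids: SignificanceGrid,
    setting: CorrectionSetting,
    z: np.ndarray,
    factor: int,
    connectivity: int,
) -> np.ndarray:
    from .cluster import correct  # local import avoids cycle at module load

    corrected = correct(sta, setting, grids, connectivity=connectivity)
    drive = linear_drive(corrected.values, z)
    return _rebin_rect(drive, factor)


def analyze_unit(
    sta: StrfEstimate,
    grids: SignificanceGrid,
    env_val: StimulusEnvelope,
    trials: list[np.ndarray],
    policies: tuple[str, ...] = DEFAULT_POLICIES,
    n_iter: int = 10,
    chunk_s: float = 1.0,
    bin_s: float = 0.010,
    connectivity: int = 8,
    seed: int = 0,
    unit_id: str = "unit0",
) -> SelectionResult:
    """Evaluate raw, fixed-setting, and cross-validated best policies.

    Best-setting policies choose the argmax setting on the validation half
    of each split and report its accuracy on the test half; raw and fixed
    policies are scored on the same test halves.  An undefined test accuracy
    (e.g. an all-zero fixed-setting STRF) propagates as NaN for that
    iteration.
    """
    z = _mean_subtracted(env_val)
    factor = int(round(bin_s / env_val.dt))
    psth = compute_psth(trials, bin_s, env_val.duration)
    splits = make_cv_splits(env_val.duration, n_iter=n_iter, chunk_s=chunk_s, seed=seed)
    transient_bins = int(np.ceil(sta.window / bin_s - 1e-9))

    tables: dict[str, SettingTable] = {}
    single_rows: dict[str, np.ndarray] = {}
    for policy in policies:
        if policy.startswith("best_"):
            variant = policy[len("best_"):]
            if variant not in tables:
                tables[variant] = setting_predictions(
                    sta, grids, variant, env_val, bin_s=bin_s,
                    connectivity=connectivity, z=z,
                )
        elif policy == "raw":
            raw_drive = linear_drive(sta.values, z)
            single_rows["raw"] = _rebin_rect(raw_drive, factor)
        else:
            single_rows[policy] = _single_setting_prediction(
                sta, grids, _fixed_setting(policy), z, factor, connectivity
            )

    per_iter = {p: np.full(n_iter, np.nan) for p in policies}
    best_settings: dict[str, list] = {p: [] for p in policies if p.startswith("best_")}
    n = min(len(psth.rate), env_val.n_time // factor)
    resp = psth.rate[:n]

    for it, split in enumerate(splits):
        val_mask = _bin_mask(n, bin_s, transient_bins, split, "validation")
        test_mask = _bin_mask(n, bin_s, transient_bins, split, "test")
        for policy in policies:
            if policy.startswith("best_"):
                table = tables[policy[len("best_"):]]
                val_acc = _rowwise_pearson(
                    table.binned_pred[:, :n][:, val_mask], resp[val_mask]
                )
                try:
                    best = select_best(table, val_acc)
                except NoValidSettingError:
                    best_settings[policy].append(None)
                    continue
                best_settings[policy].append(best)
                idx = table.settings.index(best)
                row = table.binned_pred[idx : idx + 1, :n]
                per_iter[policy][it] = _rowwise_pearson(
                    row[:, test_mask], resp[test_mask]
                )[0]
            else:
                row = single_rows[policy][None, :n]
                per_iter[policy][it] = _rowwise_pearson(
                    row[:, test_mask], resp[test_mask]
                )[0]

    mean_acc = {
        p: float(np.nanmean(v)) if np.isfinite(v).any() else float("nan")
        for p, v in per_iter.items()
    }
    return SelectionResult(
        unit_id=unit_id,
        mean_accuracy=mean_acc,
        per_iteration=per_iter,
        best_settings=best_settings,
    )


def evaluate_population(results: list[SelectionResult]) -> dict:
    """Population summary: mean, SEM and percent improvement per policy.

    Percent improvement applies the published formula to the population mean
    accuracies relative to the raw STA.
    """
    if not results:
        raise InvalidParameterError("need at least one unit")
    policies = list(results[0].mean_accuracy.keys())
    summary: dict[str, dict] = {}
    raw_mean = None
    for policy in policies:
        vals = np.array([r.mean_accuracy[policy] for r in results])
        ok = np.isfinite(vals)
        mean = float(vals[ok].mean()) if ok.any() else float("nan")
        sem = (
            float(vals[ok].std(ddof=1) / np.sqrt(ok.sum())) if ok.sum() > 1 else float("nan")
        )
        summary[policy] = {"mean": mean, "sem": sem, "n": int(ok.sum())}
        if policy == "raw":
            raw_mean = mean
    if raw_mean is not None and np.isfinite(raw_mean) and raw_mean != 0:
        for policy in policies:
            summary[policy]["pct_improvement"] = percent_improvement(
                summary[policy]["mean"], raw_mean
            )
    return summary
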