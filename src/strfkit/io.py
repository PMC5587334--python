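"""File formats: spike CSVs, envelope/STRF HDF5, grids and run configs.

Desk-scale plain formats rather than neurophysiology containers: spikes as
CSV (one row per spike, 6-decimal seconds), envelopes and STRFs as HDF5
with axis datasets and scalar attributes, fitted significance grids as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields

import h5py
import numpy as np
import pandas as pd
import yaml

from .dmr import StimulusEnvelope
from .exceptions import InvalidParameterError
from .lnp import SpikeData
from .nulls import ClusterNullFit, GainNullFit, SignificanceGrid, make_p_grid
from .sta import StrfEstimate

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "spike_data_from_frame",
    "write_envelope_h5",
    "read_envelope_h5",
    "write_strf_h5",
    "read_strf_h5",
    "write_grid_json",
    "read_grid_json",
    "write_prediction_csv",
    "write_modulation_h5",
    "read_modulation_h5",
    "RunConfig",
    "load_config",
]

SPIKE_COLUMNS = ["unit_id", "segment", "trial", "time_s"]


def write_spike_csv(path, spike_data: SpikeData | list[SpikeData]) -> None:
    """Write spike times (estimation + validation trials) to CSV."""
    units = spike_data if isinstance(spike_data, list) else [spike_data]
    rows = []
    for sd in units:
        for t in sd.estimation_spikes:
            rows.append((sd.unit_id, "est", 0, f"{t:.6f}"))
        for k, trial in enumerate(sd.validation_trials):
            for t in trial:
                rows.append((sd.unit_id, "val", k, f"{t:.6f}"))
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, index=False)


def read_spike_csv(path) -> pd.DataFrame:
    """Read a spike CSV, validating rows (errors carry the offending row)."""
    df = pd.read_csv(path, dtype={"unit_id": str, "segment": str})
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"spike CSV missing columns: {missing}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = df.index[times.isna()]
    if len(bad):
        raise InvalidParameterError(f"malformed time_s at row {int(bad[0]) + 2}")
    neg = df.index[times < 0]
    if len(neg):
        raise InvalidParameterError(f"negative spike time at row {int(neg[0]) + 2}")
    badseg = df.index[~df["segment"].isin(["est", "val"])]
    if len(badseg):
        raise InvalidParameterError(f"unknown segment label at row {int(badseg[0]) + 2}")
    df["time_s"] = times
    return df


def spike_data_from_frame(
    df: pd.DataFrame, unit_id: str, T_est: float, T_val: float
) -> SpikeData:
    """Assemble one unit's SpikeData from a spike table, checking ranges."""
    sub = df[df["unit_id"] == unit_id]
    est = np.sort(sub.loc[sub["segment"] == "est", "time_s"].to_numpy(float))
    if est.size and est.max() >= T_est:
        bad = sub.index[(sub["segment"] == "est") & (sub["time_s"] >= T_est)][0]
        raise InvalidParameterError(
            f"estimation spike beyond T_est={T_est} at row {int(bad) + 2}"
        )
    val = sub[sub["segment"] == "val"]
    trials = []
    if len(val):
        if val["time_s"].max() >= T_val:
            bad = val.index[val["time_s"] >= T_val][0]
            raise InvalidParameterError(
                f"validation spike beyond T_val={T_val} at row {int(bad) + 2}"
            )
        for k in range(int(val["trial"].max()) + 1):
            trials.append(
                np.sort(val.loc[val["trial"] == k, "time_s"].to_numpy(float))
            )
    return SpikeData(
        estimation_spikes=est, validation_trials=trials,
        T_est=T_est, T_val=T_val, unit_id=unit_id,
    )


def write_envelope_h5(path, env: StimulusEnvelope) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=env.values.astype(np.float32))
        f.create_dataset("freq_axis_oct", data=env.freq_axis)
        f.attrs["f_low_hz"] = env.f_low
        f.attrs["dt_s"] = env.dt
        f.attrs["mod_depth_db"] = env.mod_depth
        f.attrs["seed"] = -1 if env.seed is None else env.seed


def read_envelope_h5(path) -> StimulusEnvelope:
    with h5py.File(path, "r") as f:
        seed = int(f.attrs["seed"])
        return StimulusEnvelope(
            values=f["values"][...],
            freq_axis=f["freq_axis_oct"][...],
            dt=float(f.attrs["dt_s"]),
            f_low=float(f.attrs["f_low_hz"]),
            mod_depth=float(f.attrs["mod_depth_db"]),
            seed=None if seed < 0 else seed,
        )


def write_strf_h5(path, strf: StrfEstimate) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=strf.values)
        f.create_dataset("freq_axis_oct", data=strf.freq_axis)
        f.create_dataset("lag_axis_s", data=strf.lag_axis)
        f.attrs["n_spikes_used"] = strf.n_spikes_used
        f.attrs["correction_tag"] = strf.correction_tag
        for key, value in strf.p_settings.items():
            f.attrs[key] = value


def read_strf_h5(path) -> StrfEstimate:
    with h5py.File(path, "r") as f:
        reserved = {"n_spikes_used", "correction_tag"}
        p_settings = {
            k: float(v) for k, v in f.attrs.items() if k not in reserved
        }
        return StrfEstimate(
            values=f["values"][...],
            freq_axis=f["freq_axis_oct"][...],
            lag_axis=f["lag_axis_s"][...],
            n_spikes_used=int(f.attrs["n_spikes_used"]),
            correction_tag=str(f.attrs["correction_tag"]),
            p_settings=p_settings,
        )


def write_grid_json(path, grid: SignificanceGrid) -> None:
    """Serialize a fitted significance grid (p grid, normal, gammas)."""
    cluster = []
    for (level, scope), fit in sorted(grid.cluster_fits.items(), reverse=True):
        entry = {"gain_level": level, "sign_scope": scope, "available": fit is not None}
        if fit is not None:
            entry.update(
                shape=fit.shape, scale=fit.scale,
                n_clusters_sampled=fit.n_clusters_sampled,
            )
        cluster.append(entry)
    payload = {
        "p_values": grid.p_grid.p_values.tolist(),
        "retained_gain_levels": grid.p_grid.retained_gain_levels.tolist(),
        "gain_fit": {
            "mu": grid.gain_fit.mu,
            "sigma": grid.gain_fit.sigma,
            "n_samples": grid.gain_fit.n_samples,
        },
        "cluster_fits": cluster,
        "n_null": grid.n_null,
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def read_grid_json(path) -> SignificanceGrid:
    with open(path) as f:
        payload = json.load(f)
    g = payload["gain_fit"]
    grid = SignificanceGrid(
        p_grid=make_p_grid(),
        gain_fit=GainNullFit(mu=g["mu"], sigma=g["sigma"], n_samples=g["n_samples"]),
        n_null=payload.get("n_null", 0),
    )
    for entry in payload["cluster_fits"]:
        fit = None
        if entry["available"]:
            fit = ClusterNullFit(
                gain_level=entry["gain_level"],
                shape=entry["shape"],
                scale=entry["scale"],
                n_clusters_sampled=entry["n_clusters_sampled"],
                sign_scope=entry["sign_scope"],
            )
        grid.set_cluster_fit(entry["gain_level"], entry["sign_scope"], fit)
    return grid


def write_prediction_csv(path, rows: list[dict]) -> None:
    """Tidy prediction-accuracy table: one row per (unit, setting, bin)."""
    columns = ["unit_id", "correction_tag", "p_settings", "bin_s", "r",
               "n_spikes_used", "n_surviving_pixels"]
    df = pd.DataFrame(rows)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"prediction rows missing fields: {missing}")
    df[columns].to_csv(path, index=False, float_format="%.6f")


def write_modulation_h5(path, profile) -> None:
    """Store a ModulationProfile (RTF, marginals, classes, BMFs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("rtf", data=profile.rtf)
        f.create_dataset("temporal_freqs_hz", data=profile.temporal_freqs)
        f.create_dataset("spectral_freqs_cyc_per_oct", data=profile.spectral_freqs)
        f.create_dataset("tmtf", data=profile.tmtf)
        f.create_dataset("smtf", data=profile.smtf)
        for name in ("t_class", "s_class"):
            value = getattr(profile, name)
            if value is not None:
                f.attrs[name] = value
        for name in ("t_bmf", "s_bmf"):
            value = getattr(profile, name)
            if value is not None:
                f.attrs[name] = float(value)


def read_modulation_h5(path):
    from .modulation import ModulationProfile

    with h5py.File(path, "r") as f:
        return ModulationProfile(
            rtf=f["rtf"][...],
            temporal_freqs=f["temporal_freqs_hz"][...],
            spectral_freqs=f["spectral_freqs_cyc_per_oct"][...],
            tmtf=f["tmtf"][...],
            smtf=f["smtf"][...],
            t_class=str(f.attrs["t_class"]) if "t_class" in f.attrs else None,
            s_class=str(f.attrs["s_class"]) if "s_class" in f.attrs else None,
            t_bmf=float(f.attrs["t_bmf"]) if "t_bmf" in f.attrs else None,
            s_bmf=float(f.attrs["s_bmf"]) if "s_bmf" in f.attrs else None,
        )


@dataclass(frozen=True)
class RunConfig:
    """Flat key-value configuration of the end-to-end pipeline."""

    out_dir: str
    seed: int
    n_units: int = 10
    duration_est: float = 300.0
    duration_val: float = 30.0
    n_trials: int = 20
    dt: float = 0.001
    f_low: float = 50.0
    f_high: float = 40000.0
    freq_step: float = 0.05
    window: float = 0.200
    n_null: int = 200
    null_stride: int = 8
    baseline_rate: float = 8.0
    modulation: float = 0.7  # drive SD as a fraction of the baseline rate
    trial_jitter_sd: float = 0.2
    bin_s: float = 0.010
    chunk_s: float = 1.0
    n_cv_iter: int = 10
    connectivity: int = 8
    screen_units: bool = False

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        blob = json.dumps(
            {
                f.name: getattr(self, f.name)
                for f in fields(self)
                if f.name != "out_dir"
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a YAML run config; unknown keys and a missing seed are errors."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise InvalidParameterError("config must be a flat key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {unknown}")
    for required in ("seed", "out_dir"):
        if required not in raw:
            raise InvalidParameterError(f"config missing required key: {required!r}")
    return RunConfig(**raw)
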