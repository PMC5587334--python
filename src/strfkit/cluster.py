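"""Pixel-gain and cluster-mass thresholding of STRF estimates.

Correction only ever zeroes pixels; surviving pixels keep their raw values.
The single-step correction zeroes pixels whose gain falls inside the null
distribution at the chosen significance level.  The two-step correction then
groups the survivors into sign-pure connected components (excitatory =
positive, inhibitory = negative) and zeroes whole clusters whose summed
absolute gain (cluster mass) falls below the null cluster-mass cutoff.
Independent excitatory/inhibitory variants apply separate significance
levels to the two signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import InvalidParameterError
from .sta import StrfEstimate

__all__ = [
    "Cluster",
    "ClusterSet",
    "CorrectionSetting",
    "apply_gain_threshold",
    "label_clusters",
    "apply_cluster_threshold",
    "correct",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class Cluster:
    """One sign-pure connected component of gain-threshold survivors."""

    rows: np.ndarray
    cols: np.ndarray
    sign: str  # "exc" | "inh"
    mass: float  # summed |gain|

    @property
    def size(self) -> int:
        return len(self.rows)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    connectivity: int
    source_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.clusters)

    def masses(self, sign: str | None = None) -> np.ndarray:
        return np.array(
            [c.mass for c in self.clusters if sign is None or c.sign == sign]
        )


@dataclass(frozen=True)
class CorrectionSetting:
    """A correction variant plus its significance levels.

    ``variant`` is one of "gain", "gain_ei", "cluster", "cluster_ei".  Joint
    variants use ``p_gain`` (and ``p_clst``); the independent variants use
    the per-sign fields instead.
    """

    variant: str
    p_gain: float | None = None
    p_gain_exc: float | None = None
    p_gain_inh: float | None = None
    p_clst: float | None = None
    p_clst_exc: float | None = None
    p_clst_inh: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("gain", "gain_ei", "cluster", "cluster_ei"):
            raise InvalidParameterError(f"unknown variant {self.variant!r}")
        for name in ("p_gain", "p_gain_exc", "p_gain_inh",
                     "p_clst", "p_clst_exc", "p_clst_inh"):
            v = getattr(self, name)
            if v is not None and not (0.0 < v <= 1.0):
                raise InvalidParameterError(f"{name} must be in (0, 1], got {v!r}")

    def as_dict(self) -> dict:
        return {
            k: v
            for k, v in (
                ("p_gain", self.p_gain),
                ("p_gain_exc", self.p_gain_exc),
                ("p_gain_inh", self.p_gain_inh),
                ("p_clst", self.p_clst),
                ("p_clst_exc", self.p_clst_exc),
                ("p_clst_inh", self.p_clst_inh),
            )
            if v is not None
        }


def apply_gain_threshold(sta: StrfEstimate, lo: float, hi: float) -> StrfEstimate:
    """Zero pixels with ``lo < value < hi``; ties (== cutoff) survive.

    For the joint variant both cutoffs come from the same two-sided gain
    level; for the independent variant ``hi`` is the excitatory cutoff and
    ``lo`` the inhibitory one, each from its own level.
    """
    if lo > hi:
        raise InvalidParameterError(f"cutoff order violated: lo={lo} > hi={hi}")
    v = sta.values
    out = np.where((v <= lo) | (v >= hi), v, 0.0)
    return sta.copy_with(out, "gain", sta.p_settings)


def label_clusters(thresholded: StrfEstimate, connectivity: int = 8) -> ClusterSet:
    """Sign-pure connected components of the non-zero pixels.

    Positive and negative survivors are labeled separately, so a cluster
    never mixes excitatory and inhibitory pixels even when they touch.
    """
    if connectivity not in _STRUCTURES:
        raise InvalidParameterError("connectivity must be 4 or 8")
    structure = _STRUCTURES[connectivity]
    v = thresholded.values
    clusters: list[Cluster] = []
    for sign, mask in (("exc", v > 0), ("inh", v < 0)):
        labels, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        flat = labels.ravel()
        nz = np.flatnonzero(flat)
        order = nz[np.argsort(flat[nz], kind="stable")]
        boundaries = np.flatnonzero(np.diff(flat[order])) + 1
        for group in np.split(order, boundaries):
            rows, cols = np.unravel_index(group, v.shape)
            mass = float(np.abs(v[rows, cols]).sum())
            clusters.append(Cluster(rows=rows, cols=cols, sign=sign, mass=mass))
    return ClusterSet(
        clusters=clusters, connectivity=connectivity, source_shape=v.shape
    )


def apply_cluster_threshold(
    sta: StrfEstimate,
    clusters: ClusterSet,
    cutoff: float | None = None,
    cutoff_exc: float | None = None,
    cutoff_inh: float | None = None,
) -> StrfEstimate:
    """Zero clusters whose mass falls below the cutoff (mass >= cutoff survives).

    Pass ``cutoff`` for the joint variant, or ``cutoff_exc``/``cutoff_inh``
    to compare excitatory and inhibitory clusters against separate cutoffs.
    """
    if clusters.source_shape != sta.values.shape:
        raise InvalidParameterError("cluster set does not match STA shape")
    if cutoff is not None:
        cutoff_exc = cutoff_inh = cutoff
    if cutoff_exc is None or cutoff_inh is None:
        raise InvalidParameterError("provide cutoff, or both cutoff_exc and cutoff_inh")
    out = np.zeros_like(sta.values)
    for cl in clusters.clusters:
        c = cutoff_exc if cl.sign == "exc" else cutoff_inh
        if cl.mass >= c:
            out[cl.rows, cl.cols] = sta.values[cl.rows, cl.cols]
    return sta.copy_with(out, "cluster", sta.p_settings)


def correct(
    sta: StrfEstimate,
    setting: CorrectionSetting,
    grids,
    connectivity: int = 8,
) -> StrfEstimate:
    """Apply a correction setting using a unit's fitted significance grid.

    ``grids`` is a :class:`~strfkit.nulls.SignificanceGrid` (or anything with
    its ``gain_cutoffs`` / ``cluster_mass_cutoff`` interface).  The corrected
    STA is tagged with the variant and the applied p settings; ``p = 1`` for
    a pure gain variant returns the raw STA unchanged.
    """
    variant = setting.variant
    if variant == "gain":
        p = setting.p_gain
        if p is None:
            raise InvalidParameterError("gain variant requires p_gain")
        if p >= 1.0:
            return sta.copy_with(sta.values.copy(), "raw", {"p_gain": 1.0})
        lo, hi = grids.gain_cutoffs(p)
        out = apply_gain_threshold(sta, lo, hi)
        return out.copy_with(out.values, "gain", setting.as_dict())

    if variant == "gain_ei":
        pe, pi = setting.p_gain_exc, setting.p_gain_inh
        if pe is None or pi is None:
            raise InvalidParameterError("gain_ei variant requires p_gain_exc and p_gain_inh")
        _, hi = grids.gain_cutoffs(pe)
        lo, _ = grids.gain_cutoffs(pi)
        if pe >= 1.0:
            hi = -np.inf  # every positive pixel survives
        if pi >= 1.0:
            lo = np.inf  # every negative pixel survives
        v = sta.values
        out_vals = np.where(((v > 0) & (v >= hi)) | ((v < 0) & (v <= lo)), v, 0.0)
        return sta.copy_with(out_vals, "gain_ei", setting.as_dict())

    if variant == "cluster":
        pg, pc = setting.p_gain, setting.p_clst
        if pg is None or pc is None:
            raise InvalidParameterError("cluster variant requires p_gain and p_clst")
        lo, hi = grids.gain_cutoffs(pg)
        thr = apply_gain_threshold(sta, lo, hi)
        clusters = label_clusters(thr, connectivity=connectivity)
        cutoff = grids.cluster_mass_cutoff(pg, pc, scope="both")
        out = apply_cluster_threshold(thr, clusters, cutoff=cutoff)
        return out.copy_with(out.values, "cluster", setting.as_dict())

    # cluster_ei
    pg = setting.p_gain
    pce, pci = setting.p_clst_exc, setting.p_clst_inh
    if pg is None or pce is None or pci is None:
        raise InvalidParameterError(
            "cluster_ei variant requires p_gain, p_clst_exc and p_clst_inh"
        )
    lo, hi = grids.gain_cutoffs(pg)
    thr = apply_gain_threshold(sta, lo, hi)
    clusters = label_clusters(thr, connectivity=connectivity)
    cutoff_exc = grids.cluster_mass_cutoff(pg, pce, scope="exc")
    cutoff_inh = grids.cluster_mass_cutoff(pg, pci, scope="inh")
    out = apply_cluster_threshold(
        thr, clusters, cutoff_exc=cutoff_exc, cutoff_inh=cutoff_inh
    )
    return out.copy_with(out.values, "cluster_ei", setting.as_dict())
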