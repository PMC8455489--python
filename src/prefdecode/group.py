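"""Second-level inference: t-fields, random field theory FWE, clusters, ROIs.

Per-subject LONG > SHORT contrast images enter a voxelwise one-sample t
test (equivalent to the paired t test on the two condition estimates).
Voxel-level family-wise error control uses the expected Euler
characteristic of a t random field: p_FWE(t) ~ sum_d R_d * rho_d(t) with
resel counts R_0..R_3 of the search region and Worsley's closed-form EC
densities. Clusters are formed at an uncorrected voxel threshold
(p < 0.001) with a minimum spatial extent (270 mm^3), and retained
clusters are unioned into the decoding ROI mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special, stats

__all__ = [
    "GroupStatMap", "SmoothnessEstimate", "ClusterTable", "RoiMask",
    "one_sample_t", "estimate_smoothness", "resel_counts",
    "ec_density_t", "expected_ec", "rft_voxel_fwe", "extract_clusters",
    "clusters_to_roi", "dice",
]

_4LN2 = 4.0 * np.log(2.0)


@dataclass
class GroupStatMap:
    t_volume: np.ndarray          # 3-D
    df: int
    mask: np.ndarray              # 3-D boolean
    mean_volume: np.ndarray | None = None
    inf_voxels: int = 0           # zero-variance voxels set to signed inf


@dataclass
class SmoothnessEstimate:
    fwhm_mm: np.ndarray           # per axis
    fwhm_vox: np.ndarray          # per axis, in voxel units
    voxel_size_mm: np.ndarray
    resels: np.ndarray            # R_0..R_3


@dataclass
class RoiMask:
    mask: np.ndarray              # 3-D boolean union of retained clusters
    cluster_labels: np.ndarray    # 3-D int, 0 = background, 1..k per cluster
    provenance: dict = field(default_factory=dict)


ClusterTable = pd.DataFrame  # columns: size_vox, size_mm3, peak_*, peak_t, peak_p_fwe, survives_fwe


def one_sample_t(maps: np.ndarray, mask: np.ndarray) -> GroupStatMap:
    """Voxelwise one-sample t on stacked contrast volumes (N, nx, ny, nz).

    On difference images this is the paired t test between the collapsed
    conditions. Zero-variance voxels get signed-infinite t and are counted
    in ``inf_voxels``.
    """
    maps = np.asarray(maps, float)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = (sd == 0) & mask
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    t[zero_var & (mean == 0)] = 0.0
    t[~mask] = 0.0
    n_inf = int((zero_var & (mean != 0)).sum())
    return GroupStatMap(t, n - 1, np.asarray(mask, bool), mean, n_inf)


def estimate_smoothness(
    residual_maps: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float | tuple[float, float, float],
) -> SmoothnessEstimate:
    """Per-axis FWHM from spatial derivatives of normalised residuals.

    Residual maps (N, nx, ny, nz) are normalised voxelwise to unit sum of
    squares across maps; the variance of their forward differences along
    each axis estimates the roughness lambda_j, and
    FWHM_j = sqrt(4 ln 2 / lambda_j) (Kiebel/Worsley estimator). For
    white noise the estimator converges to sqrt(2 ln 2) ~ 1.18 voxels.
    """
    R = np.asarray(residual_maps, float)
    if R.ndim != 4 or R.shape[0] < 2:
        raise ValueError("need >= 2 residual maps of shape (N, nx, ny, nz)")
    mask = np.asarray(mask, bool)
    vs = np.broadcast_to(np.atleast_1d(np.asarray(voxel_size_mm, float)), (3,))
    ss = np.sqrt((R ** 2).sum(axis=0))
    ss[ss == 0] = np.inf
    U = R / ss
    lam = np.empty(3)
    for ax in range(3):
        d = np.diff(U, axis=ax + 1)
        m = (mask & np.roll(mask, -1, axis=ax))
        sl = [slice(None)] * 3
        sl[ax] = slice(0, mask.shape[ax] - 1)
        m = m[tuple(sl)]
        lam[ax] = float((d ** 2).sum(axis=0)[m].mean())
    fwhm_vox = np.sqrt(_4LN2 / lam)
    fwhm_mm = fwhm_vox * vs
    resels = resel_counts(mask, fwhm_vox)
    return SmoothnessEstimate(fwhm_mm, fwhm_vox, vs, resels)


def resel_counts(mask: np.ndarray, fwhm_vox: np.ndarray | float) -> np.ndarray:
    """Resolution-element counts R_0..R_3 of a binary search region.

    Counts points, edges, faces, and cubes of the voxel lattice inside the
    mask and converts them to resel units with r_j = 1 / FWHM_j (per-axis
    FWHM in voxels). For a solid box R_0 = 1 (Euler characteristic) and
    R_3 = volume in resels.
    """
    m = np.asarray(mask, bool)
    f = np.broadcast_to(np.atleast_1d(np.asarray(fwhm_vox, float)), (3,))
    rx, ry, rz = 1.0 / f
    P = int(m.sum())
    Ex = int((m[:-1] & m[1:]).sum())
    Ey = int((m[:, :-1] & m[:, 1:]).sum())
    Ez = int((m[:, :, :-1] & m[:, :, 1:]).sum())
    Fxy = int((m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:]).sum())
    Fxz = int((m[:-1, :, :-1] & m[1:, :, :-1] & m[:-1, :, 1:] & m[1:, :, 1:]).sum())
    Fyz = int((m[:, :-1, :-1] & m[:, 1:, :-1] & m[:, :-1, 1:] & m[:, 1:, 1:]).sum())
    C = int((m[:-1, :-1, :-1] & m[1:, :-1, :-1] & m[:-1, 1:, :-1]
             & m[:-1, :-1, 1:] & m[1:, 1:, :-1] & m[1:, :-1, 1:]
             & m[:-1, 1:, 1:] & m[1:, 1:, 1:]).sum())
    r0 = P - (Ex + Ey + Ez) + (Fxy + Fxz + Fyz) - C
    r1 = ((Ex - Fxy - Fxz + C) * rx + (Ey - Fxy - Fyz + C) * ry
          + (Ez - Fxz - Fyz + C) * rz)
    r2 = (Fxy - C) * rx * ry + (Fxz - C) * rx * rz + (Fyz - C) * ry * rz
    r3 = C * rx * ry * rz
    return np.array([r0, r1, r2, r3], float)


def ec_density_t(t: float | np.ndarray, df: int, dim: int) -> np.ndarray:
    """Euler characteristic density rho_d of a t field with ``df`` dof."""
    t = np.asarray(t, float)
    v = float(df)
    base = (1.0 + t ** 2 / v) ** (-(v - 1.0) / 2.0)
    if dim == 0:
        return stats.t.sf(t, df)
    if dim == 1:
        return np.sqrt(_4LN2) / (2.0 * np.pi) * base
    if dim == 2:
        c = np.exp(special.gammaln((v + 1.0) / 2.0)
                   - special.gammaln(v / 2.0)) / np.sqrt(v / 2.0)
        return _4LN2 / (2.0 * np.pi) ** 1.5 * c * t * base
    if dim == 3:
        return (_4LN2 ** 1.5 / (2.0 * np.pi) ** 2
                * base * ((v - 1.0) / v * t ** 2 - 1.0))
    raise ValueError("dim must be 0..3")


def expected_ec(t: float | np.ndarray, df: int, resels: np.ndarray) -> np.ndarray:
    """Expected Euler characteristic of the excursion set above ``t``."""
    return sum(resels[d] * ec_density_t(t, df, d) for d in range(4))


def rft_voxel_fwe(
    stat: GroupStatMap,
    smooth: SmoothnessEstimate,
    alpha: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Voxel-level FWE-corrected p volume and the critical threshold t_FWE.

    p_FWE(t) = min(1, E[EC at t], V * P(T > t)); the Bonferroni bound over
    the V in-mask voxels caps the expected-EC approximation, which can
    exceed it at low smoothness (SPM applies the same cap). t_FWE solves
    p_FWE = alpha by monotone root finding.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    resels = smooth.resels
    if not np.all(np.isfinite(resels)):
        raise ValueError("non-finite resel counts")
    n_vox = int(stat.mask.sum())

    def p_fwe_of(tv: np.ndarray) -> np.ndarray:
        ec = expected_ec(tv, stat.df, resels)
        bonf = n_vox * stats.t.sf(tv, stat.df)
        return np.minimum(1.0, np.maximum(np.minimum(ec, bonf), 0.0))

    t = stat.t_volume
    p = np.ones_like(t)
    inside = stat.mask
    p[inside] = p_fwe_of(np.where(np.isinf(t[inside]), 1e6, t[inside]))
    p[inside & np.isposinf(t)] = 0.0

    def f(x: float) -> float:
        return float(p_fwe_of(np.array([x]))[0]) - alpha

    # E[EC](t) is non-monotone at low t (the 3-D density is negative below
    # t ~ 1); root-find on the decreasing branch right of its maximum.
    ts = np.linspace(0.5, 12.0, 256)
    ec = p_fwe_of(ts)
    i0 = int(np.argmax(ec))
    if ec[i0] <= alpha:
        t_fwe = float(ts[0])  # whole curve below alpha: everything survives
    else:
        t_fwe = float(optimize.brentq(f, ts[i0], 100.0))
    return p, t_fwe


_CONN = {6: ndimage.generate_binary_structure(3, 1),
         18: ndimage.generate_binary_structure(3, 2),
         26: ndimage.generate_binary_structure(3, 3)}


def extract_clusters(
    stat: GroupStatMap,
    smooth: SmoothnessEstimate,
    cluster_p: float = 0.001,
    extent_mm3: float = 270.0,
    fwe_alpha: float = 0.05,
    connectivity: int = 18,
) -> tuple[ClusterTable, RoiMask]:
    """Suprathreshold clusters of the group t field.

    Voxels with uncorrected p < ``cluster_p`` form connected components
    (18-connectivity by default); components with volume >= ``extent_mm3``
    are kept, ordered by peak t (ties by lexicographic peak coordinate).
    Peak FWE p-values come from the expected-EC formula; a cluster
    ``survives_fwe`` when its peak p_FWE < ``fwe_alpha``.
    """
    if not (0 < cluster_p < 1):
        raise ValueError("cluster_p must be in (0, 1)")
    if connectivity not in _CONN:
        raise ValueError("connectivity must be 6, 18 or 26")
    vox_mm3 = float(np.prod(smooth.voxel_size_mm))
    t_unc = stats.t.isf(cluster_p, stat.df)
    supra = (stat.t_volume > t_unc) & stat.mask
    labels, n_comp = ndimage.label(supra, structure=_CONN[connectivity])
    p_fwe, t_fwe = rft_voxel_fwe(stat, smooth, fwe_alpha)

    rows, kept = [], []
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        size_vox = int(comp.sum())
        size_mm3 = size_vox * vox_mm3
        if size_mm3 < extent_mm3:
            continue
        tv = np.where(comp, stat.t_volume, -np.inf)
        flat_peak = np.argmax(tv)
        peak = np.unravel_index(flat_peak, tv.shape)
        # deterministic tie-break: smallest lexicographic coordinate at max t
        tmax = tv[peak]
        cand = np.argwhere(np.isclose(tv, tmax))
        peak = tuple(cand[np.lexsort(cand.T[::-1])][0])
        rows.append({
            "size_vox": size_vox, "size_mm3": size_mm3,
            "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2],
            "peak_t": float(stat.t_volume[peak]),
            "peak_p_fwe": float(p_fwe[peak]),
            "survives_fwe": bool(p_fwe[peak] < fwe_alpha),
        })
        kept.append(comp)

    order = sorted(
        range(len(rows)),
        key=lambda i: (-rows[i]["peak_t"], rows[i]["peak_i"],
                       rows[i]["peak_j"], rows[i]["peak_k"]))
    table = pd.DataFrame([rows[i] for i in order],
                         columns=["size_vox", "size_mm3", "peak_i", "peak_j",
                                  "peak_k", "peak_t", "peak_p_fwe",
                                  "survives_fwe"])
    cl_labels = np.zeros(stat.t_volume.shape, int)
    for new_id, i in enumerate(order, start=1):
        cl_labels[kept[i]] = new_id
    roi = RoiMask(cl_labels > 0, cl_labels, provenance={
        "cluster_p": cluster_p, "extent_mm3": extent_mm3,
        "fwe_alpha": fwe_alpha, "connectivity": connectivity,
        "t_uncorrected": float(t_unc), "t_fwe": t_fwe,
    })
    return table, roi


def clusters_to_roi(table: ClusterTable, roi: RoiMask,
                    mode: str = "all_clusters") -> RoiMask:
    """Union retained clusters into the decoding mask.

    ``all_clusters`` (default) keeps every cluster passing the extent rule;
    ``fwe_peaks_only`` restricts to clusters whose peak survives voxel FWE.
    """
    if mode not in ("all_clusters", "fwe_peaks_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(table) == 0:
        raise ValueError("no ROI available: cluster table is empty")
    keep = (np.arange(1, len(table) + 1) if mode == "all_clusters"
            else 1 + np.flatnonzero(table["survives_fwe"].to_numpy()))
    if keep.size == 0:
        raise ValueError("no ROI available: no cluster survives FWE")
    mask = np.isin(roi.cluster_labels, keep)
    labels = np.where(mask, roi.cluster_labels, 0)
    return RoiMask(mask, labels, {**roi.provenance, "mode": mode})


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else float("nan")
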