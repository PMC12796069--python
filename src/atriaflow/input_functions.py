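"""Image-derived input functions by cluster analysis of voxel TACs.

High-activity voxels (raw first-pass AUC above a percentile) are clustered
on amplitude-normalised TAC shape with k-means (default k = 6).  The venous
input C_RV is the mean TAC of the earliest-peaking high-AUC cluster (right
heart); the arterial input C_A is the highest-AUC cluster peaking at least
``min_av_lag_s`` later (left ventricle / aorta), with near-AUC ties broken
toward the latest peak so the left atrium is not mistaken for C_A.

A scalar lung timing reference t_lungs — needed by the atrial gates — is the
centroid of the cluster with intermediate AUC lying between the venous and
arterial centroids; when no cluster qualifies it falls back to the midpoint
of the two centroids (flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans, kmeans_plusplus

from .config import ClusterConfig, FirstPassConfig
from .errors import ParameterError, SegmentationError
from .firstpass import ParametricMaps, extract_first_pass_peak
from .imaging_io import DynamicSeries

__all__ = ["InputFunctions", "cluster_input_functions", "estimate_lung_tmid"]


@dataclass
class InputFunctions:
    """Arterial and venous input functions plus clustering by-products."""

    c_a: np.ndarray                     # kBq/mL, per frame
    c_rv: np.ndarray
    cluster_labels: np.ndarray          # per-candidate-voxel cluster index
    cluster_voxels: np.ndarray          # flat voxel indices of candidates (sorted)
    cluster_means: np.ndarray           # (k, n_frames) mean raw TACs
    arterial_cluster: int
    venous_cluster: int
    t_a: float                          # s, centroid of C_A first pass
    t_v: float                          # s, centroid of C_RV first pass
    peak_time_a: float                  # s, frame mid-time of the C_A maximum
    peak_time_v: float
    auc_a: float                        # kBq*s/mL, first-pass AUC of C_A
    t_lungs: float | None = None
    lung_cluster: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def arterial_voxels(self) -> np.ndarray:
        return self.cluster_voxels[self.cluster_labels == self.arterial_cluster]


def _cluster_summary(mean_tac, frame_start, frame_duration, fp_cfg):
    """(peak_time, t_mid, auc) of a cluster-mean TAC via first-pass metrics."""
    peak = extract_first_pass_peak(mean_tac, frame_start, frame_duration, fp_cfg)
    mids = np.asarray(frame_start) + 0.5 * np.asarray(frame_duration)
    peak_time = float(mids[int(np.argmax(mean_tac))])
    if peak is None:
        return peak_time, np.nan, 0.0
    return peak_time, peak.t_mid, peak.auc


def cluster_input_functions(
    series: DynamicSeries,
    maps: ParametricMaps,
    cfg: ClusterConfig | None = None,
    seed: int = 0,
    fp_cfg: FirstPassConfig | None = None,
) -> InputFunctions:
    """Derive C_A and C_RV from the dynamic series by TAC clustering."""
    cfg = cfg or ClusterConfig()
    fp_cfg = fp_cfg or FirstPassConfig()
    if cfg.k < 3:
        raise ParameterError("need at least 3 clusters to separate arterial/venous blood")

    det = maps.detected.reshape(-1)
    auc = maps.auc_raw.reshape(-1)
    det_idx = np.flatnonzero(det)
    if det_idx.size < cfg.k:
        raise SegmentationError(
            "too few peak-detected voxels for clustering",
            {"n_detected": int(det_idx.size)},
        )
    thresh = np.percentile(auc[det_idx], cfg.auc_percentile)
    cand = det_idx[auc[det_idx] >= thresh]          # sorted: canonical voxel order
    tacs = series.data.reshape(-1, series.n_frames)[cand].astype(float)
    amp = tacs.max(axis=1, keepdims=True)
    feats = tacs / np.maximum(amp, 1e-12)

    centers, _ = kmeans_plusplus(feats, n_clusters=cfg.k, random_state=int(seed) % (2**31))
    km = KMeans(n_clusters=cfg.k, init=centers, n_init=1, max_iter=cfg.max_iter)
    labels = km.fit_predict(feats)

    means = np.stack([tacs[labels == j].mean(axis=0) for j in range(cfg.k)])
    summaries = [
        _cluster_summary(means[j], series.frame_start, series.frame_duration, fp_cfg)
        for j in range(cfg.k)
    ]
    peak_times = np.array([s[0] for s in summaries])
    aucs = np.array([s[2] for s in summaries])

    high = aucs >= cfg.venous_auc_frac * aucs.max()
    venous = int(np.flatnonzero(high)[np.argmin(peak_times[high])])

    qualify = np.flatnonzero(peak_times >= peak_times[venous] + cfg.min_av_lag_s)
    qualify = qualify[aucs[qualify] > 0]
    if qualify.size == 0:
        raise SegmentationError(
            "no cluster satisfies the arterial lag criterion",
            {
                "venous_peak_s": float(peak_times[venous]),
                "cluster_peak_times_s": peak_times.tolist(),
                "cluster_aucs": aucs.tolist(),
            },
        )
    best = aucs[qualify].max()
    near = qualify[aucs[qualify] >= (1.0 - cfg.arterial_auc_tol) * best]
    arterial = int(near[np.argmax(peak_times[near])])

    def core_mean(j: int) -> np.ndarray:
        # hottest members only: partial-volume-diluted rim voxels depress the
        # input-function amplitude and contaminate its tail with tissue signal
        member = tacs[labels == j]
        amp = member.max(axis=1)
        return member[amp >= np.percentile(amp, cfg.core_percentile)].mean(axis=0)

    c_a = core_mean(arterial)
    c_rv = core_mean(venous)
    _, t_a, auc_a = _cluster_summary(c_a, series.frame_start, series.frame_duration, fp_cfg)
    _, t_v, _ = _cluster_summary(c_rv, series.frame_start, series.frame_duration, fp_cfg)

    inputs = InputFunctions(
        c_a=c_a,
        c_rv=c_rv,
        cluster_labels=labels,
        cluster_voxels=cand,
        cluster_means=means,
        arterial_cluster=arterial,
        venous_cluster=venous,
        t_a=t_a,
        t_v=t_v,
        peak_time_a=float(peak_times[arterial]),
        peak_time_v=float(peak_times[venous]),
        auc_a=float(auc_a),
        flags=[],
    )
    estimate_lung_tmid(inputs, series, cfg, fp_cfg)
    return inputs


def estimate_lung_tmid(
    inputs: InputFunctions,
    series: DynamicSeries,
    cfg: ClusterConfig | None = None,
    fp_cfg: FirstPassConfig | None = None,
) -> float:
    """Lung timing reference from the cluster set (stored on ``inputs``).

    Lung cluster: intermediate AUC (0.15-0.5 of the arterial AUC) whose
    first-pass centroid lies strictly between the venous and arterial
    centroids.  Fallback: midpoint of the two centroids, flagged.
    """
    cfg = cfg or ClusterConfig()
    fp_cfg = fp_cfg or FirstPassConfig()
    k = inputs.cluster_means.shape[0]
    counts = np.bincount(inputs.cluster_labels, minlength=k)
    best_j, best_count = None, -1
    for j in range(k):
        if j in (inputs.arterial_cluster, inputs.venous_cluster):
            continue
        _, t_mid, auc = _cluster_summary(
            inputs.cluster_means[j], series.frame_start, series.frame_duration, fp_cfg
        )
        rel = auc / inputs.auc_a if inputs.auc_a > 0 else 0.0
        if (
            cfg.lung_auc_min < rel < cfg.lung_auc_max
            and np.isfinite(t_mid)
            and inputs.t_v < t_mid < inputs.t_a
            and counts[j] > best_count
        ):
            best_j, best_count, best_t = j, counts[j], t_mid
    if best_j is None:
        inputs.t_lungs = 0.5 * (inputs.t_v + inputs.t_a)
        inputs.lung_cluster = None
        inputs.flags.append("lung_tmid_fallback")
    else:
        inputs.t_lungs = float(best_t)
        inputs.lung_cluster = best_j
    return inputs.t_lungs
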