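"""First-pass bolus analysis: per-voxel peak extraction, t_mid and AUC maps.

For every voxel the first transit of the injected bolus is isolated from its
time-activity curve (TAC), then summarised by two scalars: the centroid time

    t_mid = sum(t * C(t)) / sum(C(t))

(a bolus arrival-time surrogate) and the area under the peak (AUC, which for
blood voxels is proportional to local blood volume).  Stacked over the grid
these give the parametric images the chamber segmentation works on.  After
normalising AUC to the LV-cavity value, the blood pool is the region with
normalized AUC > 2/3 and t_mid below 1.5 min.

Peak isolation (the exact rule in the original tooling is unpublished): the
global maximum inside a search window (default first 120 s) is extended in
both directions until the TAC drops below ``peak_tail_frac`` of the maximum,
a local minimum below half-maximum is reached (recirculation cut), or the
window ends.  Centroids use frame mid-times weighted by frame duration so
the estimate does not depend on the (strongly non-uniform) framing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FirstPassConfig
from .errors import InputError, ParameterError, StateError
from .imaging_io import DynamicSeries

__all__ = [
    "FirstPassPeak",
    "ParametricMaps",
    "extract_first_pass_peak",
    "extract_peaks_batch",
    "peak_metrics",
    "compute_parametric_maps",
    "blood_mask",
]


@dataclass
class FirstPassPeak:
    """The isolated first-pass segment of one TAC."""

    frame_indices: np.ndarray     # contiguous indices into the schedule
    values: np.ndarray            # kBq/mL
    mid_times: np.ndarray         # s
    durations: np.ndarray         # s
    t_mid: float                  # s, duration-weighted centroid
    auc: float                    # kBq*s/mL


@dataclass
class ParametricMaps:
    """Voxel-wise t_mid / AUC images plus the no-peak flag.

    Voxels without a detectable peak carry NaN (flagged, not zero-filled).
    ``auc_norm`` appears once :meth:`normalize` has been called with the
    LV-cavity reference.
    """

    tmid: np.ndarray
    auc_raw: np.ndarray
    detected: np.ndarray
    auc_norm: np.ndarray | None = None
    auc_reference: float | None = None
    seg_lo: np.ndarray | None = field(default=None, repr=False)
    seg_hi: np.ndarray | None = field(default=None, repr=False)

    def normalize(self, auc_reference: float) -> None:
        """Scale the AUC image so the blood pool has normalized area 1."""
        if not np.isfinite(auc_reference) or auc_reference <= 0:
            raise ParameterError(f"invalid AUC reference {auc_reference}")
        self.auc_reference = float(auc_reference)
        self.auc_norm = self.auc_raw / self.auc_reference


def _batch_extract(tacs: np.ndarray, starts: np.ndarray, durs: np.ndarray, cfg: FirstPassConfig):
    """Vectorised peak extraction over N TACs; returns per-voxel arrays."""
    tacs = np.asarray(tacs, float)
    n, t = tacs.shape
    mids = starts + 0.5 * durs
    total = starts[-1] + durs[-1]

    in_window = mids < cfg.search_window_s
    if not in_window.any():
        in_window = np.zeros(t, bool)
        in_window[0] = True
    win_hi = int(np.max(np.nonzero(in_window)[0]))  # last frame index inside window

    masked = np.where(in_window[None, :], tacs, -np.inf)
    imax = np.argmax(masked, axis=1)
    peak = np.take_along_axis(tacs, imax[:, None], axis=1)[:, 0]

    # late-frame background: last part of the scan, but never the whole of a
    # short schedule (keep at least the final quarter)
    bg_start = max(total - cfg.background_window_s, 0.75 * total)
    bg_frames = mids >= bg_start
    if not bg_frames.any():
        bg_frames = np.zeros(t, bool)
        bg_frames[-1] = True
    background = np.clip(tacs[:, bg_frames], 0, None).mean(axis=1)
    threshold = np.maximum(cfg.min_peak_snr * background, cfg.min_peak_abs)
    detected = peak > threshold

    tail = cfg.peak_tail_frac * peak
    half = cfg.recirc_min_frac * peak

    # rightward extension from the maximum
    hi = imax.copy()
    active = detected.copy()
    stop_tail_r = np.zeros(n, bool)
    for _ in range(t):
        j = hi + 1
        can = active & (j <= win_hi)
        if not can.any():
            break
        jj = np.minimum(j, t - 1)
        vj = np.take_along_axis(tacs, jj[:, None], axis=1)[:, 0]
        vprev = np.take_along_axis(tacs, hi[:, None], axis=1)[:, 0]
        below = vj < tail
        locmin = (vj >= vprev) & (vprev < half)
        stop_tail_r |= can & below & ~locmin
        grow = can & ~below & ~locmin
        hi = np.where(grow, jj, hi)
        active = active & grow

    # leftward extension
    lo = imax.copy()
    active = detected.copy()
    stop_tail_l = np.zeros(n, bool)
    for _ in range(t):
        j = lo - 1
        can = active & (j >= 0)
        if not can.any():
            break
        jj = np.maximum(j, 0)
        vj = np.take_along_axis(tacs, jj[:, None], axis=1)[:, 0]
        vprev = np.take_along_axis(tacs, lo[:, None], axis=1)[:, 0]
        below = vj < tail
        locmin = (vj >= vprev) & (vprev < half)
        stop_tail_l |= can & below & ~locmin
        grow = can & ~below & ~locmin
        lo = np.where(grow, jj, lo)
        active = active & grow

    # the first sub-threshold frame at each end still holds bolus onset/tail
    # area (a frame averages the curve, so a "below 10%" frame is rarely
    # empty); include it unless the stop was the recirculation local minimum
    hi = np.where(stop_tail_r, np.minimum(hi + 1, win_hi), hi)
    lo = np.where(stop_tail_l, np.maximum(lo - 1, 0), lo)

    # duration-weighted centroid and AUC over the segment
    frame_idx = np.arange(t)
    seg = (frame_idx[None, :] >= lo[:, None]) & (frame_idx[None, :] <= hi[:, None])
    vals = np.clip(tacs, 0, None) * seg
    wsum = vals @ durs
    with np.errstate(invalid="ignore", divide="ignore"):
        tmid = (vals @ (mids * durs)) / wsum
    auc = wsum
    ok = detected & (wsum > 0)
    tmid = np.where(ok, tmid, np.nan)
    auc = np.where(ok, auc, np.nan)
    return ok, lo, hi, tmid, auc


def extract_peaks_batch(
    tacs: np.ndarray,
    frame_start: np.ndarray,
    frame_duration: np.ndarray,
    cfg: FirstPassConfig | None = None,
):
    """Peak extraction for an (N, n_frames) stack of TACs.

    Returns ``(detected, seg_lo, seg_hi, t_mid, auc)`` arrays of length N.
    """
    cfg = cfg or FirstPassConfig()
    tacs = np.atleast_2d(np.asarray(tacs, float))
    if tacs.shape[1] != np.asarray(frame_start).size:
        raise InputError("TAC length does not match the frame schedule")
    return _batch_extract(tacs, np.asarray(frame_start, float), np.asarray(frame_duration, float), cfg)


def extract_first_pass_peak(
    tac: np.ndarray,
    frame_start: np.ndarray,
    frame_duration: np.ndarray,
    cfg: FirstPassConfig | None = None,
) -> FirstPassPeak | None:
    """Isolate the first-pass segment of a single TAC (None if no peak)."""
    detected, lo, hi, tmid, auc = extract_peaks_batch(
        np.atleast_2d(tac), frame_start, frame_duration, cfg
    )
    if not detected[0]:
        return None
    idx = np.arange(int(lo[0]), int(hi[0]) + 1)
    mids = np.asarray(frame_start, float) + 0.5 * np.asarray(frame_duration, float)
    return FirstPassPeak(
        frame_indices=idx,
        values=np.asarray(tac, float)[idx],
        mid_times=mids[idx],
        durations=np.asarray(frame_duration, float)[idx],
        t_mid=float(tmid[0]),
        auc=float(auc[0]),
    )


def peak_metrics(peak: FirstPassPeak) -> tuple[float, float]:
    """(t_mid, AUC) of a peak segment: duration-weighted centroid and area."""
    vals = np.clip(peak.values, 0, None)
    w = vals * peak.durations
    if w.sum() <= 0:
        raise InputError("all-zero peak segment: centroid undefined")
    t_mid = float((peak.mid_times * w).sum() / w.sum())
    return t_mid, float(w.sum())


def compute_parametric_maps(series: DynamicSeries, cfg: FirstPassConfig | None = None) -> ParametricMaps:
    """Apply peak extraction + metrics to every voxel of a dynamic series.

    AUC normalisation is deferred until the LV-cavity reference is known
    (call :meth:`ParametricMaps.normalize`).
    """
    cfg = cfg or FirstPassConfig()
    shape = series.grid_shape
    flat = series.data.reshape(-1, series.n_frames)

    # cheap prefilter: voxels whose TAC never exceeds the absolute floor
    candidates = np.flatnonzero(flat.max(axis=1) > cfg.min_peak_abs)
    tmid = np.full(flat.shape[0], np.nan)
    auc = np.full(flat.shape[0], np.nan)
    det = np.zeros(flat.shape[0], bool)
    lo = np.zeros(flat.shape[0], np.int32)
    hi = np.zeros(flat.shape[0], np.int32)
    if candidates.size:
        d, l, h, tm, a = _batch_extract(
            flat[candidates], series.frame_start, series.frame_duration, cfg
        )
        det[candidates] = d
        lo[candidates] = l
        hi[candidates] = h
        tmid[candidates] = tm
        auc[candidates] = a
    return ParametricMaps(
        tmid=tmid.reshape(shape),
        auc_raw=auc.reshape(shape),
        detected=det.reshape(shape),
        seg_lo=lo.reshape(shape),
        seg_hi=hi.reshape(shape),
    )


def blood_mask(maps: ParametricMaps, cfg: FirstPassConfig | None = None) -> np.ndarray:
    """Blood region: normalized AUC > 2/3 and t_mid < 1.5 min, peak detected."""
    cfg = cfg or FirstPassConfig()
    if maps.auc_norm is None:
        raise StateError("AUC map not normalized yet: call ParametricMaps.normalize first")
    with np.errstate(invalid="ignore"):
        return (
            maps.detected
            & (maps.auc_norm > cfg.auc_blood_frac)
            & (maps.tmid < cfg.tmid_blood_max_s)
        )
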