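"""Atrial segmentation from the blood mask using bolus-timing gates.

Left atrium: starting from the blood mask (normalized AUC > 2/3), all
regions arriving later than the LV plus two heartbeats are dropped, as are
regions arriving before the lungs and everything inside the segmented left
ventricle.  What remains is LA plus aorta; the LV outflow tract axis is
extrapolated as a cylinder of growing radius until the candidate splits into
(at least) two sizeable components, and the earliest-arriving component is
the LA.

Right atrium: the mirrored rule gated on t_RV (no lung gate — the right
heart fills before the lungs), minus the right ventricle and the left-heart
labels.  The superior vena cava is removed by scanning axial slices from the
superior end: a run of consecutive slices whose cross-section is small and
circular (a tube) is labelled SVC.

Volumes are voxel counts times voxel volume; body-surface-area indexing
uses Du Bois (BSA = 0.007184 * weight^0.425 * height^0.725).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .config import AtriaConfig
from .errors import ParameterError, SegmentationError
from .chambers import ChamberStats

__all__ = [
    "VolumeReport",
    "segment_left_atrium",
    "segment_right_atrium",
    "atrial_volume_report",
    "du_bois_bsa",
]

_STRUCT26 = ndimage.generate_binary_structure(3, 3)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class VolumeReport:
    """Atrial volumes, BSA-indexed values and pipeline timing summary."""

    lav_ml: float
    rav_ml: float
    bsa_m2: float | None = None
    lavi_ml_m2: float | None = None
    ravi_ml_m2: float | None = None
    t_lv_s: float | None = None
    t_rv_s: float | None = None
    t_lungs_s: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "lav_ml": self.lav_ml,
            "rav_ml": self.rav_ml,
            "bsa_m2": self.bsa_m2,
            "lavi_ml_m2": self.lavi_ml_m2,
            "ravi_ml_m2": self.ravi_ml_m2,
            "t_lv_s": self.t_lv_s,
            "t_rv_s": self.t_rv_s,
            "t_lungs_s": self.t_lungs_s,
            "flags": ";".join(self.flags),
        }


def du_bois_bsa(height_cm: float, weight_kg: float) -> float:
    """Du Bois body surface area in m^2."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ParameterError("height and weight must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def _components(mask: np.ndarray):
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    return lab, n


def _line_distance(shape, spacing, point_mm, direction) -> np.ndarray:
    """Perpendicular distance (mm) of every voxel center to an infinite line."""
    sp = np.asarray(spacing, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)], indexing="ij")
    rel = [g - p for g, p in zip(grids, np.asarray(point_mm, float))]
    t = rel[0] * d[0] + rel[1] * d[1] + rel[2] * d[2]
    sq = sum((r - t * di) ** 2 for r, di in zip(rel, d))
    return np.sqrt(sq)


def segment_left_atrium(
    blood_mask: np.ndarray,
    tmid: np.ndarray,
    stats: ChamberStats,
    t_lungs: float,
    lv_interior: np.ndarray,
    lvot_point_mm: np.ndarray,
    lvot_direction: np.ndarray,
    spacing,
    cfg: AtriaConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(LA mask, aorta mask, flags) from the blood mask and timing gates."""
    cfg = cfg or AtriaConfig()
    spacing = np.asarray(spacing, float)
    voxvol_ml = float(np.prod(spacing)) / 1000.0
    beat = 60.0 / cfg.heart_rate_bpm

    with np.errstate(invalid="ignore"):
        candidate = (
            np.asarray(blood_mask, bool)
            & (tmid <= stats.t_lv + 2.0 * beat)
            & (tmid >= t_lungs)
            & ~ndimage.binary_dilation(np.asarray(lv_interior, bool), structure=_STRUCT6)
        )
    if not candidate.any():
        raise SegmentationError(
            "empty left-atrial candidate after timing gates",
            {"t_lv_s": stats.t_lv, "t_lungs_s": t_lungs, "gate_s": stats.t_lv + 2 * beat},
        )

    dist = _line_distance(candidate.shape, spacing, lvot_point_mm, lvot_direction)
    flags: list[str] = []
    radius = cfg.lvot_radius_start_mm
    la = aorta = None
    while radius <= cfg.lvot_radius_max_mm + 1e-9:
        remaining = candidate & (dist > radius)
        lab, n = _components(remaining)
        if n >= 2:
            sizes = np.bincount(lab.ravel())[1:] * voxvol_ml
            big = np.flatnonzero(sizes >= cfg.min_component_ml) + 1
            if big.size >= 2:
                med = [float(np.nanmedian(tmid[lab == j])) for j in big]
                la_label = int(big[int(np.argmin(med))])
                la = lab == la_label
                aorta = candidate & ~la
                break
        radius += cfg.lvot_radius_step_mm
    if la is None:
        la = candidate.copy()
        aorta = np.zeros_like(candidate)
        flags.append("la_aorta_split_failed")
    return la, aorta, flags


def _tube_like(slice_mask: np.ndarray, pixel_area_mm2: float, cfg: AtriaConfig) -> bool:
    n = int(slice_mask.sum())
    if n == 0:
        return False
    area_cm2 = n * pixel_area_mm2 / 100.0
    if area_cm2 >= cfg.tube_area_max_cm2:
        return False
    lab2, n2 = ndimage.label(slice_mask)
    sizes = np.bincount(lab2.ravel())[1:]
    biggest = lab2 == (int(np.argmax(sizes)) + 1)
    perim = measure.perimeter(biggest)
    if perim <= 0:
        return True  # single-pixel blob: trivially compact
    circularity = 4.0 * np.pi * float(biggest.sum()) / float(perim) ** 2
    return circularity > cfg.tube_circularity_min


def segment_right_atrium(
    blood_mask: np.ndarray,
    tmid: np.ndarray,
    stats: ChamberStats,
    rv_interior: np.ndarray,
    la_mask: np.ndarray,
    aorta_mask: np.ndarray,
    superior_direction: np.ndarray,
    spacing,
    cfg: AtriaConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(RA mask, SVC mask, flags): mirrored timing gate plus SVC tube removal.

    ``superior_direction`` (native world frame) defines which image axis and
    direction is scanned for the vena-cava tube; the basal long-axis
    direction from the reorientation serves, assuming a near-axial study.
    """
    cfg = cfg or AtriaConfig()
    spacing = np.asarray(spacing, float)
    beat = 60.0 / cfg.heart_rate_bpm

    with np.errstate(invalid="ignore"):
        candidate = (
            np.asarray(blood_mask, bool)
            & (tmid <= stats.t_rv + 2.0 * beat)
            & ~ndimage.binary_dilation(np.asarray(rv_interior, bool), structure=_STRUCT6)
            & ~np.asarray(la_mask, bool)
            & ~np.asarray(aorta_mask, bool)
        )
    if not candidate.any():
        raise SegmentationError(
            "empty right-atrial candidate after timing gates",
            {"t_rv_s": stats.t_rv, "gate_s": stats.t_rv + 2 * beat},
        )

    axis = int(np.argmax(np.abs(superior_direction)))
    sign = 1 if superior_direction[axis] >= 0 else -1
    in_plane = [i for i in range(3) if i != axis]
    pixel_area = float(spacing[in_plane[0]] * spacing[in_plane[1]])

    n_slices = candidate.shape[axis]
    order = range(n_slices - 1, -1, -1) if sign > 0 else range(n_slices)
    run: list[int] = []
    started = False
    for s in order:
        sl = np.take(candidate, s, axis=axis)
        if not sl.any():
            if started:
                break
            continue
        started = True
        if _tube_like(sl, pixel_area, cfg):
            run.append(s)
        else:
            break

    svc = np.zeros_like(candidate)
    flags: list[str] = []
    if len(run) >= cfg.tube_min_slices:
        sl_idx = [slice(None)] * 3
        for s in run:
            sl_idx[axis] = s
            svc[tuple(sl_idx)] = np.take(candidate, s, axis=axis)
    remaining = candidate & ~svc
    lab, n = _components(remaining)
    if n == 0:
        raise SegmentationError("right-atrial candidate vanished after SVC removal", {})
    sizes = np.bincount(lab.ravel())[1:]
    ra = lab == (int(np.argmax(sizes)) + 1)
    return ra, svc, flags


def atrial_volume_report(
    la_mask: np.ndarray,
    ra_mask: np.ndarray,
    spacing,
    height_cm: float | None,
    weight_kg: float | None,
    stats: ChamberStats | None = None,
    t_lungs: float | None = None,
    flags: list[str] | None = None,
) -> VolumeReport:
    """Mean atrial volumes (mL) with optional BSA indexing and QC flags."""
    spacing = np.asarray(spacing, float)
    voxvol_ml = float(np.prod(spacing)) / 1000.0
    lav = float(np.asarray(la_mask, bool).sum()) * voxvol_ml
    rav = float(np.asarray(ra_mask, bool).sum()) * voxvol_ml
    flags = list(flags or [])
    if lav == 0:
        flags.append("empty_la")
    if rav == 0:
        flags.append("empty_ra")

    bsa = lavi = ravi = None
    if height_cm is not None and weight_kg is not None:
        try:
            bsa = du_bois_bsa(height_cm, weight_kg)
            lavi = lav / bsa
            ravi = rav / bsa
        except ParameterError:
            flags.append("invalid_height_weight")
    return VolumeReport(
        lav_ml=lav,
        rav_ml=rav,
        bsa_m2=bsa,
        lavi_ml_m2=lavi,
        ravi_ml_m2=ravi,
        t_lv_s=stats.t_lv if stats else None,
        t_rv_s=stats.t_rv if stats else None,
        t_lungs_s=t_lungs,
        flags=flags,
    )
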