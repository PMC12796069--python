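"""End-to-end orchestration: dynamic series in, chamber volumes out.

Stage order: first-pass parametric maps -> input-function clustering ->
kinetic parametric maps -> short-axis reorientation -> ventricular
myocardium and cavities -> AUC normalisation to AUC_LV -> blood mask ->
atrial segmentation -> volume report.  The AUC image is normalised twice:
provisionally to the arterial-cluster AUC (the LV-cavity reference does
not exist before the ventricles are segmented), then finally to AUC_LV.

Everything is deterministic given the configuration (which carries the
clustering seed); a structured log records each stage's key scalars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atria, chambers, firstpass, input_functions, kinetics, phantom, stats
from .config import PipelineConfig
from .errors import SegmentationError
from .imaging_io import LABEL_CODES, DynamicSeries, save_outputs

__all__ = ["PipelineResult", "run_pipeline", "run_test_retest"]


@dataclass
class PipelineResult:
    """All products of one pipeline run."""

    report: atria.VolumeReport
    labels: np.ndarray
    maps: firstpass.ParametricMaps
    kmaps: kinetics.KineticMaps
    inputs: input_functions.InputFunctions
    chamber_stats: chambers.ChamberStats
    transform: chambers.ShortAxisTransform
    masks: dict[str, np.ndarray]
    log: list[dict] = field(default_factory=list)
    config_hash: str = ""

    def save(self, series: DynamicSeries, out_dir: str | Path) -> None:
        maps = {
            "tmid_s": np.nan_to_num(self.maps.tmid, nan=-1.0),
            "auc_norm": np.nan_to_num(self.maps.auc_norm, nan=-1.0),
            "mbf": np.nan_to_num(self.kmaps.mbf),
            "ptf": np.nan_to_num(self.kmaps.ptf),
            "v_a": np.nan_to_num(self.kmaps.v_a),
            "v_rv": np.nan_to_num(self.kmaps.v_rv),
        }
        save_outputs(self.labels, maps, self.report, series.voxel_size, out_dir)
        log_path = Path(out_dir) / "log.jsonl"
        log_path.write_text("".join(json.dumps(e) + "\n" for e in self.log))


def _assemble_labels(masks: dict[str, np.ndarray], shape) -> np.ndarray:
    labels = np.zeros(shape, np.int16)
    # blood structures take precedence over myocardium at overlaps
    order = [
        "lv_cavity", "rv_cavity", "left_atrium", "right_atrium",
        "aorta", "svc", "lv_myocardium", "rv_myocardium",
    ]
    for name in order:
        mask = masks.get(name)
        if mask is not None:
            labels[(labels == 0) & mask] = LABEL_CODES[name]
    return labels


def run_pipeline(series: DynamicSeries, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full segmentation pipeline on a dynamic series."""
    cfg = config or PipelineConfig()
    log: list[dict] = []

    def note(stage: str, **kv):
        log.append({"stage": stage, **{k: _jsonable(v) for k, v in kv.items()}})

    maps = firstpass.compute_parametric_maps(series, cfg.firstpass)
    n_det = int(maps.detected.sum())
    note("firstpass", n_detected=n_det)
    if n_det == 0:
        raise SegmentationError("no voxel shows a first-pass peak", {"n_detected": 0})

    inputs = input_functions.cluster_input_functions(
        series, maps, cfg.clustering, seed=cfg.seed, fp_cfg=cfg.firstpass
    )
    note("input_functions", t_v=inputs.t_v, t_a=inputs.t_a, t_lungs=inputs.t_lungs,
         flags=inputs.flags)

    basis = kinetics.build_basis(
        inputs.c_a, inputs.c_rv, series.frame_start, series.frame_duration, cfg.kinetics
    )
    kmaps = kinetics.fit_parametric_maps(series, basis, maps.detected, cfg.kinetics)
    note("kinetics", n_fitted=int(kmaps.fitted.sum()))

    # provisional blood mask from the arterial-cluster AUC; refined below
    maps.normalize(inputs.auc_a)
    blood_prov = firstpass.blood_mask(maps, cfg.firstpass)

    transform = chambers.reorient_short_axis(kmaps, series.voxel_size, cfg.chambers)
    note("reorient", long_axis=transform.long_axis_native.tolist())

    ptf_sa = transform.to_short_axis(np.nan_to_num(kmaps.ptf))
    va_sa = transform.to_short_axis(np.nan_to_num(kmaps.v_a))
    vrv_sa = transform.to_short_axis(np.nan_to_num(kmaps.v_rv))
    blood_sa = transform.to_short_axis(blood_prov.astype(float), order=0) > 0.5

    lv_myo_sa = chambers.segment_myocardium(ptf_sa, va_sa, series.voxel_size, cfg.chambers)
    rv_myo_sa = chambers.segment_myocardium(
        ptf_sa, vrv_sa, series.voxel_size, cfg.chambers, threshold=cfg.chambers.v_rv_threshold
    )
    (lv_cav_sa, lv_int_sa), (rv_cav_sa, rv_int_sa) = chambers.extract_cavities(
        lv_myo_sa, rv_myo_sa, blood_sa, series.voxel_size, cfg.chambers
    )
    if not lv_cav_sa.any() or not rv_cav_sa.any():
        raise SegmentationError(
            "cavity extraction produced an empty ventricular cavity",
            {"lv_voxels": int(lv_cav_sa.sum()), "rv_voxels": int(rv_cav_sa.sum())},
        )

    masks = {
        "lv_myocardium": chambers._mask_to_native(transform, lv_myo_sa),
        "rv_myocardium": chambers._mask_to_native(transform, rv_myo_sa),
        "lv_cavity": chambers._mask_to_native(transform, lv_cav_sa),
        "rv_cavity": chambers._mask_to_native(transform, rv_cav_sa),
    }
    lv_interior = chambers._mask_to_native(transform, lv_int_sa)
    rv_interior = chambers._mask_to_native(transform, rv_int_sa)

    cstats = chambers.chamber_stats(series, masks["lv_cavity"], masks["rv_cavity"], cfg.firstpass)
    note("chambers", t_lv=cstats.t_lv, t_rv=cstats.t_rv,
         auc_lv=cstats.auc_lv, auc_rv=cstats.auc_rv)

    # final normalisation to AUC_LV and the definitive blood mask
    maps.normalize(cstats.auc_lv)
    blood = firstpass.blood_mask(maps, cfg.firstpass)

    # LVOT axis: LV-cavity centroid through the basal-most cavity slice centroid
    sp = np.asarray(series.voxel_size, float)
    cav_idx = np.argwhere(lv_cav_sa)
    cav_centroid_sa = cav_idx.mean(axis=0) * sp
    basal_z = cav_idx[:, 2].max()
    basal_sl = cav_idx[cav_idx[:, 2] == basal_z]
    basal_centroid_sa = basal_sl.mean(axis=0) * sp
    d_sa = basal_centroid_sa - cav_centroid_sa
    if np.linalg.norm(d_sa) < 1e-6:
        d_sa = np.array([0.0, 0.0, 1.0])
    lvot_point = transform.point_to_native(basal_centroid_sa)
    lvot_dir = transform.direction_to_native(d_sa / np.linalg.norm(d_sa))

    la, aorta_mask, la_flags = atria.segment_left_atrium(
        blood, maps.tmid, cstats, inputs.t_lungs, lv_interior,
        lvot_point, lvot_dir, series.voxel_size, cfg.atria,
    )
    ra, svc, ra_flags = atria.segment_right_atrium(
        blood, maps.tmid, cstats, rv_interior, la, aorta_mask,
        transform.long_axis_native, series.voxel_size, cfg.atria,
    )
    masks.update({"left_atrium": la, "right_atrium": ra, "aorta": aorta_mask, "svc": svc})
    note("atria", la_ml=float(la.sum()) * series.voxel_volume_ml,
         ra_ml=float(ra.sum()) * series.voxel_volume_ml, flags=la_flags + ra_flags)

    labels = _assemble_labels(masks, series.grid_shape)
    # expose the disjoint label partition (blood labels win myocardium overlaps,
    # and the two ventricular walls share the septum before this step)
    masks = {name: labels == code for name, code in LABEL_CODES.items()}
    report = atria.atrial_volume_report(
        la, ra, series.voxel_size, cfg.height_cm, cfg.weight_kg,
        stats=cstats, t_lungs=inputs.t_lungs,
        flags=inputs.flags + la_flags + ra_flags,
    )
    note("report", **{k: v for k, v in report.to_dict().items()})
    return PipelineResult(
        report=report,
        labels=labels,
        maps=maps,
        kmaps=kmaps,
        inputs=inputs,
        chamber_stats=cstats,
        transform=transform,
        masks=masks,
        log=log,
        config_hash=cfg.config_hash(),
    )


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def run_test_retest(
    n_pairs: int = 20,
    seed: int = 0,
    config: PipelineConfig | None = None,
    grid_n: int = 64,
    voxel_mm: float = 3.0,
    noise_scale: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, stats.RepeatabilityStats]]:
    """Paired noisy-phantom experiment mirroring a same-day test-retest study.

    Synthetic subjects span a wide atrial-size range (linear scale factors
    0.90-1.15, i.e. >50% volume spread); each subject is imaged twice with
    independent noise.  Returns the per-subject volume table and the
    repeatability statistics of LAV and RAV.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    cfg = config or PipelineConfig()
    base = phantom.default_phantom_spec(
        grid_n=grid_n, voxel_mm=voxel_mm, noise_scale=noise_scale
    )
    la_scales = np.linspace(0.90, 1.15, n_pairs)
    ra_scales = la_scales[::-1].copy()
    ss = np.random.SeedSequence(seed)
    rows = []
    failures = 0
    for i in range(n_pairs):
        spec_i = phantom.subject_spec(base, la_scales[i], ra_scales[i], seed=0)
        rec = {"subject": i, "la_scale": la_scales[i], "ra_scale": ra_scales[i]}
        ok = True
        for rep, tag in ((0, "test"), (1, "retest")):
            child = ss.spawn(1)[0]
            noise_seed = int(child.generate_state(1)[0] % (2**31))
            s = phantom.subject_spec(base, la_scales[i], ra_scales[i], seed=noise_seed)
            series, truth = phantom.generate_phantom(s)
            try:
                res = run_pipeline(series, cfg)
            except SegmentationError:
                ok = False
                failures += 1
                break
            rec[f"lav_{tag}"] = res.report.lav_ml
            rec[f"rav_{tag}"] = res.report.rav_ml
            rec[f"lav_true_{tag}"] = truth.volumes_ml["left_atrium"]
        if ok:
            rows.append(rec)
    frame = pd.DataFrame(rows)
    frame.attrs["n_failures"] = failures
    out = {}
    for which in ("lav", "rav"):
        pairs = stats.PairedMeasurements(
            frame["subject"].to_numpy(),
            frame[f"{which}_test"].to_numpy(),
            frame[f"{which}_retest"].to_numpy(),
        )
        out[which] = stats.repeatability_stats(pairs)
    return frame, out
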