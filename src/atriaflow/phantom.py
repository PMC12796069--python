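"""Digital 4D cardiac first-pass phantom.

Generates a dynamic PET series with known chamber geometry, bolus transit
timing and myocardial kinetics, emulating a 6-minute resting O-15 water
acquisition reconstructed into the standard 22-frame schedule.  The tracer
bolus passes SVC -> RA -> RV -> lungs -> LA -> LV -> aorta with distinct
arrival times; each blood structure carries a gamma-variate first-pass curve

    C(t) = A * ((t - t0) / (alpha*beta))**alpha * exp(alpha - (t - t0)/beta)

(peak value A at t0 + alpha*beta, analytic centroid t0 + beta*(alpha + 1))
plus a delayed, dispersed, low-amplitude recirculation copy.  Myocardial
shells follow the single-tissue compartment forward model driven by the LV
curve (arterial) and the RV curve (venous spillover).  An isotropic Gaussian
PSF emulates reconstructed resolution; optional multiplicative Gaussian
noise scales with sqrt(value / frame duration), mimicking the variance
decrease with frame length.

Default geometry (96**3 grid, 2 mm voxels, 192 mm FOV) places prolate
ventricles with their long axis along z (configurable global rotation),
enlarged atria sized after the patient cohorts the method targets
(LAV ~ 70 mL, RAV ~ 84 mL), paired lung ellipsoids, a tilted ascending
aorta leaving the LV outflow tract and an SVC tube entering the RA roof.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter

from .errors import GeometryError, ParameterError, ScheduleError
from .imaging_io import DynamicSeries, default_frame_schedule, save_dynamic_series, save_volume
from .kinetics import fine_time_grid, simulate_tissue_tac

__all__ = [
    "BolusParams",
    "TissueParams",
    "Structure",
    "PhantomSpec",
    "GroundTruth",
    "bolus_curve",
    "structure_curve",
    "frame_average",
    "default_phantom_spec",
    "generate_phantom",
    "write_phantom",
]

#: Ground-truth label codes (superset of the output labels: lungs are 9).
TRUTH_CODES = {
    "lv_myocardium": 1,
    "rv_myocardium": 2,
    "lv_cavity": 3,
    "rv_cavity": 4,
    "left_atrium": 5,
    "right_atrium": 6,
    "aorta": 7,
    "svc": 8,
    "lungs": 9,
}

#: Blood-pool structures (carry the bolus curve directly).
BLOOD_STRUCTURES = ("lv_cavity", "rv_cavity", "left_atrium", "right_atrium", "aorta", "svc")


@dataclass(frozen=True)
class BolusParams:
    """Gamma-variate first-pass bolus with a recirculation tail."""

    t0: float                  # s, arrival delay
    alpha: float               # unitless shape
    beta: float                # s, time scale
    amplitude: float           # kBq/mL, peak value
    recirc_frac: float = 0.15  # recirculation amplitude fraction
    recirc_delay_s: float = 30.0
    recirc_beta_scale: float = 2.0

    @property
    def centroid_s(self) -> float:
        """Analytic first-pass centroid t0 + beta*(alpha+1)."""
        return self.t0 + self.beta * (self.alpha + 1.0)


@dataclass(frozen=True)
class TissueParams:
    """Myocardial kinetic parameters of one shell."""

    mbf: float      # mL/g/min
    ptf: float      # g/mL
    v_a: float      # fraction
    v_rv: float     # fraction


@dataclass(frozen=True)
class Structure:
    """One geometric primitive: ellipsoid, ellipsoidal shell or cylinder.

    Coordinates are world mm (voxel index * spacing, 0-based).  Shells are
    the region between ``semi_axes_inner`` and ``semi_axes``; cylinders run
    from ``center`` along ``axis`` for ``length`` mm with ``radius`` mm.
    """

    name: str
    kind: str                                   # "ellipsoid" | "shell" | "cylinder"
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float] | None = None
    semi_axes_inner: tuple[float, float, float] | None = None
    axis: tuple[float, float, float] | None = None
    radius: float | None = None
    length: float | None = None

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Boolean membership for an (N, 3) array of world points (mm)."""
        c = np.asarray(self.center, float)
        d = pts - c
        if self.kind == "ellipsoid":
            s = np.asarray(self.semi_axes, float)
            return ((d / s) ** 2).sum(axis=1) <= 1.0
        if self.kind == "shell":
            so = np.asarray(self.semi_axes, float)
            si = np.asarray(self.semi_axes_inner, float)
            r_out = ((d / so) ** 2).sum(axis=1)
            r_in = ((d / si) ** 2).sum(axis=1)
            return (r_out <= 1.0) & (r_in > 1.0)
        if self.kind == "cylinder":
            a = np.asarray(self.axis, float)
            a = a / np.linalg.norm(a)
            t = d @ a
            radial = d - t[:, None] * a[None, :]
            return (t >= 0) & (t <= self.length) & ((radial**2).sum(axis=1) <= self.radius**2)
        raise GeometryError(f"unknown structure kind '{self.kind}'")

    def extent_points(self) -> np.ndarray:
        """Conservative bounding points used for the fits-in-grid check."""
        c = np.asarray(self.center, float)
        if self.kind in ("ellipsoid", "shell"):
            s = np.asarray(self.semi_axes, float)
            return np.stack([c - s, c + s])
        a = np.asarray(self.axis, float)
        a = a / np.linalg.norm(a)
        ends = np.stack([c, c + a * self.length])
        pad = self.radius * np.sqrt(np.clip(1.0 - a**2, 0.0, 1.0))  # tight AABB
        return np.stack([ends.min(axis=0) - pad, ends.max(axis=0) + pad])


@dataclass
class PhantomSpec:
    """Full phantom description; :func:`default_phantom_spec` builds one."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]           # mm
    structures: list[Structure]                      # precedence order
    bolus: dict[str, BolusParams]
    tissue: dict[str, TissueParams]
    frame_start: np.ndarray
    frame_duration: np.ndarray
    heart_rate_bpm: float = 60.0
    psf_fwhm_mm: float = 5.0
    noise_scale: float = 1.0
    rng_seed: int = 0
    rotation_deg: float = 0.0
    rotation_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def validate(self) -> None:
        if self.noise_scale < 0:
            raise ParameterError("noise_scale must be >= 0")
        try:
            from .imaging_io import validate_schedule

            validate_schedule(self.frame_start, self.frame_duration)
        except ScheduleError:
            raise
        t0 = {name: bp.t0 for name, bp in self.bolus.items()}
        order = [
            ("svc", "right_atrium"),
            ("right_atrium", "rv_cavity"),
            ("rv_cavity", "lungs"),
            ("lungs", "left_atrium"),
            ("left_atrium", "lv_cavity"),
            ("lv_cavity", "aorta"),
        ]
        strict = {("rv_cavity", "lungs"), ("lungs", "left_atrium"), ("left_atrium", "lv_cavity")}
        for a, b in order:
            if a in t0 and b in t0:
                if (a, b) in strict:
                    if not t0[a] < t0[b]:
                        raise ParameterError(f"bolus delay ordering violated: t0({a}) < t0({b})")
                elif not t0[a] <= t0[b]:
                    raise ParameterError(f"bolus delay ordering violated: t0({a}) <= t0({b})")
        fov = np.asarray(self.grid_shape) * np.asarray(self.voxel_size)
        rot = _rotation_matrix(self.rotation_deg, self.rotation_axis)
        center = fov / 2.0
        for s in self.structures:
            pts = (rot @ (s.extent_points() - center).T).T + center
            if (pts < -1e-6).any() or (pts > fov + 1e-6).any():
                raise GeometryError(f"structure '{s.name}' exceeds the grid")


@dataclass
class GroundTruth:
    """Known phantom truth used by tests and accuracy evaluation."""

    labels: np.ndarray                       # int codes per TRUTH_CODES
    codes: dict[str, int]
    volumes_ml: dict[str, float]             # voxel count x voxel volume
    centroid_times_s: dict[str, float]       # analytic first-pass centroids
    tissue: dict[str, TissueParams]
    voxel_size: tuple[float, float, float]
    long_axis: np.ndarray                    # unit vector, ventricular long axis
    basal_direction: np.ndarray              # unit vector toward atria/great vessels

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.codes[name]


def bolus_curve(t, t0: float, alpha: float, beta: float, amplitude: float) -> np.ndarray:
    """Gamma-variate bolus, zero before arrival; peak value = amplitude."""
    if alpha <= 0 or beta <= 0:
        raise ParameterError("alpha and beta must be positive")
    t = np.asarray(t, float)
    dt = np.clip(t - t0, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = amplitude * (dt / (alpha * beta)) ** alpha * np.exp(alpha - dt / beta)
    return np.where(t > t0, val, 0.0)


def structure_curve(t, bp: BolusParams) -> np.ndarray:
    """First-pass bolus plus its recirculation tail."""
    first = bolus_curve(t, bp.t0, bp.alpha, bp.beta, bp.amplitude)
    if bp.recirc_frac > 0:
        first = first + bolus_curve(
            t,
            bp.t0 + bp.recirc_delay_s,
            bp.alpha,
            bp.beta * bp.recirc_beta_scale,
            bp.amplitude * bp.recirc_frac,
        )
    return first


def frame_average(curve, frame_start, frame_duration, dt: float = 0.01) -> np.ndarray:
    """Mean of a continuous curve over each frame [start, start + dur).

    ``curve`` is a callable t -> activity; integration by trapezoid on a
    uniform ``dt`` grid (exact for linear curves).
    """
    frame_start = np.asarray(frame_start, float)
    frame_duration = np.asarray(frame_duration, float)
    from .imaging_io import validate_schedule

    validate_schedule(frame_start, frame_duration)
    end = frame_start[-1] + frame_duration[-1]
    t = fine_time_grid(end, dt)
    c = np.asarray(curve(t), float)
    cum = cumulative_trapezoid(c, dx=dt, initial=0.0)
    lo = np.rint(frame_start / dt).astype(int)
    hi = np.rint((frame_start + frame_duration) / dt).astype(int)
    return (cum[hi] - cum[lo]) / frame_duration


def _rotation_matrix(angle_deg: float, axis) -> np.ndarray:
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    th = np.deg2rad(angle_deg)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def default_phantom_spec(
    grid_n: int = 96,
    voxel_mm: float = 2.0,
    noise_scale: float = 1.0,
    psf_fwhm_mm: float = 5.0,
    seed: int = 0,
    rotation_deg: float = 0.0,
    rotation_axis=(1.0, 0.0, 0.0),
    la_scale: float = 1.0,
    ra_scale: float = 1.0,
) -> PhantomSpec:
    """Standard thorax phantom in a 192 mm field of view.

    ``grid_n * voxel_mm`` should equal 192 (96 x 2 mm, 64 x 3 mm, ...);
    other FOVs scale the structure centers proportionally while keeping
    absolute structure sizes.  ``la_scale`` / ``ra_scale`` scale the atrial
    semi-axes (used to spread atrial size across synthetic subjects).
    """
    fov = grid_n * voxel_mm
    f = fov / 192.0

    def c(x, y, z):
        return (x * f, y * f, z * f)

    la_ax = tuple(v * la_scale for v in (27.0, 24.0, 26.0))
    ra_ax = tuple(v * ra_scale for v in (30.0, 28.0, 24.0))
    structures = [
        Structure("lv_cavity", "ellipsoid", c(96, 66, 78), semi_axes=(21.0, 21.0, 30.0)),
        Structure("rv_cavity", "ellipsoid", c(96, 124, 76), semi_axes=(22.0, 22.0, 28.0)),
        Structure("left_atrium", "ellipsoid", c(96, 38, 138), semi_axes=la_ax),
        Structure("right_atrium", "ellipsoid", c(96, 120, 135), semi_axes=ra_ax),
        Structure(
            "aorta", "cylinder", c(96, 66, 114),
            axis=(0.0, 0.4226, 0.9063), radius=11.0, length=56.0,
        ),
        Structure("svc", "cylinder", c(96, 118, 152), axis=(0.0, 0.0, 1.0), radius=9.0, length=34.0),
        Structure(
            "lv_myocardium", "shell", c(96, 66, 78),
            semi_axes=(31.0, 31.0, 40.0), semi_axes_inner=(21.0, 21.0, 30.0),
        ),
        Structure(
            "rv_myocardium", "shell", c(96, 124, 76),
            semi_axes=(28.0, 28.0, 34.0), semi_axes_inner=(22.0, 22.0, 28.0),
        ),
        Structure("lungs", "ellipsoid", c(38, 96, 110), semi_axes=(26.0, 42.0, 58.0)),
        Structure("lungs", "ellipsoid", c(154, 96, 110), semi_axes=(26.0, 42.0, 58.0)),
    ]
    blood_amp = 80.0  # kBq/mL peak, typical first-pass blood activity
    bolus = {
        "svc": BolusParams(4.0, 3.0, 2.5, blood_amp),
        "right_atrium": BolusParams(6.0, 3.0, 2.5, blood_amp),
        "rv_cavity": BolusParams(8.0, 3.0, 2.5, blood_amp),
        "lungs": BolusParams(11.0, 3.0, 3.0, 17.0),
        "left_atrium": BolusParams(16.5, 3.0, 2.5, blood_amp),
        "lv_cavity": BolusParams(20.0, 3.0, 2.5, blood_amp),
        "aorta": BolusParams(20.5, 3.0, 2.5, blood_amp),
    }
    tissue = {
        "lv_myocardium": TissueParams(mbf=0.9, ptf=0.60, v_a=0.15, v_rv=0.05),
        "rv_myocardium": TissueParams(mbf=0.9, ptf=0.55, v_a=0.05, v_rv=0.20),
    }
    starts, durs = default_frame_schedule()
    return PhantomSpec(
        grid_shape=(grid_n, grid_n, grid_n),
        voxel_size=(voxel_mm, voxel_mm, voxel_mm),
        structures=structures,
        bolus=bolus,
        tissue=tissue,
        frame_start=starts,
        frame_duration=durs,
        psf_fwhm_mm=psf_fwhm_mm,
        noise_scale=noise_scale,
        rng_seed=seed,
        rotation_deg=rotation_deg,
        rotation_axis=rotation_axis,
    )


def voxelize(spec: PhantomSpec) -> np.ndarray:
    """Integer label volume (TRUTH_CODES) with precedence-ordered assignment.

    Earlier structures in ``spec.structures`` win overlaps, which guarantees
    pairwise-disjoint masks after voxelization.
    """
    shape = spec.grid_shape
    sp = np.asarray(spec.voxel_size, float)
    fov = np.asarray(shape) * sp
    center = fov / 2.0
    rot = _rotation_matrix(spec.rotation_deg, spec.rotation_axis)

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    pts = np.stack([ii.ravel() * sp[0], jj.ravel() * sp[1], kk.ravel() * sp[2]], axis=1)
    # evaluate unrotated geometry in the body frame
    body = (rot.T @ (pts - center).T).T + center

    labels = np.zeros(int(np.prod(shape)), np.int16)
    for s in spec.structures:
        code = TRUTH_CODES[s.name]
        lo = np.asarray(s.extent_points()).min(axis=0) - 1
        hi = np.asarray(s.extent_points()).max(axis=0) + 1
        box = np.flatnonzero(
            (labels == 0)
            & (body[:, 0] >= lo[0]) & (body[:, 0] <= hi[0])
            & (body[:, 1] >= lo[1]) & (body[:, 1] <= hi[1])
            & (body[:, 2] >= lo[2]) & (body[:, 2] <= hi[2])
        )
        if box.size:
            inside = s.contains(body[box])
            labels[box[inside]] = code
    return labels.reshape(shape)


def generate_phantom(spec: PhantomSpec) -> tuple[DynamicSeries, GroundTruth]:
    """Render the dynamic series and its ground truth.

    Identical spec (including ``rng_seed``) gives bit-identical output.
    """
    spec.validate()
    labels = voxelize(spec)
    sp = tuple(float(v) for v in spec.voxel_size)
    starts, durs = np.asarray(spec.frame_start, float), np.asarray(spec.frame_duration, float)
    n_frames = starts.size

    # continuous input curves for the kinetic forward model (no frame averaging)
    t_fine = fine_time_grid(starts[-1] + durs[-1], 0.1)
    ca_fine = structure_curve(t_fine, spec.bolus["lv_cavity"])
    crv_fine = structure_curve(t_fine, spec.bolus["rv_cavity"])

    tacs: dict[str, np.ndarray] = {}
    for name, bp in spec.bolus.items():
        tacs[name] = frame_average(lambda t: structure_curve(t, bp), starts, durs)
    for name, tp in spec.tissue.items():
        tacs[name] = simulate_tissue_tac(
            tp.mbf, tp.ptf, tp.v_a, tp.v_rv, t_fine, ca_fine, crv_fine, starts, durs
        )

    data = np.zeros(spec.grid_shape + (n_frames,), np.float32)
    for name, tac in tacs.items():
        mask = labels == TRUTH_CODES[name]
        if mask.any():
            data[mask] = tac.astype(np.float32)

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm / 2.354820045 / np.asarray(sp)
        for fidx in range(n_frames):
            data[..., fidx] = gaussian_filter(data[..., fidx], sigma=sigma_vox)

    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.rng_seed)
        for fidx in range(n_frames):
            frame = data[..., fidx]
            sd = spec.noise_scale * np.sqrt(np.clip(frame, 0, None) / durs[fidx])
            frame += (rng.standard_normal(frame.shape) * sd).astype(np.float32)

    series = DynamicSeries(data=data, voxel_size=sp, frame_start=starts, frame_duration=durs)

    voxvol = series.voxel_volume_ml
    volumes = {
        name: float((labels == code).sum()) * voxvol for name, code in TRUTH_CODES.items()
    }
    centroids = {name: bp.centroid_s for name, bp in spec.bolus.items()}
    rot = _rotation_matrix(spec.rotation_deg, spec.rotation_axis)
    truth = GroundTruth(
        labels=labels,
        codes=dict(TRUTH_CODES),
        volumes_ml=volumes,
        centroid_times_s=centroids,
        tissue=dict(spec.tissue),
        voxel_size=sp,
        long_axis=rot @ np.array([0.0, 0.0, 1.0]),
        basal_direction=rot @ np.array([0.0, 0.0, 1.0]),
    )
    return series, truth


def write_phantom(series: DynamicSeries, truth: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Persist a phantom: 4D series + timing sidecar + truth labels + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_dynamic_series(series, out / "series.nii.gz", out / "timing.json")
    save_volume(truth.labels, truth.voxel_size, out / "truth_labels.nii.gz", integer=True)
    meta = {
        "codes": truth.codes,
        "volumes_ml": truth.volumes_ml,
        "centroid_times_s": truth.centroid_times_s,
        "tissue": {k: vars(v) for k, v in truth.tissue.items()},
        "long_axis": truth.long_axis.tolist(),
        "basal_direction": truth.basal_direction.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(meta, indent=2) + "\n")
    return {
        "series": out / "series.nii.gz",
        "timing": out / "timing.json",
        "truth_labels": out / "truth_labels.nii.gz",
        "truth": out / "truth.json",
    }


def subject_spec(base: PhantomSpec, la_scale: float, ra_scale: float, seed: int) -> PhantomSpec:
    """A subject variant of ``base`` with rescaled atria and a new seed."""
    structures = []
    for s in base.structures:
        if s.name == "left_atrium":
            structures.append(replace(s, semi_axes=tuple(v * la_scale for v in s.semi_axes)))
        elif s.name == "right_atrium":
            structures.append(replace(s, semi_axes=tuple(v * ra_scale for v in s.semi_axes)))
        else:
            structures.append(s)
    return replace(base, structures=structures, rng_seed=seed)
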