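"""Synthetic study generator: phantoms, k-space motion corruption, raters.

The generator reproduces the statistical structure the agreement analysis
assumes, without any image download:

* **phantoms** -- nested smooth ellipsoids (scalp, skull, CSF, grey and
  white matter, ventricles) with preset tissue-intensity orderings for
  MP-RAGE-like and FLAIR-like contrast, a mild smooth intensity
  inhomogeneity, and Rician-like noise whose level varies from acquisition
  to acquisition.  The brain occupies well under 40% of the field of view,
  so background dominates the image as it does in brain MR.
* **motion** -- segment-wise rigid k-space corruption: the phase-encode
  axis is split into segments, the object is rigidly moved per segment, and
  each segment keeps its own lines of the Fourier transform of the moved
  object.  Trajectories are recentred on the segment that acquires the
  k-space centre, so the corrupted volume stays co-registered with its
  reference (bulk shifts become ghosting, as in a registered study).
* **raters** -- a latent quality score decreasing linearly in motion
  severity, plus per-rater bias and noise (radiographers noisier than
  radiologists), rounded and clipped to the 1-5 Likert range.

All randomness derives from one master seed through ``numpy``'s
``SeedSequence`` spawning, so a study is reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .agreement import RatingTable
from .volume import BrainMask, Volume

__all__ = [
    "CONTRAST_PRESETS",
    "MotionTrajectory",
    "StudyConfig",
    "SyntheticStudy",
    "make_phantom",
    "make_trajectory",
    "corrupt_with_motion",
    "add_ghost",
    "add_rician_noise",
    "add_wrap_band",
    "simulate_raters",
    "build_study",
    "inject_outliers",
    "study_with_outliers",
]

# Tissue intensity ratios (white matter = 1 for the T1-weighted preset).
CONTRAST_PRESETS = {
    "MPRAGE": {"scalp": 0.55, "skull": 0.10, "csf": 0.15, "gm": 0.60, "wm": 1.00},
    "FLAIR": {"scalp": 0.45, "skull": 0.10, "csf": 0.10, "gm": 1.00, "wm": 0.55},
}

# Effective head radius (mm) converting rotations into mean displacement.
R_EFF_MM = 64.0


def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    return ((x - center[0]) / semi[0]) ** 2 + ((y - center[1]) / semi[1]) ** 2 \
        + ((z - center[2]) / semi[2]) ** 2 <= 1.0


def make_phantom(shape: Sequence[int] = (64, 64, 64), contrast: str = "MPRAGE",
                 seed: int = 0, noise_sd: float = 0.02,
                 voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
                 geometry_jitter: float = 0.0,
                 volume_id: str = "phantom",
                 noise_seed: Optional[int] = None) -> tuple[Volume, BrainMask]:
    """Deterministic brain-like phantom and its binary brain mask.

    ``noise_sd`` is the Rician noise level relative to the brightest tissue;
    ``geometry_jitter`` scales a per-seed random perturbation of the
    ellipsoid axes, providing subject-to-subject anatomy variation.
    ``noise_seed`` decouples the noise realization from the anatomy seed, so
    repeated acquisitions of the same subject carry independent noise.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError(f"phantom shape must be >= 32 per dimension, got {shape}")
    if contrast not in CONTRAST_PRESETS:
        raise ValueError(f"unknown contrast preset {contrast!r}")
    tint = CONTRAST_PRESETS[contrast]
    rng = np.random.default_rng(seed)

    jit = 1.0 + geometry_jitter * rng.uniform(-1.0, 1.0, size=3)
    cshift = geometry_jitter * rng.uniform(-0.05, 0.05, size=3)
    coords = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")

    def semi(base):
        return tuple(b * j for b, j in zip(base, jit))

    def center(base=(0.0, 0.0, 0.0)):
        return tuple(b + c for b, c in zip(base, cshift))

    img = np.zeros(shape)
    img[_ellipsoid(coords, center(), semi((0.85, 0.95, 0.90)))] = tint["scalp"]
    img[_ellipsoid(coords, center(), semi((0.80, 0.90, 0.85)))] = tint["skull"]
    img[_ellipsoid(coords, center(), semi((0.74, 0.84, 0.79)))] = tint["csf"]
    # the brain mask includes a thin subarachnoid CSF rim, as skull-stripped
    # masks do, so the mask boundary falls on dark CSF rather than cortex
    brain = _ellipsoid(coords, center(), semi((0.70, 0.80, 0.75)))
    img[brain] = tint["csf"]
    img[_ellipsoid(coords, center(), semi((0.66, 0.76, 0.71)))] = tint["gm"]
    img[_ellipsoid(coords, center(), semi((0.54, 0.66, 0.60)))] = tint["wm"]
    # deep grey nuclei and lateral ventricles; their size varies strongly
    # between subjects (atrophy / ventricle variability)
    vjit = rng.uniform(0.5, 1.6)
    njit = rng.uniform(0.6, 1.4)
    for sx in (-0.20, 0.20):
        img[_ellipsoid(coords, center((sx, -0.08, 0.0)),
                       tuple(njit * s for s in semi((0.10, 0.12, 0.12))))] = tint["gm"]
    for sx in (-0.12, 0.12):
        img[_ellipsoid(coords, center((sx, 0.10, 0.05)),
                       tuple(vjit * s for s in semi((0.07, 0.22, 0.10))))] = tint["csf"]

    # gyrification-like texture inside the brain: a coarse multiplicative
    # component for anatomy variation and a fine additive component
    # (near-voxel correlation length, vessels/trabeculae) supplying the
    # high-frequency detail that motion blur destroys
    coarse = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    coarse /= max(coarse[brain].std(), 1e-12)
    fine = ndimage.gaussian_filter(rng.standard_normal(shape), 0.65)
    fine /= max(fine[brain].std(), 1e-12)
    img[brain] *= 1.0 + 0.06 * coarse[brain]
    img[brain] += 0.08 * fine[brain]
    img = np.maximum(img, 0.0)

    img = ndimage.gaussian_filter(img, 0.7)  # partial-volume smoothing

    bias = ndimage.gaussian_filter(rng.standard_normal(shape), 12.0)
    bias /= max(np.abs(bias).max(), 1e-12)
    img *= 1.0 + 0.08 * bias

    if noise_sd > 0:
        nrng = rng if noise_seed is None else np.random.default_rng(noise_seed)
        n1 = nrng.normal(0.0, noise_sd, shape)
        n2 = nrng.normal(0.0, noise_sd, shape)
        img = np.sqrt((img + n1) ** 2 + n2 ** 2)

    vol = Volume(data=img, slice_axis=2, voxel_size=tuple(voxel_size), id=volume_id)
    return vol, BrainMask(data=brain.astype(np.uint8))


@dataclass(frozen=True)
class MotionTrajectory:
    """Piecewise-constant rigid motion over the phase-encode axis.

    ``segments`` are half-open ``(start, stop)`` line ranges that must cover
    the phase-encode axis exactly once.  Translations are in mm, rotations
    in degrees (about the volume centre).  ``severity`` summarises the
    trajectory as the segment-length-weighted mean displacement in mm,
    counting a rotation of theta as a displacement of ``r_eff * theta``.
    """

    translations_mm: np.ndarray   # (S, 3)
    rotations_deg: np.ndarray     # (S, 3)
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.translations_mm, dtype=float))
        r = np.atleast_2d(np.asarray(self.rotations_deg, dtype=float))
        object.__setattr__(self, "translations_mm", t)
        object.__setattr__(self, "rotations_deg", r)
        s = len(self.segments)
        if t.shape != (s, 3) or r.shape != (s, 3):
            raise ValueError("need one (3 translation, 3 rotation) set per segment")

    def validate_coverage(self, n_lines: int) -> None:
        segs = sorted(self.segments)
        if segs[0][0] != 0 or segs[-1][1] != n_lines:
            raise ValueError(f"segments must cover [0, {n_lines}) exactly")
        for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
            if a1 != b0:
                raise ValueError("segments must tile the phase-encode axis "
                                 "without gaps or overlaps")

    def severity(self, r_eff_mm: float = R_EFF_MM) -> float:
        disp = (np.linalg.norm(self.translations_mm, axis=1)
                + r_eff_mm * np.deg2rad(np.linalg.norm(self.rotations_deg, axis=1)))
        weights = np.array([b - a for a, b in self.segments], dtype=float)
        return float((disp * weights).sum() / weights.sum())

    def recentred(self, centre_line: int) -> "MotionTrajectory":
        """Express all positions relative to the k-space-centre segment."""
        for i, (a, b) in enumerate(self.segments):
            if a <= centre_line < b:
                return MotionTrajectory(
                    self.translations_mm - self.translations_mm[i],
                    self.rotations_deg - self.rotations_deg[i],
                    self.segments)
        raise ValueError(f"no segment contains line {centre_line}")


def make_trajectory(severity: float, n_lines: int, n_segments: int = 8,
                    seed: int = 0, r_eff_mm: float = R_EFF_MM) -> MotionTrajectory:
    """Random-walk rigid trajectory scaled to a requested mean displacement.

    The walk is recentred on the segment acquiring the k-space centre (the
    subject's reference position) before scaling, so the returned
    trajectory's :meth:`~MotionTrajectory.severity` equals ``severity``.
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    bounds = np.linspace(0, n_lines, n_segments + 1).astype(int)
    segments = tuple((int(a), int(b)) for a, b in zip(bounds, bounds[1:]))
    if severity == 0:
        zeros = np.zeros((n_segments, 3))
        return MotionTrajectory(zeros, zeros.copy(), segments)
    rng = np.random.default_rng(seed)
    trans = np.cumsum(rng.normal(0.0, 1.0, (n_segments, 3)), axis=0)
    # raw rotation steps chosen so rotational displacement is comparable
    rot = np.cumsum(rng.normal(0.0, np.rad2deg(1.0 / r_eff_mm),
                               (n_segments, 3)), axis=0)
    traj = MotionTrajectory(trans, rot, segments).recentred(n_lines // 2)
    raw = traj.severity(r_eff_mm)
    if raw == 0:  # pragma: no cover - vanishing random walk
        raise RuntimeError("degenerate random walk; use a different seed")
    f = severity / raw
    return MotionTrajectory(traj.translations_mm * f, traj.rotations_deg * f,
                            segments)


def _rigid_transform(data: np.ndarray, translation_mm: np.ndarray,
                     rotation_deg: np.ndarray,
                     voxel_size: Sequence[float]) -> np.ndarray:
    """Rigidly move the object (rotation about centre, then translation).

    Trilinear interpolation, zero padding outside the field of view.
    """
    if not translation_mm.any() and not rotation_deg.any():
        return data
    ax, ay, az = np.deg2rad(rotation_deg)
    rx = np.array([[1, 0, 0],
                   [0, math.cos(ax), -math.sin(ax)],
                   [0, math.sin(ax), math.cos(ax)]])
    ry = np.array([[math.cos(ay), 0, math.sin(ay)],
                   [0, 1, 0],
                   [-math.sin(ay), 0, math.cos(ay)]])
    rz = np.array([[math.cos(az), -math.sin(az), 0],
                   [math.sin(az), math.cos(az), 0],
                   [0, 0, 1]])
    rot = rz @ ry @ rx
    t_vox = np.asarray(translation_mm, dtype=float) / np.asarray(voxel_size, dtype=float)
    centre = (np.array(data.shape) - 1) / 2.0
    rot_inv = rot.T
    offset = centre - rot_inv @ (centre + t_vox)
    return ndimage.affine_transform(data, rot_inv, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def corrupt_with_motion(v: Volume, traj: MotionTrajectory,
                        phase_axis: int = 0) -> Volume:
    """Composite k-space from segment-wise rigidly moved copies of a volume.

    Segments index fftshifted (linear-ordered) phase-encode lines, so the
    k-space centre sits at line ``n // 2``.  The output is the magnitude of
    the inverse transform of the composited k-space.
    """
    n_lines = v.data.shape[phase_axis]
    traj.validate_coverage(n_lines)
    composite = np.zeros(v.data.shape, dtype=complex)
    for i, (a, b) in enumerate(traj.segments):
        moved = _rigid_transform(v.data, traj.translations_mm[i],
                                 traj.rotations_deg[i], v.voxel_size)
        k = np.fft.fftshift(np.fft.fftn(moved), axes=phase_axis)
        sel = [slice(None)] * 3
        sel[phase_axis] = slice(a, b)
        composite[tuple(sel)] = k[tuple(sel)]
    out = np.abs(np.fft.ifftn(np.fft.ifftshift(composite, axes=phase_axis)))
    return v.with_data(out)


def add_ghost(v: Volume, amplitude: float, phase_axis: int = 0,
              source: Optional[np.ndarray] = None,
              smear_sigma: float = 0.0,
              shift: Optional[int] = None) -> Volume:
    """Superimpose a half-FOV (N/2-type) ghost replica along the phase axis.

    Such ghosts arise from reconstruction imperfections and pulsatile
    signal (gradient timing, parallel imaging, flowing blood, scalp fat)
    with an amplitude unrelated to subject motion; they land mostly in the
    image background and are the kind of nuisance that contaminates metrics
    evaluated without a brain mask.  ``source`` optionally restricts the
    ghosted signal (e.g. to the bright fat/scalp ring, the classic ghost
    source); by default the whole image ghosts.
    """
    if amplitude < 0:
        raise ValueError("ghost amplitude must be >= 0")
    src = v.data if source is None else v.data * source
    if smear_sigma > 0:
        # pulsatile ghosts are temporally modulated, which smears them
        # along the phase-encode direction
        src = ndimage.gaussian_filter1d(src, smear_sigma, axis=phase_axis)
    if shift is None:
        shift = v.data.shape[phase_axis] // 2
    return v.with_data(v.data + amplitude * np.roll(src, shift, axis=phase_axis))


def _scalp_gain_field(clean: np.ndarray, mask: BrainMask,
                      gain: float) -> np.ndarray:
    """Smooth multiplicative field scaling the bright peripheral tissue.

    Coil loading and proximity change from one positioning to the next,
    modulating the scalp/fat brightness while leaving the head centre
    essentially unchanged.
    """
    scalp = (clean > 0.3) & ~mask.data
    w = ndimage.gaussian_filter(scalp.astype(float), 1.0)
    return 1.0 + (gain - 1.0) * w


def add_wrap_band(v: Volume, intensity: float, thickness: float,
                  edge: int = 0, phase_axis: int = 0, seed: int = 0) -> Volume:
    """Add a wrap-around (aliasing) band at one edge of the phase axis.

    Tissue outside the field of view along the phase-encode direction wraps
    to the opposite image edge; neck/shoulder wrap bands of varying
    brightness are ubiquitous in 3D brain acquisitions and live entirely in
    the background.
    """
    rng = np.random.default_rng(seed)
    n = v.data.shape[phase_axis]
    x = np.arange(n, dtype=float)
    centre = (thickness / 2.0) if edge == 0 else (n - 1 - thickness / 2.0)
    profile = np.exp(-0.5 * ((x - centre) / max(thickness / 2.0, 1e-6)) ** 2)
    # wrap bands are compact and never reach the head centre
    profile[np.abs(x - centre) > min(2.5 * thickness, 8.0)] = 0.0
    shape2d = [d for a, d in enumerate(v.data.shape) if a != phase_axis]
    envelope = ndimage.gaussian_filter(rng.random(shape2d), 4.0)
    envelope /= max(envelope.max(), 1e-12)
    # wrapped tissue is textured: give the band edge content of its own
    tex = ndimage.gaussian_filter(rng.standard_normal(shape2d), 1.0)
    tex /= max(tex.std(), 1e-12)
    envelope = envelope * np.clip(1.0 + 0.8 * tex, 0.0, None)
    # wrapped tissue stays at tissue-level brightness
    band = np.clip(intensity * np.tensordot(profile, envelope, axes=0), 0.0, 0.85)
    band = np.moveaxis(band, 0, phase_axis)
    # overlay rather than add, so band + scalp cannot exceed tissue range
    return v.with_data(np.maximum(v.data, band))


def add_rician_noise(v: Volume, noise_sd: float, seed: int = 0) -> Volume:
    """Rician magnitude noise, applied after motion/ghosting.

    Thermal noise enters the receive chain, so it is independent of subject
    motion and identically distributed over the whole field of view.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return v
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, noise_sd, v.data.shape)
    n2 = rng.normal(0.0, noise_sd, v.data.shape)
    return v.with_data(np.sqrt((v.data + n1) ** 2 + n2 ** 2))


def simulate_raters(severities: Sequence[float], volume_ids: Sequence[str],
                    n_radiologists: int = 2, n_radiographers: int = 2,
                    noise_sd: float = 0.3, radiographer_noise_factor: float = 1.6,
                    bias_sd: float = 0.2, slope: Optional[float] = None,
                    seed: int = 0) -> RatingTable:
    """Ordinal 1-5 scores from a severity-driven latent quality.

    The latent score is ``5 - slope * severity`` (slope calibrated so the
    worst volume in the batch lands near score 1), shifted by a per-rater
    bias and i.i.d. noise -- radiographers get ``radiographer_noise_factor``
    times the radiologists' noise, mirroring their smaller reading
    experience -- then rounded and clipped to {1..5}.
    """
    sev = np.asarray(list(severities), dtype=float)
    if (sev < 0).any():
        raise ValueError("severities must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if slope is None:
        slope = 4.0 / sev.max() if sev.max() > 0 else 0.0
    rng = np.random.default_rng(seed)
    raters, roles = [], {}
    for i in range(n_radiologists):
        raters.append(f"radiologist_{i + 1}")
        roles[raters[-1]] = "radiologist"
    for i in range(n_radiographers):
        raters.append(f"radiographer_{i + 1}")
        roles[raters[-1]] = "radiographer"
    latent = 5.0 - slope * sev
    scores = {}
    for r in raters:
        sd = noise_sd * (radiographer_noise_factor if roles[r] == "radiographer" else 1.0)
        bias = rng.normal(0.0, bias_sd) if bias_sd > 0 else 0.0
        noisy = latent + bias + (rng.normal(0.0, sd, sev.shape) if sd > 0 else 0.0)
        scores[r] = np.clip(np.round(noisy), 1, 5)
    table = pd.DataFrame(scores, index=list(volume_ids))
    table.index.name = "volume_id"
    return RatingTable(scores=table, roles=roles)


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the default synthetic study.

    22 subjects, one reference (no instructed motion) plus three
    motion-degraded acquisitions each, at 64^3 / 3 mm resolution.
    Instructed severities are a graded base ladder (mm mean displacement)
    jittered per subject.  Every acquisition -- references included --
    additionally carries a small involuntary (physiological) motion
    severity, a random reconstruction-ghost amplitude and its own thermal
    noise level, none of which depend on the instructed severity; these are
    the nuisance channels that contaminate metrics evaluated without a
    brain mask.
    """

    n_subjects: int = 22
    severities: tuple[float, ...] = (1.5, 3.5, 8.0)
    severity_jitter: float = 0.3
    involuntary_severity_range: tuple[float, float] = (0.2, 0.8)
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    sequence: str = "MPRAGE"
    n_segments: int = 8
    phase_axis: int = 0
    noise_sd_range: tuple[float, float] = (0.004, 0.007)
    ghost_amplitude_range: tuple[float, float] = (0.05, 0.25)
    ghost_smear_range: tuple[float, float] = (0.5, 4.0)
    scalp_gain_range: tuple[float, float] = (0.7, 1.3)
    wrap_intensity_range: tuple[float, float] = (0.0, 0.7)
    wrap_thickness_range: tuple[float, float] = (1.0, 3.0)
    geometry_jitter: float = 0.02
    n_radiologists: int = 2
    n_radiographers: int = 2
    rater_noise_sd: float = 0.3
    rater_bias_sd: float = 0.2


@dataclass
class SubjectRecord:
    subject_id: str
    reference: Volume
    mask: BrainMask
    degraded: list[Volume]
    severities: list[float]          # total (instructed + involuntary), mm
    reference_severity: float = 0.0  # involuntary motion of the reference


@dataclass
class SyntheticStudy:
    """A full synthetic cohort: volumes, masks and observer scores."""

    subjects: list[SubjectRecord]
    ratings: RatingTable
    config: StudyConfig
    seed: int

    @property
    def sequence(self) -> str:
        return self.config.sequence

    def table(self) -> pd.DataFrame:
        """Per-volume metadata (id, subject, condition, severity, is_reference)."""
        rows = []
        for sub in self.subjects:
            rows.append({"volume_id": sub.reference.id, "subject": sub.subject_id,
                         "sequence": self.sequence, "condition": 0,
                         "severity": sub.reference_severity, "is_reference": True})
            for k, (vol, sev) in enumerate(zip(sub.degraded, sub.severities), 1):
                rows.append({"volume_id": vol.id, "subject": sub.subject_id,
                             "sequence": self.sequence, "condition": k,
                             "severity": sev, "is_reference": False})
        return pd.DataFrame(rows)


def build_study(config: StudyConfig = StudyConfig(), seed: int = 0) -> SyntheticStudy:
    """Generate the full synthetic study from one master seed."""
    if not config.severities or any(s <= 0 for s in config.severities):
        raise ValueError("severity grid must be positive")
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(config.n_subjects)
    rater_seed = master.spawn(1)[0]

    subjects = []
    all_ids, all_sev = [], []
    for i, sseq in enumerate(subject_seeds):
        sid = f"sub-{i + 1:02d}"
        n_cond = len(config.severities)
        streams = sseq.spawn(4 + 3 * n_cond)
        s_int = [int(s.generate_state(1)[0] % (2 ** 31)) for s in streams]
        rng = np.random.default_rng(s_int[0])
        n_lines = config.shape[config.phase_axis]

        clean, mask = make_phantom(config.shape, config.sequence, seed=s_int[1],
                                    noise_sd=0.0, voxel_size=config.voxel_size,
                                    geometry_jitter=config.geometry_jitter,
                                    volume_id=f"{sid}_{config.sequence}_cond-0")
        ref_invol = rng.uniform(*config.involuntary_severity_range)
        ref = clean.with_data(clean.data * _scalp_gain_field(
            clean.data, mask, rng.uniform(*config.scalp_gain_range)))
        if ref_invol > 0:
            ref = corrupt_with_motion(
                ref, make_trajectory(ref_invol, n_lines, config.n_segments,
                                     seed=s_int[3]),
                phase_axis=config.phase_axis)
        ref_src = (ref.data > 0.1) & ~mask.data
        ref = add_ghost(ref, rng.uniform(*config.ghost_amplitude_range),
                        config.phase_axis, source=ref_src,
                        smear_sigma=rng.uniform(*config.ghost_smear_range))
        for _ in range(2):
            ref = add_wrap_band(ref, rng.uniform(*config.wrap_intensity_range),
                                rng.uniform(*config.wrap_thickness_range),
                                edge=int(rng.integers(2)),
                                phase_axis=config.phase_axis,
                                seed=int(rng.integers(2 ** 31)))
        ref = add_rician_noise(ref, rng.uniform(*config.noise_sd_range),
                               seed=s_int[2])
        degraded, severities = [], []
        for k, base_sev in enumerate(config.severities, 1):
            instructed = base_sev * rng.uniform(1 - config.severity_jitter,
                                                1 + config.severity_jitter)
            invol = rng.uniform(*config.involuntary_severity_range)
            acq = clean.with_data(clean.data * _scalp_gain_field(
                clean.data, mask, rng.uniform(*config.scalp_gain_range)))
            acq.id = f"{sid}_{config.sequence}_cond-{k}"
            t_instr = make_trajectory(instructed, n_lines, config.n_segments,
                                      seed=s_int[3 * k + 1])
            t_invol = make_trajectory(invol, n_lines, config.n_segments,
                                      seed=s_int[3 * k + 2])
            traj = MotionTrajectory(
                t_instr.translations_mm + t_invol.translations_mm,
                t_instr.rotations_deg + t_invol.rotations_deg,
                t_instr.segments)
            vol = corrupt_with_motion(acq, traj, phase_axis=config.phase_axis)
            vol_src = (vol.data > 0.1) & ~mask.data
            vol = add_ghost(vol, rng.uniform(*config.ghost_amplitude_range),
                            config.phase_axis, source=vol_src,
                            smear_sigma=rng.uniform(*config.ghost_smear_range))
            for _ in range(2):
                vol = add_wrap_band(
                    vol, rng.uniform(*config.wrap_intensity_range),
                    rng.uniform(*config.wrap_thickness_range),
                    edge=int(rng.integers(2)),
                    phase_axis=config.phase_axis,
                    seed=int(rng.integers(2 ** 31)))
            vol = add_rician_noise(vol, rng.uniform(*config.noise_sd_range),
                                   seed=s_int[3 * k + 3])
            degraded.append(vol)
            severities.append(traj.severity())
        subjects.append(SubjectRecord(sid, ref, mask, degraded, severities,
                                      reference_severity=ref_invol))
        all_ids.append(ref.id)
        all_sev.append(ref_invol)
        all_ids.extend(v.id for v in degraded)
        all_sev.extend(severities)

    ratings = simulate_raters(
        all_sev, all_ids, n_radiologists=config.n_radiologists,
        n_radiographers=config.n_radiographers, noise_sd=config.rater_noise_sd,
        bias_sd=config.rater_bias_sd,
        seed=int(rater_seed.generate_state(1)[0] % (2 ** 31)))
    return SyntheticStudy(subjects=subjects, ratings=ratings, config=config,
                          seed=seed)


def inject_outliers(v: Volume, fraction: float = 0.001,
                    magnitude_range: tuple[float, float] = (10.0, 100.0),
                    seed: int = 0) -> Volume:
    """Replace a small random voxel fraction with extreme intensities.

    The outlier magnitude is a random multiple of the volume maximum, so
    each volume's intensity ceiling moves by a different amount -- exactly
    the situation that derails min-max normalization while the percentile
    mapping clips it away.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    data = v.data.copy()
    n = max(1, int(round(fraction * data.size)))
    flat = rng.choice(data.size, size=n, replace=False)
    data.ravel()[flat] = data.max() * rng.uniform(*magnitude_range, size=n)
    return v.with_data(data)


def study_with_outliers(study: SyntheticStudy, fraction: float = 0.001,
                        magnitude_range: tuple[float, float] = (10.0, 100.0),
                        seed: int = 0) -> SyntheticStudy:
    """Copy of a study with outlier voxels injected into every volume."""
    sub_seeds = np.random.SeedSequence(seed).spawn(len(study.subjects))
    subjects = []
    for sub, sseq in zip(study.subjects, sub_seeds):
        seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in sseq.spawn(1 + len(sub.degraded))]
        subjects.append(SubjectRecord(
            sub.subject_id,
            inject_outliers(sub.reference, fraction, magnitude_range, seeds[0]),
            sub.mask,
            [inject_outliers(v, fraction, magnitude_range, s)
             for v, s in zip(sub.degraded, seeds[1:])],
            list(sub.severities),
            reference_severity=sub.reference_severity))
    return SyntheticStudy(subjects=subjects, ratings=study.ratings,
                          config=study.config, seed=study.seed)
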