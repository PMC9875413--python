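"""Digital FDG-uptake phantoms coupled to a latent T-cell exhaustion state.

The generator emulates the data the analysis assumes but which is not
publicly deposited: tumor-bearing 3D PET/CT volumes with an ellipsoidal
ROI, an underlying immunology (early / terminal exhausted CD8+ T-cell
fractions, E/T ratio, PD-1 MFI), and paired test–retest acquisitions.

The imaging mechanism follows the biological picture that motivates the
score: terminally exhausted infiltrates locally suppress FDG uptake, so a
lesion with a higher terminal-Tex fraction carries deeper cold spots
decorating a less suppressed background — a more heterogeneous uptake
landscape. Concretely, within the tumor ellipsoid

    activity(x) = base_suv + smooth(x) - cold(x) + noise

where ``smooth`` is a fixed-amplitude, large-scale intensity field (sum of
broad seeded Gaussian bumps) and ``cold`` is a set of sharp suppression
blobs whose depth scales with ``heterogeneity_gain * terminal_tex_frac``.
Both fields are analytic functions of position, so a retest acquisition is
the same latent lesion re-evaluated at sub-voxel-shifted coordinates with
an intensity rescale and independent extra noise.

Exhaustion timecourses are calibrated to the murine data the pipeline
mirrors: LLC tumors start near 40% terminal Tex and B16 near 20%; after
ablative irradiation the LLC terminal-Tex fraction peaks at 69.44–76.35%
over days 7–14 and drops below baseline by day 21.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .imaging import RoiMask, ScanVolume

__all__ = [
    "ExhaustionState",
    "PhantomSpec",
    "CohortTimecourse",
    "PerturbationParams",
    "CohortSubject",
    "GeometryError",
    "llc_rt_timecourse",
    "llc_ici_timecourse",
    "b16_ici_timecourse",
    "sample_exhaustion_state",
    "generate_phantom",
    "generate_test_retest_pair",
    "generate_cohort",
    "generate_cohort_schedule",
    "assign_median_labels",
]

#: fraction of the non-terminal CD8+ pool occupied by early Tex; keeps
#: early + terminal <= 1 for every terminal fraction.
EARLY_TEX_POOL_FRACTION = 0.9

_NOISE_TAG = 104729  # seed stream tag for the base acquisition noise
_RETEST_TAG = 7919   # seed stream tag for retest perturbation draws


class GeometryError(ValueError):
    """Tumor geometry does not fit inside the image grid."""


@dataclass(frozen=True)
class ExhaustionState:
    """Latent immunology of one subject.

    ``early_tex_frac`` and ``terminal_tex_frac`` are fractions of CD8+
    T cells that are PD-1-intermediate and PD-1-high respectively;
    ``e_t_ratio`` is early/terminal; ``pd1_mfi`` is in arbitrary
    fluorescence units. ``label_high`` marks subjects above the cohort
    median terminal-Tex fraction and is assigned at the cohort level,
    never per subject.
    """

    early_tex_frac: float
    terminal_tex_frac: float
    e_t_ratio: float
    pd1_mfi: float
    label_high: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.terminal_tex_frac <= 1.0:
            raise ValueError("terminal_tex_frac must lie in [0, 1]")
        if not 0.0 <= self.early_tex_frac <= 1.0:
            raise ValueError("early_tex_frac must lie in [0, 1]")
        if self.early_tex_frac + self.terminal_tex_frac > 1.0 + 1e-12:
            raise ValueError("early + terminal Tex fractions exceed 1")
        if self.pd1_mfi <= 0:
            raise ValueError("pd1_mfi must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, uptake and acquisition parameters of one phantom.

    Defaults mirror the treatment-start conditions of the murine
    experiments: a ~200 mm^3 tumor (semi-axes 3.9/3.6/3.3 mm), 5.55 MBq
    injected FDG, 20 g body weight, 0.5 mm isotropic voxels on a 48^3
    grid. ``heterogeneity_gain`` scales the coupling between the
    terminal-Tex fraction and cold-spot depth; ``noise_sigma`` is the
    additive Gaussian acquisition noise on activity (SUV-scale units).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    tumor_semi_axes_mm: tuple[float, float, float] = (3.9, 3.6, 3.3)
    base_suv: float = 1.8
    heterogeneity_gain: float = 1.0
    noise_sigma: float = 0.02
    injected_dose_MBq: float = 5.55
    body_weight_g: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_mm + self.tumor_semi_axes_mm):
            raise ValueError("spacings and semi-axes must be positive")
        if self.base_suv <= 0:
            raise ValueError("base_suv must be positive")
        if self.noise_sigma < 0 or self.heterogeneity_gain < 0:
            raise ValueError("noise_sigma and heterogeneity_gain must be non-negative")


@dataclass(frozen=True)
class PerturbationParams:
    """Test–retest repositioning model: sub-voxel translation (per-axis
    Gaussian, sd in mm), a global intensity rescale (1 + Gaussian), and
    independent extra acquisition noise. All-zero parameters reproduce the
    test scan exactly."""

    shift_sd_mm: float = 0.25
    intensity_scale_sd: float = 0.02
    noise_sigma: float = 0.04


@dataclass(frozen=True)
class CohortTimecourse:
    """Per-timepoint mean/sd of the terminal-Tex fraction for one tumor model."""

    model: str
    timepoints: tuple[int, ...]
    terminal_tex_mean: tuple[float, ...]
    terminal_tex_sd: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.timepoints)
        if len(self.terminal_tex_mean) != n or len(self.terminal_tex_sd) != n:
            raise ValueError("timepoints, means and sds must have equal length")

    def at(self, day: int) -> tuple[float, float]:
        if day not in self.timepoints:
            raise KeyError(
                f"day {day} is not a timepoint of the {self.model} timecourse "
                f"(available: {list(self.timepoints)})"
            )
        i = self.timepoints.index(day)
        return self.terminal_tex_mean[i], self.terminal_tex_sd[i]


def llc_rt_timecourse() -> CohortTimecourse:
    """LLC tumors after 20 Gy ablative irradiation: ~40% terminal Tex at
    baseline, little change through day 3, a peak of ~73% at days 7–14
    (within the observed 69.44–76.35% range), below baseline by day 21."""
    return CohortTimecourse(
        model="LLC",
        timepoints=(0, 3, 7, 14, 21),
        terminal_tex_mean=(0.40, 0.42, 0.73, 0.72, 0.30),
        terminal_tex_sd=(0.06, 0.06, 0.06, 0.06, 0.05),
    )


def llc_ici_timecourse() -> CohortTimecourse:
    """LLC under anti-PD-L1: a highly exhausted, ICI-resistant baseline
    (~40% terminal Tex) that does not reinvigorate appreciably."""
    return CohortTimecourse(
        model="LLC",
        timepoints=(0, 7, 22),
        terminal_tex_mean=(0.40, 0.44, 0.46),
        terminal_tex_sd=(0.06, 0.06, 0.06),
    )


def b16_ici_timecourse() -> CohortTimecourse:
    """B16 under anti-PD-L1: a less exhausted baseline (~20% terminal Tex)
    that reinvigorates after treatment."""
    return CohortTimecourse(
        model="B16",
        timepoints=(0, 7, 22),
        terminal_tex_mean=(0.20, 0.24, 0.12),
        terminal_tex_sd=(0.05, 0.05, 0.04),
    )


def sample_exhaustion_state(
    timecourse: CohortTimecourse, day: int, seed: int
) -> ExhaustionState:
    """Draw one subject's exhaustion state at a given day.

    The terminal-Tex fraction is drawn from a normal distribution with
    the timepoint's mean/sd, truncated to [0, 1] (a zero sd yields the
    mean exactly). Early Tex occupies a fixed fraction of the remaining
    CD8+ pool, and PD-1 MFI rises with the terminal fraction with
    multiplicative lognormal scatter.
    """
    mean, sd = timecourse.at(day)
    rng = np.random.default_rng(seed)
    if sd == 0:
        t = float(mean)
    else:
        a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
        t = float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    early = EARLY_TEX_POOL_FRACTION * (1.0 - t)
    e_t = early / t if t > 0 else float("inf")
    mfi = float((800.0 + 2600.0 * t) * np.exp(rng.normal(0.0, 0.10)))
    return ExhaustionState(
        early_tex_frac=early, terminal_tex_frac=t, e_t_ratio=e_t, pd1_mfi=mfi
    )


# --------------------------------------------------------------------------
# Lesion model: analytic fields evaluated at voxel centers


@dataclass(frozen=True)
class _LesionParams:
    center_mm: np.ndarray
    smooth_centers: np.ndarray      # (K, 3) bump centers, mm
    smooth_amps: np.ndarray         # (K,) signed amplitudes, SUV units
    smooth_sigma_mm: float
    cold_centers: np.ndarray        # (M, 3) cold-spot centers, mm
    cold_depths: np.ndarray         # (M,) suppression depths, SUV units
    cold_sigma_mm: float
    ct_centers: np.ndarray
    ct_amps: np.ndarray
    ct_sigma_mm: float


_N_SMOOTH_BUMPS = 40
_N_COLD_SPOTS = 250
_SMOOTH_STD_FRACTION = 0.15   # ROI std of the smooth field as a fraction of gain*base
_SMOOTH_SIGMA_MM = 1.8
_COLD_SIGMA_MM = 0.4
_COLD_DEPTH_RANGE = (0.12, 0.24)  # per-blob depth as a fraction of gain*t*base
_BACKGROUND_FRACTION = 0.15
_CT_BASE_DENSITY = 40.0
_CT_BUMP_AMP = 3.0
_CT_SIGMA_MM = 1.2
_CT_NOISE_SIGMA = 0.5
_CT_EDGE_WIDTH = 0.12          # softness of the CT ellipsoid edge (normalized r^2)


def _voxel_centers_mm(
    spec: PhantomSpec, slices: tuple[slice, ...] | None = None
) -> tuple[np.ndarray, ...]:
    axes = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(spec.grid_shape, spec.voxel_spacing_mm)
    ]
    if slices is not None:
        axes = [a[sl] for a, sl in zip(axes, slices)]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def _tumor_bbox(spec: PhantomSpec, center: np.ndarray, margin_mm: float) -> tuple[slice, ...]:
    """Grid slices covering the tumor ellipsoid plus a margin."""
    slices = []
    for n, s, c, a in zip(
        spec.grid_shape, spec.voxel_spacing_mm, center, spec.tumor_semi_axes_mm
    ):
        lo = max(0, int(np.floor((c - a - margin_mm) / s)))
        hi = min(n, int(np.ceil((c + a + margin_mm) / s)) + 1)
        slices.append(slice(lo, hi))
    return tuple(slices)


def _check_geometry(spec: PhantomSpec) -> np.ndarray:
    extent = np.array(spec.grid_shape) * np.array(spec.voxel_spacing_mm)
    center = extent / 2.0
    margin = np.array(spec.voxel_spacing_mm)  # one voxel clearance
    if np.any(np.array(spec.tumor_semi_axes_mm) + margin >= extent / 2.0):
        raise GeometryError(
            f"tumor semi-axes {spec.tumor_semi_axes_mm} mm do not fit inside the "
            f"grid extent {tuple(extent)} mm"
        )
    return center


def _draw_lesion_params(spec: PhantomSpec, state: ExhaustionState) -> _LesionParams:
    center = _check_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    semi = np.array(spec.tumor_semi_axes_mm)
    gain = spec.heterogeneity_gain
    base = spec.base_suv

    def _uniform_in_ellipsoid(n: int, shrink: float) -> np.ndarray:
        pts = np.empty((n, 3))
        got = 0
        while got < n:
            cand = rng.uniform(-1.0, 1.0, size=(2 * n, 3))
            ok = cand[(cand**2).sum(axis=1) <= 1.0]
            take = min(n - got, len(ok))
            pts[got : got + take] = ok[:take]
            got += take
        return center + pts * (semi * shrink)

    smooth_centers = _uniform_in_ellipsoid(_N_SMOOTH_BUMPS, 1.0)
    smooth_amps = rng.normal(0.0, 1.0, _N_SMOOTH_BUMPS)
    # normalize the realized field to a fixed ROI std so the baseline
    # texture amplitude does not depend on the bump draw
    if gain > 0:
        bbox = _tumor_bbox(spec, center, 0.0)
        zz, yy, xx = _voxel_centers_mm(spec, bbox)
        raw = _sum_gaussians((zz, yy, xx), smooth_centers, smooth_amps, _SMOOTH_SIGMA_MM)
        r2 = (
            ((zz - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((xx - center[2]) / semi[2]) ** 2
        )
        realized_std = raw[r2 <= 1.0].std()
        if realized_std > 0:
            smooth_amps *= _SMOOTH_STD_FRACTION * gain * base / realized_std
    else:
        smooth_amps = np.zeros(_N_SMOOTH_BUMPS)
    cold_centers = _uniform_in_ellipsoid(_N_COLD_SPOTS, 0.85)
    # depth scales with gain * terminal-Tex fraction: deeper suppression in
    # lesions with more terminally exhausted infiltrate
    cold_depths = (
        gain
        * state.terminal_tex_frac
        * base
        * rng.uniform(*_COLD_DEPTH_RANGE, _N_COLD_SPOTS)
    )
    ct_centers = _uniform_in_ellipsoid(24, 1.0)
    ct_amps = rng.normal(0.0, _CT_BUMP_AMP, 24)
    return _LesionParams(
        center_mm=center,
        smooth_centers=smooth_centers,
        smooth_amps=smooth_amps,
        smooth_sigma_mm=_SMOOTH_SIGMA_MM,
        cold_centers=cold_centers,
        cold_depths=cold_depths,
        cold_sigma_mm=_COLD_SIGMA_MM,
        ct_centers=ct_centers,
        ct_amps=ct_amps,
        ct_sigma_mm=_CT_SIGMA_MM,
    )


def _sum_gaussians(
    coords: tuple[np.ndarray, ...],
    centers: np.ndarray,
    amps: np.ndarray,
    sigma: float,
) -> np.ndarray:
    out = np.zeros_like(coords[0])
    inv = 1.0 / (2.0 * sigma * sigma)
    for c, a in zip(centers, amps):
        d2 = (
            (coords[0] - c[0]) ** 2
            + (coords[1] - c[1]) ** 2
            + (coords[2] - c[2]) ** 2
        )
        out += a * np.exp(-d2 * inv)
    return out


def _realize(
    spec: PhantomSpec,
    params: _LesionParams,
    offset: np.ndarray,
    scale: float,
    extra_noise_sigma: float,
    extra_noise_rng: np.random.Generator | None,
) -> tuple[ScanVolume, ScanVolume, RoiMask]:
    base = spec.base_suv
    # evaluate the analytic fields only near the tumor: everywhere else the
    # PET image is flat background and the CT density is ~0
    margin = 5.0 * max(spec.voxel_spacing_mm) + float(np.abs(offset).max())
    bbox = _tumor_bbox(spec, params.center_mm, margin)
    zz, yy, xx = _voxel_centers_mm(spec, bbox)
    # the lesion moves by +offset, so the latent fields are sampled at x-offset
    coords = (zz - offset[0], yy - offset[1], xx - offset[2])

    c = params.center_mm + offset
    semi = np.array(spec.tumor_semi_axes_mm)
    r2 = ((zz - c[0]) / semi[0]) ** 2 + ((yy - c[1]) / semi[1]) ** 2 + (
        (xx - c[2]) / semi[2]
    ) ** 2
    inside_box = r2 <= 1.0
    inside = np.zeros(spec.grid_shape, dtype=bool)
    inside[bbox] = inside_box

    smooth = _sum_gaussians(
        coords, params.smooth_centers, params.smooth_amps, params.smooth_sigma_mm
    )
    cold = _sum_gaussians(
        coords, params.cold_centers, params.cold_depths, params.cold_sigma_mm
    )
    # suppression acts multiplicatively on uptake: overlapping cold spots
    # deepen smoothly without ever producing flat clipped regions
    lesion = (base + smooth) * np.exp(-cold / base)
    pet = np.full(spec.grid_shape, _BACKGROUND_FRACTION * base)
    pet[inside] = lesion[inside_box]
    pet *= scale

    noise_rng = np.random.default_rng([spec.seed, _NOISE_TAG])
    pet = pet + noise_rng.normal(0.0, spec.noise_sigma, spec.grid_shape) if spec.noise_sigma > 0 else pet
    if extra_noise_sigma > 0 and extra_noise_rng is not None:
        pet = pet + extra_noise_rng.normal(0.0, extra_noise_sigma, spec.grid_shape)
    pet = np.maximum(pet, 0.01 * base)
    # the lesion model lives on the SUV scale; the stored PET image is the
    # corresponding activity concentration, so SUV conversion recovers it
    pet = pet * (spec.injected_dose_MBq * 1000.0 / spec.body_weight_g)

    ct = np.zeros(spec.grid_shape)
    ct_box = _CT_BASE_DENSITY / (1.0 + np.exp(np.minimum((r2 - 1.0) / _CT_EDGE_WIDTH, 60.0)))
    ct_box += _sum_gaussians(coords, params.ct_centers, params.ct_amps, params.ct_sigma_mm)
    ct[bbox] = ct_box
    if _CT_NOISE_SIGMA > 0:
        ct = ct + noise_rng.normal(0.0, _CT_NOISE_SIGMA, spec.grid_shape)

    meta = {
        "injected_dose_MBq": spec.injected_dose_MBq,
        "body_weight_g": spec.body_weight_g,
    }
    pet_scan = ScanVolume(
        voxels=pet, spacing_mm=spec.voxel_spacing_mm, modality="PET",
        unit="kBq/mL", meta=dict(meta),
    )
    ct_scan = ScanVolume(
        voxels=ct, spacing_mm=spec.voxel_spacing_mm, modality="CT",
        unit="HU", meta=dict(meta),
    )
    mask = RoiMask(voxels=inside.astype(np.uint8), spacing_mm=spec.voxel_spacing_mm)
    return pet_scan, ct_scan, mask


def generate_phantom(
    spec: PhantomSpec, state: ExhaustionState
) -> tuple[ScanVolume, ScanVolume, RoiMask]:
    """Generate co-aligned PET activity and CT volumes with the tumor mask.

    The PET lesion carries the exhaustion-coupled cold-spot texture; the
    CT volume is a smooth density ellipsoid with its own mild texture
    (independent of the exhaustion state) so CT features are well defined.
    Output is a pure function of ``spec`` (including its seed) and
    ``state``.
    """
    params = _draw_lesion_params(spec, state)
    return _realize(spec, params, np.zeros(3), 1.0, 0.0, None)


def generate_test_retest_pair(
    spec: PhantomSpec,
    state: ExhaustionState,
    perturbation: PerturbationParams = PerturbationParams(),
) -> tuple[tuple[ScanVolume, RoiMask], tuple[ScanVolume, RoiMask]]:
    """Generate a PET test–retest pair for one latent lesion.

    The retest scan re-evaluates the same analytic lesion at sub-voxel
    shifted coordinates, applies a global intensity rescale, adds
    independent extra noise per ``perturbation``, and re-rasterizes the
    mask at the shifted position. All-zero perturbation parameters yield
    a voxelwise identical pair.
    """
    params = _draw_lesion_params(spec, state)
    pet1, _, mask1 = _realize(spec, params, np.zeros(3), 1.0, 0.0, None)
    rng = np.random.default_rng([spec.seed, _RETEST_TAG])
    shift = rng.normal(0.0, perturbation.shift_sd_mm, 3) if perturbation.shift_sd_mm > 0 else np.zeros(3)
    scale = 1.0 + (rng.normal(0.0, perturbation.intensity_scale_sd) if perturbation.intensity_scale_sd > 0 else 0.0)
    pet2, _, mask2 = _realize(
        spec, params, shift, scale, perturbation.noise_sigma, rng
    )
    return (pet1, mask1), (pet2, mask2)


# --------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSubject:
    subject_id: str
    day: int
    pet: ScanVolume
    ct: ScanVolume
    mask: RoiMask
    state: ExhaustionState
    spec: PhantomSpec


def assign_median_labels(states: Sequence[ExhaustionState]) -> list[ExhaustionState]:
    """Binarize a cohort at its median terminal-Tex fraction.

    Subjects strictly above the median are labeled high; ties at the
    median go to the low class so the rule is deterministic.
    """
    t = np.array([s.terminal_tex_frac for s in states])
    cutoff = float(np.median(t))
    return [replace(s, label_high=bool(ti > cutoff)) for s, ti in zip(states, t)]


def generate_cohort_schedule(
    schedule: Sequence[tuple[CohortTimecourse, int]],
    spec_template: PhantomSpec,
    seed: int,
) -> list[CohortSubject]:
    """Generate one subject per (timecourse, day) entry of ``schedule``.

    Per-subject seeds derive deterministically from the master seed;
    ``label_high`` is assigned by the cohort median split.
    """
    n = len(schedule)
    if n < 4:
        raise ValueError(
            f"cohort size {n} too small: median split and model fitting need n >= 4"
        )
    sub_seeds = np.random.SeedSequence(seed).generate_state(2 * n, dtype=np.uint32)
    states = [
        sample_exhaustion_state(tc, day, int(sub_seeds[2 * i]))
        for i, (tc, day) in enumerate(schedule)
    ]
    states = assign_median_labels(states)
    subjects = []
    for i, ((tc, day), state) in enumerate(zip(schedule, states)):
        spec = replace(spec_template, seed=int(sub_seeds[2 * i + 1]))
        pet, ct, mask = generate_phantom(spec, state)
        pet.meta.update(subject_id=f"S{i:03d}", day=day)
        ct.meta.update(subject_id=f"S{i:03d}", day=day)
        subjects.append(
            CohortSubject(
                subject_id=f"S{i:03d}", day=day, pet=pet, ct=ct, mask=mask,
                state=state, spec=spec,
            )
        )
    return subjects


def generate_cohort(
    n: int,
    timecourse: CohortTimecourse,
    day: int,
    spec_template: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> list[CohortSubject]:
    """Generate ``n`` subjects at one timepoint of one tumor model."""
    return generate_cohort_schedule([(timecourse, day)] * n, spec_template, seed)
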