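"""Synthetic LA phantoms and cohorts with known continuous ground truth.

A subject is an ellipsoidal endocardial chamber (axis ratio <= 1.25)
whose wall is swept outward along the surface normal by a thickness
field T(u) = mu_T + sigma_T * Pn(u), where Pn is a Gaussian-bump patch
field re-centred and re-scaled to zero area-mean and unit area-SD over
the mapped region.  Five spherical caps (four PV ostia, one mitral
annulus) are excluded from the mapped wall; their joint aperture scale
is solved so the mapped offset-shell volume hits the subject's target
wall volume.  Wall indices are therefore known analytically:

    LAV      = 4/3 pi a b c          (inner chamber)
    LAWT     = mu_T, LAWT(SD) = sigma_T   (area-weighted, by construction)
    LAWV     = curvature-corrected quadrature of the mapped shell

Cohort draws are calibrated to published four-group summaries: wall
indices are log-normal laws fitted to median [IQR]; echo covariates are
group Gaussians; the within-group LAVi-PALS coupling is a Gaussian
copula whose latent correlation is calibrated by bisection so the
pooled standardized PALS-on-LAVi slope matches a configured value.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import calibration as cal
from .distributions import DistributionSpec, fit_lognormal_from_median_iqr, truncated_normal
from .geometry import (
    CapSet,
    Ellipsoid,
    GeometryError,
    PatchSpec,
    SphereQuadrature,
    ThicknessField,
    MAX_CAP_SCALE,
    default_cap_layout,
    normalisation_over_region,
    patch_field,
    shell_region_integrals,
    shell_volume_from_integrals,
    shell_volume_from_moments,
    shell_volume_moments,
)
from .volume import BACKGROUND, CHAMBER, EXCLUDED, WALL, GridSpec, LabeledVolume

# fixed semi-axis ratios (max/min = 1.244 <= 1.25 keeps normal offsets
# well-conditioned and far from self-intersection)
AXIS_RATIOS = np.array([1.12, 1.0, 0.90])

MAPPED_FRACTION_RANGE = (0.5, 0.95)
MAX_REDRAWS = 100

# quadrature resolutions; full-sphere integrands are smooth (bump widths
# >= 0.3 rad), caps get their own boundary-conforming rule
FULL_QUAD = dict(n_theta=48, n_phi=96)
CAP_QUAD = dict(n_r=12, n_phi=24)


def _cap_frames(dirs):
    """Orthonormal frames (d, e1, e2) for each cap direction."""
    frames = []
    for d in dirs:
        d = np.asarray(d, dtype=float)
        helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        frames.append((d, e1, e2))
    return frames


def _cap_union_region(ellipsoid, patches, frames, apertures):
    """Quadrature data over the (pairwise-disjoint) cap union, batched into
    one node array; same dict shape as shell_region_integrals."""
    from .geometry import _leggauss_cached

    n_r, n_phi = CAP_QUAD["n_r"], CAP_QUAD["n_phi"]
    zg, wz = _leggauss_cached(n_r)
    phi = (np.arange(n_phi) + 0.5) * (2.0 * math.pi / n_phi)
    wphi = 2.0 * math.pi / n_phi
    d = np.array([f[0] for f in frames])  # (k,3)
    e1 = np.array([f[1] for f in frames])
    e2 = np.array([f[2] for f in frames])
    lo = np.cos(np.asarray(apertures, dtype=float))  # (k,)
    cg = lo[:, None] + 0.5 * (zg + 1.0)[None, :] * (1.0 - lo)[:, None]  # (k,n_r)
    wcg = wz[None, :] * 0.5 * (1.0 - lo)[:, None]
    sg = np.sqrt(np.clip(1.0 - cg**2, 0.0, None))
    ring = (
        np.cos(phi)[None, :, None] * e1[:, None, :]
        + np.sin(phi)[None, :, None] * e2[:, None, :]
    )  # (k,n_phi,3)
    u = (
        cg[:, :, None, None] * d[:, None, None, :]
        + sg[:, :, None, None] * ring[:, None, :, :]
    ).reshape(-1, 3)
    w = np.repeat(wcg.reshape(-1), n_phi) * wphi
    da = ellipsoid.area_element(u) * w
    p0 = patch_field(patches, u)
    sum_k, gauss_k = ellipsoid.curvatures(u)
    return {
        "area": float(da.sum()),
        "int_p": float((p0 * da).sum()),
        "int_p2": float((p0**2 * da).sum()),
        "da": da,
        "p0": p0,
        "sum_k": sum_k,
        "gauss_k": gauss_k,
    }


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectParams:
    """Everything needed to build one phantom plus its clinical covariates."""

    group: str
    inner_radii_mm: tuple[float, float, float]
    mean_thickness_mm: float
    thickness_sd_mm: float
    patch_spec: tuple
    mapped_fraction: float
    bsa_m2: float
    covariates: dict
    target_indices: dict  # the drawn (lavi, lawv, lawt, lawt_sd) this subject realises
    seed: int

    def __post_init__(self):
        r = np.asarray(self.inner_radii_mm, dtype=float)
        if r.max() / r.min() > 1.25 + 1e-9:
            raise PhantomError(f"axis ratio {r.max() / r.min():.3f} exceeds 1.25")
        if not (1.2 <= self.bsa_m2 <= 2.6):
            raise PhantomError(f"BSA {self.bsa_m2} outside [1.2, 2.6] m2")
        # cohort draws keep f in MAPPED_FRACTION_RANGE; hand-built phantoms
        # (oracle fixtures) may use any fraction up to a fully mapped wall
        if not (0.0 < self.mapped_fraction <= 1.0):
            raise PhantomError(
                f"mapped fraction {self.mapped_fraction:.3f} outside (0, 1]"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic index values of the continuous phantom geometry."""

    lav_ml: float
    lawv_ml: float
    lawt_mm: float
    lawt_sd_mm: float
    cap_scale: float
    field_offset: float
    field_scale: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CalibrationTable:
    """Group calibration: wall-index median/IQR, echo mean/SD, prevalences."""

    group_sizes: dict = field(default_factory=lambda: dict(cal.GROUP_SIZES))
    wall_index_median_iqr: dict = field(default_factory=lambda: dict(cal.WALL_INDEX_MEDIAN_IQR))
    gaussian_covariates: dict = field(default_factory=lambda: dict(cal.GAUSSIAN_COVARIATES))
    binary_covariates: dict = field(default_factory=lambda: dict(cal.BINARY_COVARIATES))
    lognormal_covariates: dict = field(default_factory=lambda: dict(cal.LOGNORMAL_COVARIATES))
    bsa_mean: float = cal.BSA_MEAN
    bsa_sd: float = cal.BSA_SD
    bsa_range: tuple = cal.BSA_RANGE
    pooled_lavi_pals_slope: float = cal.POOLED_LAVI_PALS_SLOPE
    wall_volume_coupling_rho: float = cal.WALL_VOLUME_COUPLING_RHO

    def index_law(self, group: str, index: str) -> DistributionSpec:
        med, q1, q3 = self.wall_index_median_iqr[group][index]
        return fit_lognormal_from_median_iqr(med, q1, q3)


DEFAULT_CALIBRATION = CalibrationTable()


def calibrate_lavi_pals_rho(table: CalibrationTable | None = None) -> float:
    """Latent within-group LAVi-PALS correlation hitting the pooled slope.

    The pooled standardized slope of PALS on LAVi equals the pooled
    Pearson correlation, which decomposes into a between-group part
    (fixed by the group means) and a within-group part linear in the
    latent copula correlation rho.  For lognormal X = exp(mu + s Z1)
    and normal Y coupled through corr(Z1, Z2) = rho,
    Cov(X, Y) = rho * s * E[X] * SD(Y).  Solved by bisection.
    """
    table = table or DEFAULT_CALIBRATION
    groups = list(table.group_sizes)
    w = np.array([table.group_sizes[g] for g in groups], dtype=float)
    w /= w.sum()
    laws = [table.index_law(g, "lavi") for g in groups]
    mx = np.array([law.mean for law in laws])
    vx = np.array([law.sd**2 for law in laws])
    sx_factor = np.array([law.sigma * law.mean for law in laws])  # Cov per unit rho per unit SD(Y)
    py = np.array([table.gaussian_covariates["pals"][g][0] for g in groups])
    sy = np.array([table.gaussian_covariates["pals"][g][1] for g in groups])
    mxb = float(w @ mx)
    pyb = float(w @ py)
    var_x = float(w @ (vx + (mx - mxb) ** 2))
    var_y = float(w @ (sy**2 + (py - pyb) ** 2))
    between = float(w @ ((mx - mxb) * (py - pyb)))
    within_per_rho = float(w @ (sx_factor * sy))
    target = table.pooled_lavi_pals_slope

    def pooled_r(rho):
        return (between + rho * within_per_rho) / math.sqrt(var_x * var_y) - target

    lo, hi = -0.999, 0.999
    if pooled_r(lo) * pooled_r(hi) > 0:
        raise PhantomError(
            f"pooled LAVi-PALS slope {target} unattainable for this calibration"
        )
    return float(brentq(pooled_r, lo, hi, xtol=1e-12))


def _draw_patches(group: str, rng: np.random.Generator) -> tuple:
    """Group-styled bump fields: AF-like walls get fewer, larger patches
    (patchy), control/HFpEF walls get many small ones (diffuse).  These
    shapes are presentational; calibration is exact via re-scaling."""
    if group in ("af", "hfpef_af"):
        n, width = 4, 0.55
        amp_lo, amp_hi = 0.8, 1.6
    else:
        n, width = 8, 0.40
        amp_lo, amp_hi = 0.5, 1.0
    patches = []
    for _ in range(n):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        amp = rng.uniform(amp_lo, amp_hi)
        patches.append(PatchSpec(center=tuple(v), width_rad=width, amplitude=amp))
    return tuple(patches)


def _full_field_stats(ellipsoid: Ellipsoid, patches) -> dict:
    quad = SphereQuadrature.full(**FULL_QUAD)
    return shell_region_integrals(ellipsoid, quad, patches=patches)


def sample_subject(
    group: str,
    table: CalibrationTable | None = None,
    rng_seed: int = 0,
    spacing_mm: float = 0.5,
) -> SubjectParams:
    """Draw one subject's geometry targets and covariates for `group`.

    Pure function of (calibration table, seed).  Draws are redone (at
    most MAX_REDRAWS times) when the implied mapped fraction leaves
    (0.5, 0.95) or the minimum of the thickness field would drop below
    half a voxel.
    """
    table = table or DEFAULT_CALIBRATION
    if group not in table.group_sizes:
        raise PhantomError(f"unknown group {group!r}; expected one of {list(table.group_sizes)}")
    rng = np.random.default_rng(rng_seed)
    rho = calibrate_lavi_pals_rho(table)
    laws = {k: table.index_law(group, k) for k in cal.WALL_INDICES}
    lo_f, hi_f = MAPPED_FRACTION_RANGE

    last_reason = ""
    for _attempt in range(MAX_REDRAWS):
        bsa = float(truncated_normal(rng, table.bsa_mean, table.bsa_sd, *table.bsa_range))
        z_lavi = rng.standard_normal()
        lavi = float(laws["lavi"].from_latent(z_lavi))
        lawt = float(laws["lawt"].sample(rng))
        lawt_sd = float(laws["lawt_sd"].sample(rng))
        # construction-induced LAWV-LAV-LAWT coupling: the wall volume's
        # latent is correlated with the log shell-volume combination
        # (2/3) log(LAVi*BSA) + log(LAWT); a Gaussian copula leaves the
        # LAWV marginal exactly log-normal while concentrating the
        # implied mapped fraction in its feasible window
        rho_wv = table.wall_volume_coupling_rho
        sig_logbsa = table.bsa_sd / table.bsa_mean
        w_mean = (2.0 / 3.0) * (laws["lavi"].mu + math.log(table.bsa_mean)) + laws["lawt"].mu
        w_sd = math.sqrt(
            ((2.0 / 3.0) * laws["lavi"].sigma) ** 2
            + ((2.0 / 3.0) * sig_logbsa) ** 2
            + laws["lawt"].sigma ** 2
        )
        w_hat = ((2.0 / 3.0) * (math.log(lavi) + math.log(bsa)) + math.log(lawt) - w_mean) / w_sd
        z_wv = rho_wv * w_hat + math.sqrt(1.0 - rho_wv**2) * rng.standard_normal()
        lawv = float(laws["lawv"].from_latent(z_wv))

        covariates = {}
        for name, per_group in table.gaussian_covariates.items():
            mean, sd = per_group[group]
            if name == "pals":
                z = rho * z_lavi + math.sqrt(1.0 - rho**2) * rng.standard_normal()
                covariates[name] = mean + sd * z
            else:
                covariates[name] = float(rng.normal(mean, sd))
        for name, per_group in table.binary_covariates.items():
            covariates[name] = int(rng.random() < per_group[group])
        for name, per_group in table.lognormal_covariates.items():
            law = fit_lognormal_from_median_iqr(*per_group[group])
            covariates[name] = float(law.sample(rng))

        lav_mm3 = lavi * bsa * 1000.0
        scale = (lav_mm3 / (4.0 / 3.0 * math.pi * float(np.prod(AXIS_RATIOS)))) ** (1.0 / 3.0)
        radii = tuple(float(r) for r in AXIS_RATIOS * scale)
        patches = _draw_patches(group, rng)

        ellipsoid = Ellipsoid(radii)
        stats = _full_field_stats(ellipsoid, patches)
        m0, s0 = normalisation_over_region(stats["area"], stats["int_p"], stats["int_p2"])
        if s0 <= 1e-9:
            last_reason = "degenerate patch field"
            continue
        v_full = shell_volume_from_integrals(stats, lawt, lawt_sd, m0, s0)
        f = lawv * 1000.0 / v_full
        t_min = lawt + lawt_sd * (stats["p_min"] - m0) / s0
        t_max = lawt + lawt_sd * (stats["p_max"] - m0) / s0
        if not (lo_f < f < hi_f):
            last_reason = (
                f"mapped fraction {f:.3f} outside ({lo_f}, {hi_f}) for "
                f"lawv={lawv:.2f} ml, lawt={lawt:.2f} mm, lavi={lavi:.1f} ml/m2, bsa={bsa:.2f}"
            )
            continue
        # closure of the voxelized chamber needs T >= spacing everywhere
        # (signed distance is 1-Lipschitz between face-adjacent centres),
        # which also guarantees the half-voxel floor
        if t_min < 1.02 * spacing_mm:
            last_reason = f"minimum thickness {t_min:.3f} mm below one voxel {spacing_mm}"
            continue
        if t_max >= ellipsoid.min_curvature_radius_mm:
            last_reason = f"maximum offset {t_max:.2f} mm reaches curvature radius"
            continue
        # exact feasibility: the build recentres the field over the mapped
        # region, whose SD can be well below the full-sphere SD, deepening
        # the minimum; check with the solved cap normalization
        try:
            # coarse aperture tolerance: this solve only gates the redraw
            # decision; build_phantom re-solves at full tolerance
            _, _, off_m, sc_m, _ = _solve_cap_scale(
                ellipsoid, patches, lawt, lawt_sd, float(f), stats, xtol=0.02
            )
        except PhantomError as exc:
            last_reason = str(exc)
            continue
        t_min_mapped = lawt + lawt_sd * (stats["p_min"] - off_m) / sc_m
        t_max_mapped = lawt + lawt_sd * (stats["p_max"] - off_m) / sc_m
        if t_min_mapped < 1.02 * spacing_mm:
            last_reason = (
                f"mapped-normalized minimum thickness {t_min_mapped:.3f} mm below one voxel"
            )
            continue
        if t_max_mapped >= ellipsoid.min_curvature_radius_mm:
            last_reason = f"mapped-normalized offset {t_max_mapped:.2f} mm reaches curvature radius"
            continue
        return SubjectParams(
            group=group,
            inner_radii_mm=radii,
            mean_thickness_mm=lawt,
            thickness_sd_mm=lawt_sd,
            patch_spec=patches,
            mapped_fraction=float(f),
            bsa_m2=bsa,
            covariates=covariates,
            target_indices={"lavi": lavi, "lawv": lawv, "lawt": lawt, "lawt_sd": lawt_sd},
            seed=int(rng_seed),
        )
    raise PhantomError(
        f"could not draw feasible subject for group {group!r} after {MAX_REDRAWS} "
        f"attempts; last violation: {last_reason}"
    )


def required_grid_shape(params: SubjectParams, spacing_mm: float, min_shape: int = 160) -> int:
    """Smallest even cubic shape holding the phantom with a 2-voxel margin.

    Uses the mapped-region field normalization (the one the build applies),
    which can amplify the bump extremes beyond the full-sphere estimate.
    """
    ellipsoid = Ellipsoid(params.inner_radii_mm)
    stats = _full_field_stats(ellipsoid, params.patch_spec)
    t_max = params.mean_thickness_mm
    if params.thickness_sd_mm > 0:
        _, _, off, sc, _ = _solve_cap_scale(
            ellipsoid,
            params.patch_spec,
            params.mean_thickness_mm,
            params.thickness_sd_mm,
            params.mapped_fraction,
            stats,
            xtol=0.02,
        )
        t_max += params.thickness_sd_mm * (stats["p_max"] - off) / sc
    extent = 2.0 * (max(params.inner_radii_mm) + t_max) / spacing_mm + 2 * 2 + 2
    n = max(min_shape, int(math.ceil(extent)))
    return n + (n % 2)


def _solve_cap_scale(ellipsoid, patches, mu, sigma, f_target, full_stats, xtol: float = 1e-4):
    """Joint cap-aperture scale whose mapped shell-volume fraction is f_target.

    Returns (scale, CapSet, offset, scale_sd, mapped_volume): offset and
    scale_sd are the raw-field mean and SD over the mapped region (the
    thickness-field normalization constants).
    """
    dirs, base = default_cap_layout()
    m0, s0 = normalisation_over_region(
        full_stats["area"], full_stats["int_p"], full_stats["int_p2"]
    )
    if sigma > 0 and s0 <= 1e-9:
        raise PhantomError("patch field is degenerate (zero area-SD); cannot carry sigma_T")
    v_full = shell_volume_from_integrals(full_stats, mu, sigma, m0, s0)

    if f_target >= 1.0 - 1e-9:  # fully mapped wall: no exclusion caps
        off, sc = (m0, s0) if sigma > 0 else (0.0, 1.0)
        caps = CapSet(directions=dirs, apertures=(0.0,) * len(dirs))
        return 0.0, caps, off, sc, v_full

    frames = _cap_frames(dirs)
    full_mom = shell_volume_moments(full_stats)

    def mapped_stats(s):
        cap_data = _cap_union_region(ellipsoid, patches, frames, [s * b for b in base])
        area = full_stats["area"] - cap_data["area"]
        int_p = full_stats["int_p"] - cap_data["int_p"]
        int_p2 = full_stats["int_p2"] - cap_data["int_p2"]
        m, sd = normalisation_over_region(area, int_p, int_p2)
        if sigma > 0 and sd <= 1e-9:
            raise PhantomError("patch field degenerate over the mapped region")
        off, sc = (m, sd) if sigma > 0 else (0.0, 1.0)
        v = shell_volume_from_moments(full_mom, mu, sigma, off, sc) - (
            shell_volume_from_integrals(cap_data, mu, sigma, off, sc)
        )
        return v, off, sc

    def g(s):
        v, _, _ = mapped_stats(s)
        return v - f_target * v_full

    s_lo, s_hi = 1e-3, MAX_CAP_SCALE
    if g(s_hi) > 0:
        raise PhantomError(
            f"mapped fraction {f_target:.3f} unreachable: caps at maximal disjoint "
            f"apertures still leave a larger mapped shell volume"
        )
    # 1e-4 on the cap scale keeps the mapped-volume fraction accurate to
    # a few 1e-5 -- far below voxelization error
    s_star = float(brentq(g, s_lo, s_hi, xtol=xtol))
    v_mapped, off, sc = mapped_stats(s_star)
    caps = CapSet(directions=dirs, apertures=tuple(s_star * b for b in base))
    caps.check_disjoint()
    return s_star, caps, off, sc, v_mapped


def build_phantom(params: SubjectParams, grid: GridSpec) -> tuple[LabeledVolume, GroundTruth]:
    """Voxelize one subject onto `grid` and return the analytic ground truth.

    A voxel is chamber when its centre lies inside the inner ellipsoid;
    wall/excluded-wall when its centre lies within the normal-offset
    thickness of its foot point (cap membership decides which); else
    background.
    """
    ellipsoid = Ellipsoid(params.inner_radii_mm)
    h = grid.spacing_mm
    full_stats = _full_field_stats(ellipsoid, params.patch_spec)
    mu, sigma = params.mean_thickness_mm, params.thickness_sd_mm
    s_star, caps, off, sc, v_mapped = _solve_cap_scale(
        ellipsoid, params.patch_spec, mu, sigma, params.mapped_fraction, full_stats
    )
    tfield = ThicknessField(mu=mu, sigma=sigma, patches=params.patch_spec, offset=off, scale=sc)

    # certified thickness bounds from the quadrature extremes of the raw field
    if sigma > 0:
        t_lo = mu + sigma * (full_stats["p_min"] - off) / sc
        t_hi = mu + sigma * (full_stats["p_max"] - off) / sc
    else:
        t_lo = t_hi = mu
    if t_hi >= ellipsoid.min_curvature_radius_mm:
        raise PhantomError(
            f"offset surface self-intersects: max offset {t_hi:.2f} mm >= minimal "
            f"curvature radius {ellipsoid.min_curvature_radius_mm:.2f} mm"
        )
    if t_lo <= 0:
        raise PhantomError(f"thickness field reaches {t_lo:.3f} mm <= 0")
    if t_lo < h:
        raise PhantomError(
            f"thickness field minimum {t_lo:.3f} mm is below one voxel ({h} mm); "
            "the voxelized chamber could not stay enclosed"
        )

    # grid fit with the mandated 2-voxel background margin
    axes = ellipsoid.axes
    for ax in range(3):
        coords = grid.axis_coords(ax)
        reach = axes[ax] + t_hi
        if -reach < coords[0] + 2 * h or reach > coords[-1] - 2 * h:
            raise PhantomError(
                f"phantom (reach {reach:.1f} mm on axis {ax}) does not fit grid "
                f"extent [{coords[0]:.1f}, {coords[-1]:.1f}] mm with 2-voxel margin"
            )

    # single-precision is ample for voxel classification (labels only);
    # the ground-truth quadrature stays in float64
    cx = [grid.axis_coords(ax).astype(np.float32) for ax in range(3)]
    q = (
        (cx[0][:, None, None] / np.float32(axes[0])) ** 2
        + (cx[1][None, :, None] / np.float32(axes[1])) ** 2
        + (cx[2][None, None, :] / np.float32(axes[2])) ** 2
    )
    labels = np.zeros(grid.shape, dtype=np.uint8)
    labels[q <= 1.0] = CHAMBER

    # certified exterior band: dist >= (q-1) a_min^2 / (2 |x|)
    r2 = (
        cx[0][:, None, None] ** 2 + cx[1][None, :, None] ** 2 + cx[2][None, None, :] ** 2
    )
    a_min = float(axes.min())
    with np.errstate(divide="ignore", invalid="ignore"):
        lower_bound = (q - 1.0) * np.float32(a_min**2) / (2.0 * np.sqrt(r2))
    band = (q > 1.0) & (lower_bound <= np.float32(t_hi + h + 0.01))
    idx = np.argwhere(band)
    if len(idx):
        pts = grid.world(idx)
        _, dist, u = ellipsoid.foot_points(pts)
        t_at = tfield(u)
        in_wall = dist <= t_at
        in_cap = caps.contains(u)
        lab = np.where(in_wall & ~in_cap, WALL, np.where(in_wall & in_cap, EXCLUDED, BACKGROUND))
        labels[tuple(idx.T)] = lab.astype(np.uint8)

    vol = LabeledVolume(labels=labels, grid=grid)
    vol.validate()
    truth = GroundTruth(
        lav_ml=ellipsoid.volume_mm3 / 1000.0,
        lawv_ml=v_mapped / 1000.0,
        lawt_mm=mu,
        lawt_sd_mm=sigma,
        cap_scale=s_star,
        field_offset=off,
        field_scale=sc,
    )
    return vol, truth


@dataclass(frozen=True)
class CohortConfig:
    group_sizes: dict = field(default_factory=lambda: dict(cal.GROUP_SIZES))
    spacing_mm: float = 0.5
    base_shape: int = 160
    calibration: CalibrationTable = field(default_factory=lambda: DEFAULT_CALIBRATION)

    def to_jsonable(self) -> dict:
        d = {
            "group_sizes": dict(self.group_sizes),
            "spacing_mm": self.spacing_mm,
            "base_shape": self.base_shape,
            "calibration": asdict(self.calibration),
        }
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def sample_cohort_params(config: CohortConfig, seed: int) -> list[SubjectParams]:
    """Draw all subjects of a cohort; pure function of (config, seed)."""
    rng = np.random.default_rng(seed)
    out = []
    for group, n in config.group_sizes.items():
        if n < 0:
            raise PhantomError(f"negative group size for {group}")
        seeds = rng.integers(0, 2**31 - 1, size=int(n))
        for s in seeds:
            out.append(
                sample_subject(group, config.calibration, int(s), spacing_mm=config.spacing_mm)
            )
    return out


COVARIATE_COLUMNS = (
    list(cal.GAUSSIAN_COVARIATES) + list(cal.BINARY_COVARIATES) + list(cal.LOGNORMAL_COVARIATES)
)
INDEX_COLUMNS = ("lav_ml", "lavi_ml_m2", "lawv_ml", "lawt_mm", "lawt_sd_mm")


def generate_cohort(config: CohortConfig, out_dir, seed: int) -> dict:
    """Write one labeled NIfTI per subject, a cohort CSV and a JSON manifest.

    The CSV wall-index columns are left empty for the wall-mapping stage
    to fill.  The manifest records the seed, a config hash and the
    per-subject analytic ground truth.  On failure every file written so
    far is removed before the error propagates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        subjects = sample_cohort_params(config, seed)
        ids = []
        counters: dict[str, int] = {}
        for p in subjects:
            k = counters.get(p.group, 0)
            counters[p.group] = k + 1
            ids.append(f"{p.group}_{k:03d}")
        if len(set(ids)) != len(ids):
            raise PhantomError(f"duplicate subject ids generated: {ids}")

        rows = []
        manifest_subjects = []
        for sid, params in zip(ids, subjects):
            n = required_grid_shape(params, config.spacing_mm, config.base_shape)
            grid = GridSpec.centered((n, n, n), config.spacing_mm)
            vol, truth = build_phantom(params, grid)
            vol_path = out_dir / f"{sid}_labels.nii.gz"
            vol.save(vol_path)
            created.append(vol_path)
            row = {"id": sid, "group": params.group, "bsa_m2": params.bsa_m2}
            row.update(params.covariates)
            row.update({c: np.nan for c in INDEX_COLUMNS})
            rows.append(row)
            manifest_subjects.append(
                {
                    "id": sid,
                    "group": params.group,
                    "seed": params.seed,
                    "grid_shape": list(grid.shape),
                    "volume_file": vol_path.name,
                    "bsa_m2": params.bsa_m2,
                    "mapped_fraction": params.mapped_fraction,
                    "target_indices": params.target_indices,
                    "ground_truth": truth.to_dict(),
                }
            )

        table_path = out_dir / "cohort.csv"
        cols = ["id", "group", "bsa_m2"] + COVARIATE_COLUMNS + list(INDEX_COLUMNS)
        pd.DataFrame(rows, columns=cols).to_csv(table_path, index=False)
        created.append(table_path)
        manifest = {
            "seed": int(seed),
            "config_hash": config.config_hash,
            "config": config.to_jsonable(),
            "n_subjects": len(subjects),
            "subjects": manifest_subjects,
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        created.append(manifest_path)
        return manifest
    except BaseException:
        for p in created:
            try:
                p.unlink()
            except OSError:
                pass
        raise
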