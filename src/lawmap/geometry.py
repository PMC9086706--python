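"""Continuous geometry for LA-like phantoms.

The phantom chamber is an ellipsoid; the wall is swept from the
endocardial (inner) surface along the outward normal by a direction-
dependent thickness field.  Everything here is exact continuous
geometry: foot-point projection onto the ellipsoid, principal-curvature
sums, and curvature-corrected quadrature of the offset-shell volume in
normal coordinates,

    V(region) = int_region [ T + T^2 (k1+k2)/2 + T^3 k1 k2 / 3 ] dA,

which is the exact volume of the normal offset solid as long as the
offset stays below the minimal radius of curvature (no self-
intersection).  Directions are parameterised by the unit sphere via
s(u) = (a u1, b u2, c u3).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import math

import numpy as np
from numpy.polynomial.legendre import leggauss


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid centred at the origin; semi-axes in mm."""

    semi_axes: tuple[float, float, float]

    def __post_init__(self):
        a = np.asarray(self.semi_axes, dtype=float)
        if a.shape != (3,) or not np.all(a > 0):
            raise GeometryError(f"semi-axes must be 3 positive reals, got {self.semi_axes}")

    @property
    def axes(self) -> np.ndarray:
        return np.asarray(self.semi_axes, dtype=float)

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def min_curvature_radius_mm(self) -> float:
        """Smallest principal radius of curvature over the surface (a_min^2/a_max)."""
        a = self.axes
        return float(a.min() ** 2 / a.max())

    def quadratic_form(self, pts: np.ndarray) -> np.ndarray:
        """q(x) = sum (x_i/a_i)^2; q<=1 inside."""
        pts = np.asarray(pts, dtype=float)
        return ((pts / self.axes) ** 2).sum(axis=-1)

    def surface_points(self, u: np.ndarray) -> np.ndarray:
        """Map unit directions u to surface points s(u) = axes * u."""
        return np.asarray(u, dtype=float) * self.axes

    def area_element(self, u: np.ndarray) -> np.ndarray:
        """dA/dOmega for the unit-sphere parameterisation: abc*|u/a|."""
        u = np.asarray(u, dtype=float)
        a = self.axes
        return float(np.prod(a)) * np.sqrt(((u / a) ** 2).sum(axis=-1))

    def curvatures(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (k1+k2, k1*k2) at surface points s(u), outward orientation.

        Implicit-surface formulas for F = sum x_i^2/a_i^2 - 1 with
        grad F = 2 x/a^2 and Hessian 2 diag(1/a^2).
        """
        a2 = self.axes**2
        x = self.surface_points(u)
        g = 2.0 * x / a2
        gn2 = (g**2).sum(axis=-1)
        gn = np.sqrt(gn2)
        h_diag = 2.0 / a2
        tr_h = h_diag.sum()
        ghg = (g**2 * h_diag).sum(axis=-1)
        sum_k = (gn2 * tr_h - ghg) / (gn2 * gn)
        adj_diag = np.array(
            [h_diag[1] * h_diag[2], h_diag[0] * h_diag[2], h_diag[0] * h_diag[1]]
        )
        gadjg = (g**2 * adj_diag).sum(axis=-1)
        gauss_k = gadjg / gn2**2
        return sum_k, gauss_k

    def foot_points(self, pts: np.ndarray, n_iter: int = 30, tol: float = 1e-12):
        """Nearest-surface-point projection for points outside the ellipsoid.

        Solves the Lagrange condition p_i = a_i^2 x_i/(t + a_i^2) with the
        largest root of f(t) = sum (a_i x_i/(t+a_i^2))^2 - 1.  f is
        decreasing and convex for t > -a_min^2, so Newton from t=0
        (where f >= 0 for exterior points) converges monotonically.

        Returns (foot, dist, u): surface points, Euclidean distances,
        and unit-sphere parameters of the feet.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        a = self.axes
        a2 = a**2
        ax2 = (a * pts) ** 2  # (a_i x_i)^2
        t = np.zeros(len(pts))
        inv = np.empty_like(ax2)
        for _ in range(n_iter):
            np.add(t[:, None], a2, out=inv)
            np.reciprocal(inv, out=inv)
            w = ax2 * inv  # (a_i x_i)^2 / (t + a_i^2)
            f = np.einsum("ij,ij->i", w, inv) - 1.0
            fp = -2.0 * np.einsum("ij,ij,ij->i", w, inv, inv)
            t -= f / fp
            if np.max(np.abs(f)) < tol:
                break
        foot = a2 * pts / (t[:, None] + a2)
        diff = pts - foot
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        u = foot / a
        u /= np.sqrt(np.einsum("ij,ij->i", u, u))[:, None]
        return foot, dist, u


@dataclass(frozen=True)
class PatchSpec:
    """One Gaussian surface bump: unit-sphere centre, angular width, amplitude."""

    center: tuple[float, float, float]
    width_rad: float
    amplitude: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        n = np.linalg.norm(c)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-6:
            raise GeometryError(f"patch centre must be a unit vector, |c|={n}")
        if self.width_rad <= 0:
            raise GeometryError("patch width must be positive")


def patch_field(patches, u: np.ndarray) -> np.ndarray:
    """Raw (pre-scaling) bump-sum field P0(u) on unit directions u."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if not patches:
        return np.zeros(len(u))
    centers = np.array([p.center for p in patches], dtype=float)  # (k,3)
    widths = np.array([p.width_rad for p in patches], dtype=float)
    amps = np.array([p.amplitude for p in patches], dtype=float)
    theta = np.arccos(np.clip(u @ centers.T, -1.0, 1.0))  # (n,k)
    return np.exp(-0.5 * (theta / widths) ** 2) @ amps


@dataclass(frozen=True)
class ThicknessField:
    """T(u) = mu + sigma * (P0(u) - offset) / scale on the unit sphere.

    offset/scale are the area-weighted mean and SD of the raw bump field
    over the mapped region, so T has area-mean mu and area-SD sigma there
    by construction.  With sigma == 0 the field is identically mu.
    """

    mu: float
    sigma: float
    patches: tuple
    offset: float = 0.0
    scale: float = 1.0

    def __call__(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(np.asarray(u, dtype=float))
        if self.sigma == 0.0 or not self.patches:
            return np.full(len(u), self.mu)
        return self.mu + self.sigma * (patch_field(self.patches, u) - self.offset) / self.scale


@dataclass(frozen=True)
class CapSet:
    """Spherical exclusion caps (PV ostia + annulus) in direction space."""

    directions: tuple  # of unit 3-tuples
    apertures: tuple  # radians

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise GeometryError("cap directions must be (k,3)")
        if len(self.apertures) != len(self.directions):
            raise GeometryError("one aperture per cap direction required")

    def contains(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(np.asarray(u, dtype=float))
        out = np.zeros(len(u), dtype=bool)
        for d, alpha in zip(self.directions, self.apertures):
            out |= u @ np.asarray(d, dtype=float) >= math.cos(alpha)
        return out

    def check_disjoint(self):
        d = np.asarray(self.directions, dtype=float)
        al = np.asarray(self.apertures, dtype=float)
        for i in range(len(d)):
            for j in range(i + 1, len(d)):
                sep = math.acos(float(np.clip(d[i] @ d[j], -1, 1)))
                if sep <= al[i] + al[j]:
                    raise GeometryError(
                        f"caps {i} and {j} overlap: separation {sep:.3f} rad "
                        f"<= aperture sum {al[i] + al[j]:.3f} rad"
                    )


# Anatomically plausible fixed cap directions: four PV ostia on the
# posterosuperior aspect (polar 50 deg, azimuths 45/135/225/315 deg) and
# one mitral-annulus cap at the inferior pole.  Base apertures are scaled
# jointly to reach a requested mapped fraction.
def default_cap_layout():
    pol = math.radians(50.0)
    dirs = []
    for az_deg in (45.0, 135.0, 225.0, 315.0):
        az = math.radians(az_deg)
        dirs.append((math.sin(pol) * math.cos(az), math.sin(pol) * math.sin(az), math.cos(pol)))
    dirs.append((0.0, 0.0, -1.0))
    base = (0.4, 0.4, 0.4, 0.4, 0.8)
    return tuple(dirs), base


# largest joint scale keeping the default caps pairwise disjoint
MAX_CAP_SCALE = 1.40


@lru_cache(maxsize=32)
def _leggauss_cached(n: int):
    return leggauss(n)


@lru_cache(maxsize=8)
def _sphere_nodes(n_theta: int, n_phi: int):
    z, wz = _leggauss_cached(n_theta)
    phi = (np.arange(n_phi) + 0.5) * (2.0 * math.pi / n_phi)
    wphi = 2.0 * math.pi / n_phi
    zz = np.repeat(z, n_phi)
    pp = np.tile(phi, n_theta)
    sin_t = np.sqrt(1.0 - zz**2)
    nodes = np.column_stack([sin_t * np.cos(pp), sin_t * np.sin(pp), zz])
    weights = np.repeat(wz, n_phi) * wphi
    return nodes, weights


class SphereQuadrature:
    """Quadrature nodes/weights integrating f(u) dOmega over a spherical region."""

    def __init__(self, nodes: np.ndarray, weights: np.ndarray):
        self.nodes = nodes
        self.weights = weights

    @classmethod
    def full(cls, n_theta: int = 48, n_phi: int = 96) -> "SphereQuadrature":
        nodes, weights = _sphere_nodes(n_theta, n_phi)
        return cls(nodes, weights)

    @classmethod
    def cap(cls, direction, aperture: float, n_r: int = 24, n_phi: int = 48) -> "SphereQuadrature":
        """Gauss-Legendre in cos(gamma) on [cos(aperture), 1] x uniform azimuth."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        # orthonormal frame around d
        helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        zg, wz = _leggauss_cached(n_r)
        lo = math.cos(aperture)
        cg = 0.5 * (zg + 1.0) * (1.0 - lo) + lo
        wcg = wz * 0.5 * (1.0 - lo)
        phi = (np.arange(n_phi) + 0.5) * (2.0 * math.pi / n_phi)
        wphi = 2.0 * math.pi / n_phi
        cgg = np.repeat(cg, n_phi)
        pp = np.tile(phi, n_r)
        sg = np.sqrt(np.clip(1.0 - cgg**2, 0.0, None))
        nodes = (
            cgg[:, None] * d[None, :]
            + sg[:, None] * (np.cos(pp)[:, None] * e1[None, :] + np.sin(pp)[:, None] * e2[None, :])
        )
        weights = np.repeat(wcg, n_phi) * wphi
        return cls(nodes, weights)


def shell_region_integrals(
    ellipsoid: Ellipsoid,
    quad: SphereQuadrature,
    patches=(),
    raw_field: np.ndarray | None = None,
) -> dict:
    """Area, raw-field moments and curvature data over a quadrature region.

    Returns a dict with the region area, integral of P0 and P0^2 (area-
    weighted), per-node area weights, raw field values and curvature sums
    so callers can assemble offset-shell volumes for any (mu, sigma,
    offset, scale) without re-evaluating the bumps.
    """
    u = quad.nodes
    da = ellipsoid.area_element(u) * quad.weights
    p0 = patch_field(patches, u) if raw_field is None else raw_field
    sum_k, gauss_k = ellipsoid.curvatures(u)
    return {
        "area": float(da.sum()),
        "int_p": float((p0 * da).sum()),
        "int_p2": float((p0**2 * da).sum()),
        "da": da,
        "p0": p0,
        "sum_k": sum_k,
        "gauss_k": gauss_k,
        "p_min": float(p0.min()) if len(p0) else 0.0,
        "p_max": float(p0.max()) if len(p0) else 0.0,
    }


def shell_volume_from_integrals(data: dict, mu: float, sigma: float, offset: float, scale: float) -> float:
    """Exact offset-shell volume over the region described by `data`."""
    if sigma == 0.0:
        t = np.full_like(data["da"], mu)
    else:
        t = mu + sigma * (data["p0"] - offset) / scale
    col = t + t**2 * data["sum_k"] / 2.0 + t**3 * data["gauss_k"] / 3.0
    return float((col * data["da"]).sum())


def shell_volume_moments(data: dict) -> dict:
    """Moments turning the offset-shell volume into a polynomial in (a, b)
    for T = a + b*P: V = sum_m a-b-monomials times int P^m {1, H, K} dA."""
    da, p0 = data["da"], data["p0"]
    h2 = data["sum_k"] / 2.0
    k3 = data["gauss_k"] / 3.0
    pw = {0: np.ones_like(p0), 1: p0, 2: p0**2, 3: p0**3}
    return {
        "lin": [float((pw[m] * da).sum()) for m in range(2)],
        "quad": [float((pw[m] * h2 * da).sum()) for m in range(3)],
        "cub": [float((pw[m] * k3 * da).sum()) for m in range(4)],
    }


def shell_volume_from_moments(mom: dict, mu: float, sigma: float, offset: float, scale: float) -> float:
    if sigma == 0.0:
        a, b = mu, 0.0
    else:
        a, b = mu - sigma * offset / scale, sigma / scale
    lin, quad, cub = mom["lin"], mom["quad"], mom["cub"]
    v = a * lin[0] + b * lin[1]
    v += a**2 * quad[0] + 2 * a * b * quad[1] + b**2 * quad[2]
    v += a**3 * cub[0] + 3 * a**2 * b * cub[1] + 3 * a * b**2 * cub[2] + b**3 * cub[3]
    return float(v)


def normalisation_over_region(area: float, int_p: float, int_p2: float) -> tuple[float, float]:
    """Area-weighted mean and SD of the raw bump field over a region."""
    m = int_p / area
    var = int_p2 / area - m**2
    return m, math.sqrt(max(var, 0.0))
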