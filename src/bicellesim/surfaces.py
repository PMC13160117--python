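"""Membrane surface parameterizations and orientation grids.

Three axisymmetric surfaces carry the lipids whose anisotropic NMR
frequencies are simulated:

* the *bicelle rim* -- a half ellipse (semi-axes ``b`` along z, ``d`` along
  x) revolved about the z axis at disc radius ``R``;
* the *toroidal pore* -- the same elliptic cross-section revolved on the
  inside of a pore of narrowest radius ``a``;
* the *cosine dimple* -- a locally thinned patch of the flat disc,
  ``z(x) = -(depth/2)(1 + cos(pi x / a))``.

Each surface yields a surface-element weight ``p(Omega)`` (the lineshape
factor: the product of the meridional and azimuthal metric factors) and a
corrected normal tilt used for the frequency of a lipid at that site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RimGeometry",
    "PoreGeometry",
    "DimpleGeometry",
    "FlatDisc",
    "OrientationGrid",
    "rim_r",
    "rim_weight",
    "pore_weight",
    "normal_angle",
    "dimple_profile",
    "build_grid",
]


@dataclass(frozen=True)
class RimGeometry:
    """Elliptic bicelle rim: half bilayer thickness b (z semi-axis), rim
    semi-axis d (x), flat-disc radius R (all nm)."""

    b: float
    d: float
    R: float

    def __post_init__(self) -> None:
        if self.b <= 0 or self.d <= 0:
            raise ValueError("rim semi-axes b, d must be positive")
        if self.R <= self.d:
            raise ValueError(
                f"degenerate rim geometry: need R > d, got R={self.R}, d={self.d}")


@dataclass(frozen=True)
class PoreGeometry:
    """Inner surface of a toroidal pore: narrowest radius a, elliptic
    cross-section semi-axes b (z) and d (x), all nm."""

    a: float
    b: float
    d: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("pore radius a must be >= 0")
        if self.b <= 0 or self.d <= 0:
            raise ValueError("cross-section semi-axes b, d must be positive")


@dataclass(frozen=True)
class DimpleGeometry:
    """Axisymmetric cosine thinning dimple of rim radius a (nm) and central
    depth ``depth`` (nm); depth/a is the thinning ratio, 0 = flat disc."""

    a: float
    depth: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("dimple radius a must be positive")
        if self.depth < 0:
            raise ValueError("dimple depth must be >= 0")

    @property
    def depth_ratio(self) -> float:
        return self.depth / self.a


@dataclass(frozen=True)
class FlatDisc:
    """Undistorted planar bilayer patch (single orientation)."""


@dataclass
class OrientationGrid:
    """Discretized lipid sites on one surface.

    ``positions`` is the meridional coordinate per distinct meridian site
    (theta in degrees for rim/pore, x in nm for the dimple).  For
    two-dimensional grids (``n_phi > 1``) sites are stored flattened with
    the meridian index fastest, azimuthal block index p slowest, i.e. the
    site (j, p) sits at flat index p*n_theta + j.

    ``h_par``/``h_azi`` are the meridional and azimuthal metric factors at
    the meridian sites; their product is the lineshape weight p(Omega).
    ``spacing`` is the meridional coordinate step (radians or nm) and
    ``scale_m`` the metres-per-length-unit conversion (None in qualitative,
    relative-rate mode).
    """

    positions: np.ndarray
    normal_angles: np.ndarray
    h_par: np.ndarray
    h_azi: np.ndarray
    spacing: float
    n_theta: int
    n_phi: int = 1
    phi_deg: np.ndarray = field(default_factory=lambda: np.zeros(1))
    geometry_tag: str = ""
    scale_m: float | None = None

    @property
    def n_sites(self) -> int:
        return self.n_theta * self.n_phi

    @property
    def weights(self) -> np.ndarray:
        """Per-site weight p(Omega), flattened over (phi block, meridian)."""
        w = self.h_par * self.h_azi
        return np.tile(w, self.n_phi)

    @property
    def site_normal_angles(self) -> np.ndarray:
        return np.tile(self.normal_angles, self.n_phi)

    @property
    def site_phi(self) -> np.ndarray:
        return np.repeat(self.phi_deg, self.n_theta)


def rim_r(geometry, theta_deg):
    """Elliptic radius r(theta) = b d / sqrt(b^2 sin^2 + d^2 cos^2), nm."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    b, d = geometry.b, geometry.d
    return b * d / np.sqrt(b**2 * np.sin(th) ** 2 + d**2 * np.cos(th) ** 2)


def _ellipse_correction(b: float, d: float, theta_deg) -> np.ndarray:
    """sqrt(1 + (r^4/4) sin^2(2 theta) (1/d^2 - 1/b^2)^2): the meridional
    stretch of the elliptic arc relative to the circular one."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    r = np.asarray(rim_r(_Axes(b, d), theta_deg), dtype=float)
    return np.sqrt(1.0 + r**4 / 4.0 * np.sin(2 * th) ** 2
                   * (1.0 / d**2 - 1.0 / b**2) ** 2)


@dataclass(frozen=True)
class _Axes:
    b: float
    d: float


def rim_meridian_metric(geometry, theta_deg):
    """h_theta(theta) = r * elliptic correction (nm per radian)."""
    r = rim_r(geometry, theta_deg)
    return r * _ellipse_correction(geometry.b, geometry.d, theta_deg)


def rim_azimuthal_metric(geometry: RimGeometry, theta_deg):
    """h_phi = R + r sin(theta): radius of the azimuthal circle, nm."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    return geometry.R + rim_r(geometry, theta_deg) * np.sin(th)


def pore_azimuthal_metric(geometry: PoreGeometry, theta_deg):
    """h_phi = a + d - r sin(theta) for the inner pore surface, nm."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    return geometry.a + geometry.d - rim_r(geometry, theta_deg) * np.sin(th)


def rim_weight(geometry: RimGeometry, theta_deg):
    """Lineshape weight p(Omega) on the rim; b = d reduces to
    b (R + b sin theta)."""
    return rim_meridian_metric(geometry, theta_deg) \
        * rim_azimuthal_metric(geometry, theta_deg)


def pore_weight(geometry: PoreGeometry, theta_deg):
    """Lineshape weight on the pore; b = d reduces to b (a + b - b sin theta)."""
    return rim_meridian_metric(geometry, theta_deg) \
        * pore_azimuthal_metric(geometry, theta_deg)


def normal_angle(geometry, theta_deg):
    """Corrected tilt theta' = atan2(b^2 sin theta, d^2 cos theta), degrees.

    On an elliptic (b != d) cross-section the surface normal is no longer
    radial; theta' is the tilt of the true outward normal, used for the
    lipid orientation while the parametric theta indexes the site.
    Quadrant-aware, so theta' runs over [0, 180] like theta.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    b, d = geometry.b, geometry.d
    return np.rad2deg(np.arctan2(b**2 * np.sin(th), d**2 * np.cos(th)))


def dimple_profile(geometry: DimpleGeometry, x):
    """Depth z(x), local tilt theta(x) (degrees) and weight p at radius x.

    z(x) = -(depth/2)(1 + cos(pi x/a)) is deepest (-depth) at the centre and
    0 at the rim; the tilt theta(x) = atan((pi depth / 2a) sin(pi x/a))
    vanishes at both, and p = x * sqrt(1 + tan^2 theta).
    """
    xv = np.asarray(x, dtype=float)
    a, depth = geometry.a, geometry.depth
    if np.any(xv < 0) or np.any(xv > a):
        raise ValueError(f"x must lie in [0, {a}] nm")
    slope = (np.pi * depth / (2 * a)) * np.sin(np.pi * xv / a)
    z = -(depth / 2.0) * (1.0 + np.cos(np.pi * xv / a))
    theta = np.rad2deg(np.arctan(slope))
    p = xv * np.sqrt(1.0 + slope**2)
    return z, theta, p


def dimple_meridian_metric(geometry: DimpleGeometry, x):
    xv = np.asarray(x, dtype=float)
    slope = (np.pi * geometry.depth / (2 * geometry.a)) \
        * np.sin(np.pi * xv / geometry.a)
    return np.sqrt(1.0 + slope**2)


def build_grid(geometry, n_theta: int, n_phi: int = 1,
               mode: str = "n_parallel_B") -> OrientationGrid:
    """Cell-centred uniform grid over the surface's parametric coordinate.

    The meridian ([0, 180] deg for rim/pore, [0, a] nm for the dimple) is
    split into ``n_theta`` equal cells sampled at their midpoints, so the
    per-site weight is exactly p(Omega) at the sampled coordinate and no
    site carries zero weight.  For ``n_parallel_B`` the azimuth is
    irrelevant and ``n_phi`` is ignored; otherwise ``n_phi`` azimuthal
    blocks cover [0, 360) degrees.
    """
    if isinstance(geometry, FlatDisc):
        return OrientationGrid(
            positions=np.array([0.0]), normal_angles=np.array([0.0]),
            h_par=np.array([1.0]), h_azi=np.array([1.0]), spacing=1.0,
            n_theta=1, n_phi=1, geometry_tag="flat_disc")
    if n_theta < 2:
        raise ValueError("n_theta must be >= 2")
    if n_phi < 1:
        raise ValueError("n_phi must be >= 1")
    if mode == "n_parallel_B":
        n_phi = 1
    phi = np.arange(n_phi) * 360.0 / n_phi

    if isinstance(geometry, DimpleGeometry):
        dx = geometry.a / n_theta
        x = (np.arange(n_theta) + 0.5) * dx
        _, tilt, _ = dimple_profile(geometry, x)
        return OrientationGrid(
            positions=x, normal_angles=tilt,
            h_par=dimple_meridian_metric(geometry, x), h_azi=x,
            spacing=dx, n_theta=n_theta, n_phi=n_phi, phi_deg=phi,
            geometry_tag="dimple")

    if isinstance(geometry, (RimGeometry, PoreGeometry)):
        dth = 180.0 / n_theta
        theta = (np.arange(n_theta) + 0.5) * dth
        h_par = rim_meridian_metric(geometry, theta)
        if isinstance(geometry, RimGeometry):
            h_azi = rim_azimuthal_metric(geometry, theta)
            tag = "rim"
        else:
            h_azi = pore_azimuthal_metric(geometry, theta)
            tag = "pore"
        if np.any(h_azi <= 0) or np.any(h_par <= 0):
            bad = int(np.argmax((h_azi <= 0) | (h_par <= 0)))
            raise ValueError(
                f"zero or negative metric factor at theta={theta[bad]:.2f} deg")
        return OrientationGrid(
            positions=theta, normal_angles=np.asarray(normal_angle(geometry, theta)),
            h_par=np.asarray(h_par), h_azi=np.asarray(h_azi),
            spacing=np.deg2rad(dth), n_theta=n_theta, n_phi=n_phi,
            phi_deg=phi, geometry_tag=tag)

    raise TypeError(f"unsupported geometry {type(geometry).__name__}")
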