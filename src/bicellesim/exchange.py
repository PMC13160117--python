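"""Lateral-diffusion exchange matrices and Bloch-McConnell propagation.

Lateral diffusion of lipids over a curved surface is Fick's second law for
the transverse magnetization.  On a discretized orientation grid it becomes
a continuous-time random walk between nearest-neighbour sites: writing
g = h_azi/h_par for the meridional conductance density and w = h_par*h_azi
(= p(Omega)) for the site weight, the link conductance between cells j and
j+1 is C = D (g_j + g_{j+1}) / (2 du^2) and the jump rates are
k(j->j+1) = C / w_j, k(j+1->j) = C / w_{j+1}.  These rates keep the total
magnetization exactly conserved (zero column sums), leave the equilibrium
distribution Meq proportional to p(Omega) stationary, and collapse to the
symmetric nearest-neighbour rates of the flat chain (D/ds^2) when the
weights are uniform.  Azimuthal jumps on an axisymmetric surface are the
usual ring diffusion D/(h_azi dphi)^2, periodic in phi.

The free induction decay follows from dM+/dt = L M+ with
L = K + 2 pi i diag(nu) - T2inv I, solved by eigendecomposition
M+(t) = V exp(lambda t) V^{-1} Meq and summation over sites, with a
step-wise matrix-exponential fallback when the eigenbasis is
ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .surfaces import OrientationGrid

__all__ = ["ExchangeSystem", "jump_rates", "assemble_1d", "assemble_2d",
           "propagate", "discrete_rim_grid"]

#: refuse to build dense supermatrices beyond this many sites
MAX_SITES_DEFAULT = 6400

#: condition-number threshold for falling back to expm stepping
COND_LIMIT = 1e10


def jump_rates(grid: OrientationGrid, d_ld: float):
    """Nearest-neighbour meridional and azimuthal jump rates, s^-1.

    Returns ``(k_up, k_down, k_phi)``: ``k_up[j]`` is the rate j -> j+1
    (zero at the last site), ``k_down[j]`` the rate j -> j-1 (zero at the
    first site: reflecting boundaries), and ``k_phi[j]`` the rate of a
    +/- azimuthal step at meridian site j (periodic in phi).

    ``d_ld`` is in m^2/s when the grid carries a metric scale
    (``grid.scale_m``), otherwise a relative rate with the grid's own
    length unit.
    """
    if d_ld < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    h_par = np.asarray(grid.h_par, dtype=float)
    h_azi = np.asarray(grid.h_azi, dtype=float)
    if np.any(h_par == 0) or np.any(h_azi == 0):
        bad = int(np.argmax((h_par == 0) | (h_azi == 0)))
        raise ValueError(
            f"zero metric factor at site {bad} "
            f"(position {grid.positions[bad]:.4g}); refine or shift the grid")
    scale = grid.scale_m if grid.scale_m is not None else 1.0
    d_eff = d_ld / scale**2  # rates in s^-1 with lengths in grid units
    g = h_azi / h_par
    w = h_par * h_azi
    n = grid.n_theta
    k_up = np.zeros(n)
    k_down = np.zeros(n)
    if n >= 2:
        cond = d_eff * 0.5 * (g[:-1] + g[1:]) / grid.spacing**2
        k_up[:-1] = cond / w[:-1]
        k_down[1:] = cond / w[1:]
    if grid.n_phi > 1:
        dphi = 2.0 * np.pi / grid.n_phi
        k_phi = d_eff / (h_azi * dphi) ** 2
    else:
        k_phi = np.zeros(n)
    return k_up, k_down, k_phi


@dataclass
class ExchangeSystem:
    """Exchange matrix over an orientation grid plus its site data.

    ``frequencies`` are the per-site anisotropic frequencies in Hz (positive
    quadrupolar branch), flattened in grid order; ``meq`` the equilibrium
    populations (normalized to 1 by default).
    """

    grid: OrientationGrid
    frequencies: np.ndarray
    d_ld: float = 0.0
    t2_inv: float = 0.0
    meq: np.ndarray | None = None
    max_sites: int = MAX_SITES_DEFAULT
    L: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n_sites = self.grid.n_sites
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size != n_sites:
            raise ValueError("one frequency per grid site required")
        if self.meq is None:
            w = self.grid.weights.astype(float)
            self.meq = w / w.sum()
        else:
            self.meq = np.asarray(self.meq, dtype=float)
            if self.meq.size != n_sites:
                raise ValueError("meq size mismatch")
        if self.grid.n_phi > 1:
            self.L = assemble_2d(self)
        else:
            self.L = assemble_1d(self)

    def propagate(self, dwell_s: float, n_points: int) -> np.ndarray:
        return propagate(self, dwell_s, n_points)


def _rate_matrix_1d(k_up: np.ndarray, k_down: np.ndarray) -> np.ndarray:
    n = k_up.size
    k = np.zeros((n, n))
    idx = np.arange(n - 1)
    k[idx + 1, idx] = k_up[:-1]
    k[idx, idx + 1] = k_down[1:]
    k[idx, idx] -= k_up[:-1]
    k[idx + 1, idx + 1] -= k_down[1:]
    return k


def assemble_1d(system: ExchangeSystem) -> np.ndarray:
    """Tridiagonal complex exchange matrix for a single meridian chain.

    The diagonal carries 2*pi*i*nu_j - T2inv minus the total leaving rate;
    off-diagonals are the arrival rates from the neighbouring sites.
    """
    grid = system.grid
    if grid.n_phi != 1:
        raise ValueError("assemble_1d requires an azimuth-free grid")
    k_up, k_down, _ = jump_rates(grid, system.d_ld)
    k = _rate_matrix_1d(k_up, k_down)
    return (k.astype(complex)
            + np.diag(2j * np.pi * system.frequencies
                      - system.t2_inv * np.ones(grid.n_theta)))


def assemble_2d(system: ExchangeSystem) -> np.ndarray:
    """Block supermatrix for a theta x phi grid (native n-perpendicular-B).

    m azimuthal blocks of the n-site meridian chain; azimuthal jumps couple
    site (j, p) to (j, p +/- 1) with a periodic wrap, at the ring-diffusion
    rate for that meridian site.
    """
    grid = system.grid
    n, m = grid.n_theta, grid.n_phi
    if n * m > system.max_sites:
        raise MemoryError(
            f"{n}x{m} grid exceeds the {system.max_sites}-site cap; "
            "reduce n_theta/n_phi or raise max_sites")
    k_up, k_down, k_phi = jump_rates(grid, system.d_ld)
    k1 = _rate_matrix_1d(k_up, k_down)
    big = np.zeros((n * m, n * m))
    for p in range(m):
        sl = slice(p * n, (p + 1) * n)
        big[sl, sl] = k1
    if m > 1:
        for p in range(m):
            q = (p + 1) % m
            rows = np.arange(q * n, (q + 1) * n)
            cols = np.arange(p * n, (p + 1) * n)
            big[rows, cols] += k_phi
            big[cols, cols] -= k_phi
            big[cols, rows] += k_phi
            big[rows, rows] -= k_phi
    return (big.astype(complex)
            + np.diag(2j * np.pi * system.frequencies
                      - system.t2_inv * np.ones(n * m)))


def propagate(system: ExchangeSystem, dwell_s: float,
              n_points: int) -> np.ndarray:
    """Free induction decay: sum over sites of exp(L t) Meq at t = k*dwell.

    The eigendecomposition path is exact up to conditioning; if the eigenvector
    matrix is ill-conditioned (cond > 1e10) the FID is instead built by
    repeated application of the single-dwell propagator expm(L*dwell).
    """
    if dwell_s <= 0:
        raise ValueError("dwell must be positive")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    L = system.L
    meq = system.meq.astype(complex)
    lam, vec = linalg.eig(L)
    if not np.all(np.isfinite(lam)):
        raise FloatingPointError(
            f"non-finite exchange eigenvalues on {system.grid.geometry_tag} "
            f"grid ({system.grid.n_theta}x{system.grid.n_phi})")
    cond = np.linalg.cond(vec)
    t = np.arange(n_points) * dwell_s
    if np.isfinite(cond) and cond < COND_LIMIT:
        coef = np.linalg.solve(vec, meq) * vec.sum(axis=0)
        return np.exp(np.outer(t, lam)) @ coef
    # ill-conditioned eigenbasis: step with the matrix exponential
    prop = linalg.expm(L * dwell_s)
    fid = np.empty(n_points, dtype=complex)
    m = meq.copy()
    for i in range(n_points):
        fid[i] = m.sum()
        m = prop @ m
    return fid


def discrete_rim_grid(alphas_deg, x_nm, b: float, d: float,
                      n_phi: int = 1, absolute: bool = True) -> OrientationGrid:
    """Grid of discrete lipid rings on the rim, spaced in arclength.

    ``alphas_deg``/``x_nm`` come from :func:`bicellesim.packing.ring_table`;
    the meridional coordinate is the arclength (uniform step) and the
    azimuthal metric the ring radius x, so the geometric weights are
    proportional to the ring circumferences (and hence to the tabulated
    ring populations).  Explicit integer populations can be passed to
    :class:`ExchangeSystem` as ``meq``.  With ``absolute`` the nm metric is
    tied to metres so a lateral diffusion coefficient in m^2/s gives rates
    in s^-1.
    """
    alphas = np.asarray(alphas_deg, dtype=float)
    x = np.asarray(x_nm, dtype=float)
    if alphas.size != x.size or alphas.size < 2:
        raise ValueError("need >= 2 matching ring positions")
    # normal tilt of the ellipse at parametric angle alpha:
    # tan(theta') = (b/d) tan(alpha)
    tilt = np.rad2deg(np.arctan2(b * np.sin(np.deg2rad(alphas)),
                                 d * np.cos(np.deg2rad(alphas))))
    from .packing import arclength
    total = arclength(b, d, 180.0)
    ds = total / (alphas.size - 1)
    return OrientationGrid(
        positions=alphas, normal_angles=tilt,
        h_par=np.ones_like(x), h_azi=x, spacing=ds,
        n_theta=alphas.size, n_phi=n_phi,
        phi_deg=np.arange(n_phi) * 360.0 / n_phi,
        geometry_tag="rim_discrete",
        scale_m=1e-9 if absolute else None)
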