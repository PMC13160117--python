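"""Motionally averaged interaction tensors and orientation-dependent frequencies.

Lipids in a fluid bilayer spin rapidly about their long axis, so the static
:sup:`31`\\ P chemical-shift-anisotropy (CSA) and :sup:`14`\\ N/:sup:`2`\\ H
first-order quadrupolar tensors are pre-averaged to axially symmetric
(``eta = 0``) effective tensors.  The anisotropic resonance frequency then
depends only on the angle between the effective unique axis (the local
bilayer normal) and the static field B0, entering through the zz element of
the tensor rotated into the laboratory frame.

Angles are degrees at the API and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InteractionTensor",
    "EulerRotation",
    "Orientation",
    "LARMOR_MHZ",
    "build_pas",
    "rotation_matrix",
    "lab_tensor",
    "zz_lab",
    "resonance_frequency",
    "motional_average",
]

#: Default Larmor frequencies (MHz) at 9.4 T.
LARMOR_MHZ = {"P31": 162.0, "N14": 28.9, "H2": 61.4}

_SPIN = {"P31": 0.5, "N14": 1.0, "H2": 1.0}


@dataclass(frozen=True)
class InteractionTensor:
    """Axially averaged CSA or first-order quadrupolar interaction tensor.

    Parameters
    ----------
    kind : {"csa", "quadrupolar"}
    magnitude : float
        Anisotropy: delta_CSA in ppm for CSA, Cq = e2qQ/h in Hz for
        quadrupolar.
    eta : float
        Asymmetry parameter in [0, 1]; 0 after motional averaging.
    iso : float
        Isotropic shift in ppm (CSA only; 0 for quadrupolar, trace-free EFG).
    larmor_mhz : float
        Larmor frequency nu0 in MHz, used to convert ppm to Hz.
    spin : float
        Nuclear spin quantum number (1/2 for 31P, 1 for 14N/2H).
    """

    kind: str
    magnitude: float
    eta: float = 0.0
    iso: float = 0.0
    larmor_mhz: float = 162.0
    spin: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("csa", "quadrupolar"):
            raise ValueError(f"unknown tensor kind {self.kind!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")
        if self.kind == "quadrupolar" and self.iso != 0.0:
            raise ValueError("quadrupolar tensor is trace-free; iso must be 0")
        if self.larmor_mhz <= 0:
            raise ValueError("larmor_mhz must be positive")

    @classmethod
    def csa(cls, delta_ppm: float, iso_ppm: float = 0.0, eta: float = 0.0,
            larmor_mhz: float = LARMOR_MHZ["P31"]) -> "InteractionTensor":
        return cls("csa", delta_ppm, eta=eta, iso=iso_ppm,
                   larmor_mhz=larmor_mhz, spin=0.5)

    @classmethod
    def quadrupolar(cls, cq_hz: float, eta: float = 0.0,
                    larmor_mhz: float = LARMOR_MHZ["N14"],
                    spin: float = 1.0) -> "InteractionTensor":
        return cls("quadrupolar", cq_hz, eta=eta, iso=0.0,
                   larmor_mhz=larmor_mhz, spin=spin)

    @classmethod
    def for_nucleus(cls, nucleus: str, magnitude: float, eta: float = 0.0,
                    iso: float = 0.0,
                    larmor_mhz: float | None = None) -> "InteractionTensor":
        """Build the conventional tensor for ``P31`` (CSA) or ``N14``/``H2``
        (quadrupolar) with the default 9.4 T Larmor frequency."""
        if nucleus not in LARMOR_MHZ:
            raise ValueError(f"unknown nucleus {nucleus!r}")
        larmor = LARMOR_MHZ[nucleus] if larmor_mhz is None else larmor_mhz
        kind = "csa" if nucleus == "P31" else "quadrupolar"
        return cls(kind, magnitude, eta=eta, iso=iso if kind == "csa" else 0.0,
                   larmor_mhz=larmor, spin=_SPIN[nucleus])


@dataclass(frozen=True)
class EulerRotation:
    """Euler angles (degrees) in the zyz-type convention used throughout."""

    alpha: float
    beta: float
    gamma: float


@dataclass(frozen=True)
class Orientation:
    """Director orientation.

    ``theta`` is the polar angle of the local bilayer normal relative to B0
    in ``n_parallel_B`` mode, or relative to the disc normal in
    ``n_perpendicular_B`` mode (where the whole disc is additionally tipped
    by 90 degrees and ``phi`` matters).
    """

    theta: float
    phi: float = 0.0
    mode: str = "n_parallel_B"

    def __post_init__(self) -> None:
        if self.mode not in ("n_parallel_B", "n_perpendicular_B"):
            raise ValueError(f"unknown orientation mode {self.mode!r}")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")


def build_pas(tensor: InteractionTensor) -> np.ndarray:
    """Diagonal 3x3 tensor in its principal axis system.

    CSA: diag(dxx, dyy, dzz) in ppm with dzz = iso + delta,
    dyy - dxx = eta*delta and trace 3*iso.  Quadrupolar: the EFG in Cq (Hz)
    units, trace-free, Vzz = Cq; for eta = 0 this is Cq*diag(-1/2, -1/2, 1).
    """
    d, eta, iso = tensor.magnitude, tensor.eta, tensor.iso
    if tensor.kind == "csa":
        return np.diag([iso - d * (1 + eta) / 2.0,
                        iso - d * (1 - eta) / 2.0,
                        iso + d])
    return np.diag([-d * (1 + eta) / 2.0, -d * (1 - eta) / 2.0, d])


def rotation_matrix(rot: EulerRotation) -> np.ndarray:
    """Active rotation matrix U(alpha, beta, gamma); orthogonal, det +1."""
    a, b, g = np.deg2rad([rot.alpha, rot.beta, rot.gamma])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    return np.array([
        [ca * cb * cg - sa * sg, sa * cb * cg + ca * sg, -sb * cg],
        [-ca * cb * sg - sa * cg, -sa * cb * sg + ca * cg, sb * sg],
        [ca * sb, sa * sb, cb],
    ])


def _total_rotation(o: Orientation) -> np.ndarray:
    u_tilt = rotation_matrix(EulerRotation(0.0, o.theta, 0.0))
    if o.mode == "n_parallel_B":
        return u_tilt
    # native alignment: disc normal perpendicular to B0 -- compose the
    # site tilt with the (phi, 90, 0) frame change
    u_flip = rotation_matrix(EulerRotation(o.phi, 90.0, 0.0))
    return u_flip @ u_tilt


def lab_tensor(pas: np.ndarray, o: Orientation) -> np.ndarray:
    """Similarity-transform a PAS tensor into the laboratory frame."""
    u = _total_rotation(o)
    return u @ pas @ u.T


def zz_lab(tensor: InteractionTensor, theta_deg, phi_deg=0.0,
           mode: str = "n_parallel_B"):
    """Vectorized zz laboratory-frame element for grids of orientations.

    Since the PAS tensor is diagonal, zz_lab = sum_k R[2,k]^2 * lambda_k with
    R the composite PAS->lab rotation; only the third row is needed.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    ph = np.deg2rad(np.asarray(phi_deg, dtype=float))
    lam = np.diag(build_pas(tensor))
    if mode == "n_parallel_B":
        r3 = (np.sin(th), np.zeros_like(th + ph), np.cos(th))
    elif mode == "n_perpendicular_B":
        r3 = (np.cos(ph) * np.cos(th), np.sin(ph) * np.ones_like(th),
              -np.cos(ph) * np.sin(th))
    else:
        raise ValueError(f"unknown orientation mode {mode!r}")
    return lam[0] * r3[0] ** 2 + lam[1] * r3[1] ** 2 + lam[2] * r3[2] ** 2


def resonance_frequency(tensor: InteractionTensor, o: Orientation):
    """Anisotropic resonance frequency in Hz.

    CSA returns a single frequency nu = zz_lab(ppm) * nu0(MHz); the
    quadrupolar spin-1 interaction returns the (+, -) satellite pair
    nu = +/- (3/4) * Cq_zz_lab.
    """
    zz = float(zz_lab(tensor, o.theta, o.phi, o.mode))
    if tensor.kind == "csa":
        return zz * tensor.larmor_mhz
    nu = 0.75 * zz
    return (nu, -nu)


def frequency_grid(tensor: InteractionTensor, theta_deg, phi_deg=0.0,
                   mode: str = "n_parallel_B") -> np.ndarray:
    """Per-site frequency array in Hz (positive branch for quadrupolar)."""
    zz = zz_lab(tensor, theta_deg, phi_deg, mode)
    if tensor.kind == "csa":
        return zz * tensor.larmor_mhz
    return 0.75 * zz


def motional_average(eigenvalues, rotation_axis: str, kind: str = "csa",
                     larmor_mhz: float = LARMOR_MHZ["P31"],
                     spin: float = 0.5) -> InteractionTensor:
    """Average a full tensor under fast uniaxial rotation about one PAS axis.

    The component along the rotation axis survives as the unique value
    (d_par); the other two average to d_perp = (sum of the others)/2, so the
    trace is conserved and the result is axially symmetric (eta = 0).
    For rotation about y this is d_par = dyy, d_perp = (dxx + dzz)/2.
    """
    axes = {"x": 0, "y": 1, "z": 2}
    if rotation_axis not in axes:
        raise ValueError("rotation_axis must be one of 'x', 'y', 'z'")
    vals = np.asarray(eigenvalues, dtype=float)
    if vals.shape != (3,):
        raise ValueError("expected three principal values")
    i = axes[rotation_axis]
    d_par = vals[i]
    iso = vals.sum() / 3.0
    if kind == "quadrupolar":
        return InteractionTensor.quadrupolar(d_par - iso, eta=0.0,
                                             larmor_mhz=larmor_mhz, spin=spin)
    return InteractionTensor.csa(d_par - iso, iso_ppm=iso, eta=0.0,
                                 larmor_mhz=larmor_mhz)
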