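"""Spectrum assembly: component FIDs, apodization, FFT, axes, populations.

A simulated spectrum is the sum of independently propagated components
(curved rim and flat disc for a bicelle; the thinned dimple for a
membrane-thinning run), each normalized per molecule and scaled by its
population.  Quadrupolar (spin-1) doublets are built by propagating the
positive satellite and adding its mirror (the complex conjugate FID), so
spectra with zero isotropic shift are symmetric about zero to machine
precision.  Axes are kHz for quadrupolar interactions and ppm for CSA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import packing
from .config import SimulationConfig
from .exchange import ExchangeSystem, discrete_rim_grid
from .surfaces import (DimpleGeometry, FlatDisc, PoreGeometry, RimGeometry,
                       build_grid)
from .tensors import InteractionTensor, frequency_grid

__all__ = ["Spectrum", "fid_to_spectrum", "simulate", "simulate_bicelle",
           "simulate_dimple"]


@dataclass
class Spectrum:
    """Frequency axis, total intensity and named component sub-spectra."""

    axis: np.ndarray
    intensity: np.ndarray
    units: str
    components: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def area(self) -> float:
        df = self.axis[1] - self.axis[0]
        return float(self.intensity.sum() * df)

    def peak_position(self) -> float:
        """Axis value at the intensity maximum."""
        return float(self.axis[int(np.argmax(self.intensity))])

    def to_table(self, component: str | None = None) -> np.ndarray:
        y = self.intensity if component is None else self.components[component]
        return np.column_stack([self.axis, y])

    def plot(self, ax=None, show_components: bool = True):
        """Quick matplotlib display (rim-style components in colour,
        total in black)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        if show_components:
            for name, y in self.components.items():
                if name != "total":
                    ax.plot(self.axis, y, label=name)
        ax.plot(self.axis, self.intensity, color="k", label="total")
        ax.set_xlabel(f"frequency ({self.units})")
        if self.units == "ppm":
            ax.invert_xaxis()
        ax.legend()
        return ax


def fid_to_spectrum(fid: np.ndarray, dwell_s: float, lb_hz: float,
                    zero_fill: int = 4):
    """Apodize, Fourier transform and phase a FID.

    Exponential apodization exp(-pi*lb*t) produces a Lorentzian convolution
    of FWHM ``lb_hz``.  The absorption spectrum is 2*Re FFT with the first
    FID point halved (the discrete form of the two-sided symmetrized
    transform), so each resonance is a unit-area Lorentzian scaled by its
    amplitude, the baseline vanishes, and the integrated intensity equals
    Re FID(0) exactly.  Returns ``(axis_hz, intensity)`` with a strictly
    increasing axis.
    """
    if dwell_s <= 0:
        raise ValueError("dwell must be positive")
    fid = np.asarray(fid, dtype=complex)
    if fid.size == 0:
        raise ValueError("empty FID")
    if lb_hz < 0:
        raise ValueError("line broadening must be >= 0")
    if zero_fill < 1:
        raise ValueError("zero_fill must be >= 1")
    t = np.arange(fid.size) * dwell_s
    apod = fid * np.exp(-np.pi * lb_hz * t)
    apod[0] *= 0.5
    n = fid.size * int(zero_fill)
    spec = 2.0 * np.fft.fftshift(np.fft.fft(apod, n)) * dwell_s
    axis = np.fft.fftshift(np.fft.fftfreq(n, dwell_s))
    return axis, spec.real


def _auto_dwell(edge_hz: float) -> float:
    """Dwell giving a spectral width of at least 4x the static edge."""
    sw = 4.0 * max(abs(edge_hz), 1.0)
    return 1.0 / sw


def _component_fid(tensor: InteractionTensor, grid, d_ld, t2_inv,
                   dwell, n_points, meq=None, mode="n_parallel_B"):
    freqs = frequency_grid(tensor, grid.site_normal_angles,
                           grid.site_phi, mode)
    system = ExchangeSystem(grid=grid, frequencies=freqs, d_ld=d_ld,
                            t2_inv=t2_inv, meq=meq)
    fid = system.propagate(dwell, n_points)
    if tensor.kind == "quadrupolar":
        fid = fid + np.conj(fid)  # mirrored satellite
    return fid


def _static_edge(tensor: InteractionTensor) -> float:
    """Largest |anisotropic frequency| over orientations, Hz."""
    cands = np.abs(frequency_grid(tensor, np.array([0.0, 90.0]),
                                  0.0, "n_parallel_B"))
    if tensor.kind == "quadrupolar":
        return float(cands.max())
    iso_hz = tensor.iso * tensor.larmor_mhz
    return float(np.max(np.abs(cands - iso_hz)) + abs(iso_hz))


def simulate(config: SimulationConfig) -> Spectrum:
    """Run one simulation described by a config; dispatch on geometry kind."""
    if config.geometry.kind == "dimple":
        return simulate_dimple(config)
    return simulate_bicelle(config)


def _acquisition(config, tensor):
    acq = config.acquisition
    dwell = acq.dwell_us * 1e-6 if acq.dwell_us else _auto_dwell(
        _static_edge(tensor))
    return dwell, acq.n_points, acq.zero_fill, acq.lb_hz


def _axis_and_unit(axis_hz, tensor):
    if tensor.kind == "csa":
        return axis_hz / tensor.larmor_mhz, "ppm"
    return axis_hz / 1e3, "kHz"


def simulate_bicelle(config: SimulationConfig) -> Spectrum:
    """Rim + disc spectrum of a bicelle (or a standalone pore surface).

    Rim lipids exchange by lateral diffusion over the curved surface; the
    flat-disc line has a single orientation and is diffusion-invariant.
    Component areas follow the q-derived molar fractions (disc:rim = q:1)
    or, in absolute mode, the explicit molecule counts.
    """
    tensor = config.tensor_object()
    mode = config.orientation_mode()
    geo = config.geometry
    dyn = config.dynamics
    dwell, n_points, zero_fill, lb = _acquisition(config, tensor)
    n_phi = config.grid.n_phi if mode == "n_perpendicular_B" else 1

    if geo.kind == "pore":
        pore = PoreGeometry(a=geo.pore_a_nm, b=geo.b_nm, d=geo.d_nm)
        grid = build_grid(pore, config.grid.n_theta, n_phi, mode)
        fid = _component_fid(tensor, grid, dyn.rate(), dyn.t2_inv,
                             dwell, n_points, mode=mode)
        fid = fid / fid[0].real
        axis_hz, total = fid_to_spectrum(fid, dwell, lb, zero_fill)
        axis, units = _axis_and_unit(axis_hz, tensor)
        return Spectrum(axis=axis, intensity=total, units=units,
                        components={"pore": total, "total": total},
                        meta={"config": config.to_dict(), "dwell_s": dwell})

    q = geo.q
    radius = geo.R_nm if geo.R_nm else packing.radius_from_q(
        q, geo.b_nm, geo.d_nm)
    rim_geo = RimGeometry(b=geo.b_nm, d=geo.d_nm, R=radius)

    if dyn.absolute_mode:
        comp = packing.BicelleComposition(q, geo.b_nm, geo.d_nm)
        if geo.ring_counts is None:
            rows = comp.rings
        else:
            rows = packing.ring_table(comp, n_positions=len(geo.ring_counts))
        grid = discrete_rim_grid([r.alpha_deg for r in rows],
                                 [r.x_nm for r in rows],
                                 geo.b_nm, geo.d_nm, n_phi=n_phi)
        counts = np.array(geo.ring_counts, dtype=float) \
            if geo.ring_counts is not None \
            else np.array([r.ring_value for r in rows], dtype=float)
        meq = np.tile(counts / n_phi, n_phi)
        meq = meq / meq.sum()
        rim_frac = comp.n_rim_total / (comp.n_rim_total + comp.n_disc)
    else:
        grid = build_grid(rim_geo, config.grid.n_theta, n_phi, mode)
        meq = None
        rim_frac = 1.0 / (1.0 + q)

    fid_rim = _component_fid(tensor, grid, dyn.rate(), dyn.t2_inv,
                             dwell, n_points, meq=meq, mode=mode)
    disc_grid = build_grid(FlatDisc(), 1, 1, mode)
    fid_disc = _component_fid(tensor, disc_grid, 0.0, dyn.t2_inv,
                              dwell, n_points, mode=mode)
    fid_rim = rim_frac * fid_rim / fid_rim[0].real
    fid_disc = (1.0 - rim_frac) * fid_disc / fid_disc[0].real

    axis_hz, rim = fid_to_spectrum(fid_rim, dwell, lb, zero_fill)
    _, disc = fid_to_spectrum(fid_disc, dwell, lb, zero_fill)
    axis, units = _axis_and_unit(axis_hz, tensor)
    total = rim + disc
    return Spectrum(axis=axis, intensity=total, units=units,
                    components={"rim": rim, "disc": disc, "total": total},
                    meta={"config": config.to_dict(), "dwell_s": dwell,
                          "rim_fraction": rim_frac, "R_nm": radius})


def simulate_dimple(config: SimulationConfig) -> Spectrum:
    """Spectrum of lipids on a cosine-thinned disc patch.

    Zero depth reproduces the flat-disc single line; increasing depth
    spreads the static lineshape over the tilt distribution, and fast
    diffusion collapses it to the p(Omega)-weighted mean frequency, which
    shrinks monotonically with the thinning ratio d/a.
    """
    tensor = config.tensor_object()
    mode = config.orientation_mode()
    geo = config.geometry
    dyn = config.dynamics
    dwell, n_points, zero_fill, lb = _acquisition(config, tensor)
    n_phi = config.grid.n_phi if mode == "n_perpendicular_B" else 1

    depth = geo.dimple_depth_ratio * geo.dimple_a_nm
    if depth == 0.0:
        grid = build_grid(FlatDisc(), 1, 1, mode)
        fid = _component_fid(tensor, grid, 0.0, dyn.t2_inv,
                             dwell, n_points, mode=mode)
    else:
        dimple = DimpleGeometry(a=geo.dimple_a_nm, depth=depth)
        grid = build_grid(dimple, config.grid.n_theta, n_phi, mode)
        fid = _component_fid(tensor, grid, dyn.rate(), dyn.t2_inv,
                             dwell, n_points, mode=mode)
    fid = fid / fid[0].real
    axis_hz, total = fid_to_spectrum(fid, dwell, lb, zero_fill)
    axis, units = _axis_and_unit(axis_hz, tensor)
    return Spectrum(axis=axis, intensity=total, units=units,
                    components={"dimple": total, "total": total},
                    meta={"config": config.to_dict(), "dwell_s": dwell})
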