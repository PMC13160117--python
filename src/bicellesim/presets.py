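"""Preset simulation parameter sets.

Each preset reproduces one published simulation series for DMPC/DHPC
bicelles at 9.4 T (Larmor 28.9 MHz for 14N, 162 MHz for 31P): diffusion
ladders, tensor-magnitude sweeps, q and rim-ellipticity sweeps, the
absolute-rate molecule-counted rim, the thinned-dimple series, and the
forward simulations of the experimental 14N / 31P bicelle spectra.
A preset expands to a list of (label, SimulationConfig) runs.

Relative diffusion rates are in arbitrary units (nm^2/s against the nm
geometry); only ratios between rows are meaningful.  Absolute-mode rates
are true lateral diffusion coefficients in m^2/s.
"""

from __future__ import annotations

from .config import (AcquisitionConfig, DynamicsConfig, GeometryConfig,
                     GridConfig, SimulationConfig, TensorConfig)

__all__ = ["PRESETS", "expand", "list_presets"]

#: relative rate giving complete motional averaging on the default rim grid
FAST_RELATIVE = 1.0e6

_Q_SWEEP = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
_DB_SWEEP = (1.3, 1.2, 1.1, 1.0, 0.9, 0.8, 0.7)
_CQ_SWEEP = (5e3, 10e3, 15e3, 20e3, 25e3, 30e3)
_CSA_SWEEP = (20.0, 40.0, 60.0, 80.0, 100.0, 120.0)
_DIMPLE_RATIOS = (0.0, 0.14, 0.17, 0.20, 0.23)


def _cfg(nucleus, orientation, *, magnitude, q=2.0, b=2.0, d=1.8,
         rel_rate=FAST_RELATIVE, d_ld=None, absolute=False, lb=120.0,
         kind="bicelle", depth_ratio=0.0, ring_counts=None,
         n_theta=200, n_phi=8):
    return SimulationConfig(
        nucleus=nucleus, orientation=orientation,
        tensor=TensorConfig(magnitude=magnitude),
        geometry=GeometryConfig(kind=kind, b_nm=b, d_nm=d, q=q,
                                dimple_depth_ratio=depth_ratio,
                                ring_counts=(list(ring_counts)
                                             if ring_counts else None)),
        dynamics=DynamicsConfig(relative_rate=rel_rate,
                                d_ld_m2_per_s=d_ld, absolute_mode=absolute),
        acquisition=AcquisitionConfig(lb_hz=lb),
        grid=GridConfig(n_theta=n_theta, n_phi=n_phi))


def _mag(nucleus):
    return 15e3 if nucleus in ("N14", "H2") else 80.0


def _diffusion_ladder():
    out = []
    for nucleus in ("N14", "P31"):
        for orientation in ("parallel", "perpendicular"):
            for k in range(6):
                rate = FAST_RELATIVE * 10.0 ** (-k)
                out.append((
                    f"{nucleus}_{orientation}_rate1e{-k:+d}",
                    _cfg(nucleus, orientation, magnitude=_mag(nucleus),
                         q=2.0, d=1.8, rel_rate=rate, lb=120.0,
                         n_theta=(200 if orientation == "parallel" else 10),
                         n_phi=8)))
    return out


def _tensor_sweep():
    out = []
    for nucleus, sweep in (("N14", _CQ_SWEEP), ("P31", _CSA_SWEEP)):
        for orientation in ("parallel", "perpendicular"):
            for mag in sweep:
                out.append((
                    f"{nucleus}_{orientation}_mag{mag:g}",
                    _cfg(nucleus, orientation, magnitude=mag, q=2.0, d=1.8,
                         n_theta=(200 if orientation == "parallel" else 10))))
    return out


def _q_sweep():
    return [(f"{nucleus}_{orientation}_q{q:g}",
             _cfg(nucleus, orientation, magnitude=_mag(nucleus), q=q, d=2.0,
                  n_theta=(200 if orientation == "parallel" else 10)))
            for nucleus in ("N14", "P31")
            for orientation in ("parallel", "perpendicular")
            for q in _Q_SWEEP]


def _ellipticity_sweep():
    return [(f"{nucleus}_{orientation}_db{db:g}",
             _cfg(nucleus, orientation, magnitude=_mag(nucleus), q=2.0,
                  d=2.0 * db,
                  n_theta=(200 if orientation == "parallel" else 10)))
            for nucleus in ("N14", "P31")
            for orientation in ("parallel", "perpendicular")
            for db in _DB_SWEEP]


#: ring populations printed for the b=2.0, d=1.8 counted rim
RING_COUNTS_D18 = (131, 138, 142, 144, 142, 138, 131)


def _counted_rim():
    out = []
    for nucleus in ("N14", "P31"):
        for orientation in ("parallel", "perpendicular"):
            for expo in (-10, -11, -12, -13, -14):
                out.append((
                    f"{nucleus}_{orientation}_dld1e{expo}",
                    _cfg(nucleus, orientation, magnitude=_mag(nucleus),
                         q=2.0, b=2.0, d=1.8, absolute=True,
                         d_ld=10.0 ** expo, lb=80.0,
                         ring_counts=RING_COUNTS_D18, n_phi=8)))
    return out


def _dimple_series(ratios=_DIMPLE_RATIOS, n_theta=60, n_phi=60):
    out = []
    for nucleus in ("N14", "P31"):
        for orientation in ("parallel", "perpendicular"):
            for ratio in ratios:
                for k in range(5):
                    rate = FAST_RELATIVE * 10.0 ** (-k)
                    out.append((
                        f"{nucleus}_{orientation}_da{ratio:g}_rate1e{-k:+d}",
                        _cfg(nucleus, orientation, magnitude=_mag(nucleus),
                             kind="dimple", depth_ratio=ratio,
                             rel_rate=rate, lb=80.0,
                             n_theta=n_theta, n_phi=n_phi)))
    return out


def _n14_experimental():
    """Forward simulations of the published 14N bicelle series (pure,
    flipped, desipramine, MSI-78 at two loadings, DMPG +/- NaCl)."""
    runs = [
        ("pure_perpendicular",
         _cfg("N14", "perpendicular", magnitude=15e3, q=3.5, b=2.0, d=1.4,
              absolute=True, d_ld=1e-11, lb=80.0, n_phi=8)),
        ("flipped_parallel",
         _cfg("N14", "parallel", magnitude=15e3, q=3.5, b=2.0, d=1.4,
              absolute=True, d_ld=1e-11, lb=80.0)),
        ("desipramine_rim",
         _cfg("N14", "perpendicular", magnitude=10.4e3, q=1.0, b=2.0, d=2.0,
              absolute=True, d_ld=1e-11, lb=80.0, n_phi=8)),
        ("desipramine_thinned_disc",
         _cfg("N14", "perpendicular", magnitude=10.4e3, kind="dimple",
              depth_ratio=0.20, rel_rate=FAST_RELATIVE * 1e-2, lb=80.0,
              n_theta=60, n_phi=60)),
        ("msi78_2.0pct_rim",
         _cfg("N14", "perpendicular", magnitude=10.4e3, q=2.5, b=2.0, d=1.8,
              absolute=True, d_ld=1e-12, lb=80.0, n_phi=8)),
        ("msi78_2.0pct_thinned_disc",
         _cfg("N14", "perpendicular", magnitude=10.4e3, kind="dimple",
              depth_ratio=0.14, rel_rate=FAST_RELATIVE * 1e-3, lb=80.0,
              n_theta=60, n_phi=60)),
        ("msi78_0.5pct_rim",
         _cfg("N14", "perpendicular", magnitude=10.4e3, q=3.0, b=2.0, d=1.6,
              absolute=True, d_ld=1e-11, lb=80.0, n_phi=8)),
        ("dmpg_nacl_rim",
         _cfg("N14", "perpendicular", magnitude=12.6e3, q=3.5, b=2.0, d=1.2,
              absolute=True, d_ld=1e-11, lb=80.0, n_phi=8)),
        ("dmpg_no_nacl_rim",
         _cfg("N14", "perpendicular", magnitude=12.6e3, q=1.0, b=2.0, d=1.6,
              absolute=True, d_ld=1e-13, lb=80.0, n_phi=8)),
        ("dmpg_no_nacl_thinned_disc",
         _cfg("N14", "perpendicular", magnitude=12.6e3, kind="dimple",
              depth_ratio=0.14, rel_rate=FAST_RELATIVE * 1e-4, lb=80.0,
              n_theta=60, n_phi=60)),
    ]
    return runs


def _p31_experimental():
    """Forward simulations of the published 31P MSI-78 titration."""
    runs = []
    for label, db, q, ratio in (("0.0pct", 0.8, 3.0, 0.0),
                                ("0.5pct", 0.9, 2.5, 0.17),
                                ("2.0pct", 1.0, 2.5, 0.23)):
        runs.append((f"msi78_{label}_rim",
                     _cfg("P31", "perpendicular", magnitude=23.0, q=q,
                          b=2.0, d=2.0 * db, absolute=True, d_ld=1e-11,
                          lb=80.0, n_phi=8)))
        if ratio > 0:
            runs.append((f"msi78_{label}_thinned_disc",
                         _cfg("P31", "perpendicular", magnitude=23.0,
                              kind="dimple", depth_ratio=ratio,
                              rel_rate=FAST_RELATIVE, lb=80.0,
                              n_theta=60, n_phi=60)))
    return runs


PRESETS = {
    "diffusion_ladder": _diffusion_ladder,
    "tensor_sweep": _tensor_sweep,
    "q_sweep": _q_sweep,
    "ellipticity_sweep": _ellipticity_sweep,
    "counted_rim": _counted_rim,
    "thinned_dimple": _dimple_series,
    "n14_experimental": _n14_experimental,
    "p31_experimental": _p31_experimental,
}


def list_presets() -> list[str]:
    return sorted(PRESETS)


def expand(name: str):
    """Return the (label, SimulationConfig) runs of one preset."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; "
                       f"available: {', '.join(list_presets())}") from None
    return factory()
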