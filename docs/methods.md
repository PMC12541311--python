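# Methods

This note records the model implemented by `cmbdf`, the numerical choices
behind it, and what the bundled synthetic tests do and do not demonstrate.

## Model

Each atom *i* carries a smooth density built from normalized Gaussians of
width σ placed on every neighbor within a hard cutoff r_cut, weighted by an
element-identity factor A(Z).  Projections onto internal coordinates give
the two-body distribution over distances, the three-body distribution over
angles (damped by the Axilrod–Teller–Muto factor `(R_ij R_ik R_jk)^-2`),
and a pseudo four-body distribution over an effective quadruplet
coordinate.  For the quadruplet, the product of the six pair Gaussians of
a cluster {i,j,k,l} collapses, by the Gaussian product theorem, to a single
Gaussian at the precision-weighted mean of the six distances with width
σ/√6 (uniform σ), times a spread-penalty exponential ζ.

Feature components are integrals of weighting functions against the m-th
derivative of each distribution.  Radial body orders use two decaying
families, `exp(-alpha (n+1) r)` and `(r+1)^-(2n+3)` (α = 1.5 Å⁻¹ for both
the two- and four-body blocks by default); the angular order uses the
difference-of-cosines / difference-of-sines Fourier pairs, which for the
odd multiplier 2n+1 equal `2 cos((2n+1)θ)` and `2 sin((2n+1)θ)`.  Since the
m-th derivative of a Gaussian is a Hermite–Gaussian, every component is a
weighted sum of values of the convolution `H_{ν,n,m} = g_n * f_m`,
tabulated once per configuration and looked up thereafter.

### Derivative-order prefactor

Expanding the defining integral gives exactly

    P_{ν,n,m}[i] = (√2 σ)^(−m) Σ A · (damping) · H_{ν,n,m}(x)

— the (−1/(√2σ))^m from the Hermite expansion of the m-th derivative
combines with the (−1)^m parity flip of f_m inside the convolution.  The
package's default (`prefactor="derivative"`) keeps this identity, so the
grid path and the quadrature oracle compute the same number by
construction.  Two alternative conventions, `(√2σ)^m` and the literal
`(2σ)^m`, are available; they rescale each m-block by a constant, which a
kernel model absorbs, and the oracle applies the same convention so the
dual-route equivalence test remains meaningful under any of them.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| ν | 3 | – | many-body order (2 diagnostics, 3 standard, 4 adds quadruplets) |
| m_max | 4 | – | highest derivative order |
| n_max | 2 | – | weighting orders per family |
| σ | 0.6 | Å | radial Gaussian width (scalar, or per-element mapping) |
| σ_ang | 0.2 | rad | angular Gaussian width |
| r_cut | 8.0 | Å | hard neighbor cutoff, no switching function |
| α₂, α₄ | 1.5 | Å⁻¹ | exponential weighting decay rates |
| radial Δx | 0.002 | Å | radial grid spacing |
| angular nodes | 4096 | – | circular-grid resolution (power of two) |

The defaults give the published operating point (ν=3, m=4, n=2; 40
components per atom).  The feature length 2(ν−1)(m_max+1)n_max is fixed
before any geometry is seen.

## Numerical choices

* **Grid construction.**  Radial grids are linear (zero-padded) discrete
  convolutions of g sampled on [0, x_hi + 8σ] with f_m sampled on
  [−8σ, 8σ], scaled by Δx; the endpoint samples of g carry trapezoid
  half-weights, which makes the discrete sum match the half-line integral
  to O(Δx²) instead of O(Δx) at the r = 0 boundary.  x_hi = r_cut + 6σ so
  the stored tail is fully decayed.  Angular grids are circular FFT
  convolutions over one 2π period with the Hermite–Gaussian wrapped over
  adjacent periods.  Grid construction is deterministic; rebuilding with
  the same configuration is bit-identical.
* **Interpolation.**  Lookups default to a cubic spline through the grid
  nodes.  Linear and nearest-node modes exist, but only the spline keeps
  the analytic gradients (built from the (m+1)-grids) consistent with
  finite differences of the features at the 1e−5 level: the derivative of
  a piecewise-linear lookup disagrees with the (m+1)-grid by O(Δx·H″),
  about 1e−3 at the default spacing, whereas the spline mismatch is
  O(Δx³).  Radial lookups beyond the stored domain return 0.
* **Boundary/domain conventions.**  Both the grid path and the oracle
  integrate the radial coordinate over [0, ∞), so the near-origin Gaussian
  tail truncation is identical on both routes.  The angular grid path is a
  periodic convolution; the default oracle therefore integrates the
  periodically wrapped angular distribution over a full period.  A literal
  [0, π] oracle domain is available (`angular_domain="eq15"`); it agrees
  with the periodic route whenever every angle is more than ~3.5 σ_ang
  from 0 and π, and the difference for near-collinear triplets is the
  wrapped tail mass.
* **Degenerate geometry.**  The angle gradient is singular at θ = 0, π;
  triplets with sin θ < 1e−6 get a zero gradient and a logged warning
  rather than an exception, so dynamics-style loops survive collinear
  fixtures.  The center atom is excluded from its own density; pairs,
  triplets and quadruplets are enumerated once per unordered set (a config
  flag restores ordered counting, a pure scale factor).
* **ζ convention.**  The quadruplet spread penalty keeps only the
  exponential part of the Gaussian-product prefactors; constant
  normalization factors are dropped as an overall scale.  A `zeta_mode=
  "unit"` renormalized variant sets ζ ≡ 1.
* **Element scaling.**  A(Z) = ln(P+1)·G with the IUPAC 1–18 group
  convention, exposed as a configurable functional form.  With this
  product form, differences along a period (ΔA = ln(P+1) per group step)
  are generally *smaller* than differences down a group for high-group
  elements (ΔA = G·Δln(P+1)); the form is monotone in G at fixed P, which
  is the property the tests assert.
* **Per-element σ.**  Accepted by the configuration; the two-body block
  then uses one grid per distinct width, and the four-body block falls
  back to direct quadrature per quadruplet because its effective width is
  no longer constant.  Analytic gradients require uniform σ.
* **Gradient validation.**  Central differences with h = 1e−5 Å are the
  ground truth for every gradient formula; the angle-gradient sign
  structure is derived from the arccos chain rule rather than transcribed.

## Synthetic data and the learning harness

The fixture generator rejection-samples atoms in a cubic box (default 6 Å,
minimum separation 1.0 Å, 2–20 atoms) from a ten-element pool spanning
three periods (H, C, N, O, F, Si, P, S, Cl, Br), with a fixed seed per
set.  Labels are sums of pairwise Morse terms with deterministic
parameters derived from period and group.  These point clouds exercise
every geometric, combinatorial and element-handling code path, but they
are not molecules: there is no valence structure, no equilibrium geometry,
and the label contains no genuine many-body physics.  Passing tests
therefore demonstrate correctness of the machinery and the qualitative
learnability of a smooth extensive pair property — not accuracy on real
quantum-chemical data.

The KRR harness uses a Laplacian kernel by default, in global mode on
summed vectors or local mode as an unnormalized sum of atomic kernel
values over atom pairs, optionally restricted to matching elements
(enabled by default in the toy learning curve, where it clearly helps).
Hyperparameters come from a 3-fold cross-validated grid on the training
split only: widths {1, 4, 16} × a median-distance heuristic,
regularization {1e−8, 1e−6}.  Problem sizes in the bundled curve (up to
800 training molecules of 4–8 atoms, 200 test molecules, five seeds) were
chosen so the full suite runs comfortably on one CPU; the curve's
monotonic descent, not its absolute level, is the tested claim.

## Known limitations

* Open boundary conditions only; no periodic images or cell lists, so the
  O(N²) neighbor search and O(N³) triplet enumeration are for molecular,
  not condensed-phase, scale.
* No forces on predicted energies (would require the trained model's chain
  rule), geometry optimization or dynamics.
* The four-body term is a pseudo many-body contraction over distances; it
  does not resolve dihedral sign.
* Weighting functions are fixed families; no learned or user-registered
  weightings.
* Element table covers Z = 1–54; no isotopes.
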