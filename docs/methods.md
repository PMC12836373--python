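# Methods

## Transport model

The engine treats a proton pencil beam in the continuous-slowing-down
approximation built entirely on the power-law range-energy relation

    R0 = a E^p,  a = 0.0022 cm/MeV^p,  p = 1.77  (Bortfeld approximation)

valid across the clinical energy interval 48.08–221.07 MeV. Everything else
follows in closed form: residual energy E(z) = ((R0 − z)/a)^(1/p) for
z < R0 (defined as 0 beyond R0 so grid evaluation is total), and electronic
stopping power S(z) = (R0 − z)^(1/p − 1) / (p a^(1/p)), which depends only on
the residual range. Multiplying S in MeV/cm by 0.1 gives LET in keV/µm.

A pristine Bragg curve is the expectation of S(z; R0′) over a Gaussian range
distribution R0′ ~ N(R0, σ_R), accounting for range straggling. The default
σ_R = 0.012·R0^0.935 (cm) is a published straggling approximation; the beam
monitor's energy spread, when a commissioning model is supplied, widens σ_R
in quadrature via dR/dE = a·p·E^(p−1). A linear fluence-loss factor
(1 − k·z/R0) is available as a stand-in for nuclear attenuation but defaults
to k = 0 (off): nuclear interactions and secondary particles are out of
scope, which also means scored LETd contains only the primary-proton
electronic stopping power.

Two engines share this model:

* **Analytic pencil-beam superposition.** Per spot, the water-equivalent
  thickness (WET) along the spot's central axis is traced once through the
  density grid; each voxel receives the Bragg-curve dose at the WET of its
  projection onto the axis, multiplied by a lateral Gaussian whose variance
  grows with depth as σ(z)² = σ0² + (σ_mcs·(WET/R0)^1.5·R0)². σ0 comes from
  the spot FWHM (σ = FWHM/2.3548); σ_mcs (default 0.04, the end-of-range
  lateral sigma as a fraction of range) is a declared fixture parameter
  standing in for multiple Coulomb scattering, not a fitted value. Spot
  weights count primaries, so dose is Gy per unit weight and linear in the
  weights.

* **Lightweight Monte Carlo.** Per primary: the spot is chosen
  weight-proportionally, the lateral offset is drawn from the spot Gaussian,
  the range from N(R0, σ_R); the primary then marches along the (rotated)
  beam direction in fixed geometric steps, converting each step to WET with
  the local relative density, depositing E(w_in) − E(w_out), and scoring
  per-step LET. LETd is finalized per voxel as Σ dᵢ·LETᵢ / Σ dᵢ. Because the
  MC samples only the initial lateral position (no in-medium scattering),
  MC and analytic central-axis doses are directly comparable when the
  analytic σ_mcs is set to 0.

Gantry rotation is a rotation about the x axis — (x, y, z) ↦
(x, y cos α − z sin α, z cos α + y sin α) — applied identically to particle
positions and direction cosines, preserving norms and angles. Degrees at
every interface, radians internally.

## HU–density calibration

The full Hounsfield range (−1000 to 3070) is divided into 27 base intervals
(a declared, Schneider-protocol-like boundary list that includes −950, −120
and 0, so the water anchor maps exactly). Each interval carries a reference
density read from the calibration curve at its median HU, plus correction
factors at both edges; within an interval the correction is linearly
interpolated, making the HU→density map continuous, monotone, and total
(out-of-range HU is clamped with a warning). Every interval must keep its
correction inside [2/3, 3/2].

Near air that bound is unreachable with wide intervals — relative density
changes by orders of magnitude — so the two lowest intervals
(−1000..−950 and −950..−120) are replaced by 14 subintervals whose edges
are spaced geometrically in density (the 14 are allocated between the two
intervals in proportion to their log density ratios), which bounds the
within-interval density ratio and hence the correction factors by
construction. The final table has 25 + 14 = 39 intervals. If a supplied
curve still violates the bound, the builder raises, or — with an explicit
override — bisects offending intervals (growing past 39).

The fixture calibration curve is piecewise linear through declared anchor
points (air −1000 → 0.00121, lung −700 → 0.26, water 0 → 1.000, soft tissue
40 → 1.04, bone 700 → 1.42, dense upper anchor 3070 → 2.50 g/cm³). These are
surrogate values standing in for a scanner curve, not measured data.

## Radiobiology

Three variable-RBE models plus the constant 1.1 baseline:

* McMahon: RBE = 1 + 0.055·LETd. Linear, tissue-independent.
* McNamara: RBE(Dp, α/β, LETd) =
  [√((α/β)² + 4·Dp·(α/β)·RBEmax + 4·Dp²·RBEmin²) − (α/β)] / (2·Dp) with
  RBEmax = 0.99064 + 0.35605·LETd/(α/β) and
  RBEmin = 1.1012 − 0.0038703·√(α/β)·LETd. The implementation follows the
  canonical quadratic-root form (the correct low- and high-dose limits,
  RBEmax and RBEmin, fall out algebraically). Parameter combinations pushing
  RBEmin below zero are outside the fitted domain and raise rather than
  extrapolate.
* Wedenberg: RBE = −(α/β)/(2D) + (1/D)·√(¼(α/β)² + (q·LETd + α/β)·D + D²),
  q = 0.434 Gy·µm/keV; exactly 1 at LETd = 0 for all D and α/β.

RBE-weighted total-course dose is computed per voxel at the per-fraction
physical dose d = D_total/n_fractions as n_fractions · RBE(d, LETd) · d.
Whether to evaluate the LQ models at fraction or course dose is a genuine
choice; the per-fraction convention matches how the models were fitted, so
n_fractions is a required parameter with no default. α/β defaults to 3 Gy
(late-responding tissue such as rib) but is always explicit in configs.
Voxels with zero dose get zero RBE-weighted dose regardless of the LETd
sentinel.

## Plan evaluation

DVH/LVH are cumulative: percent of structure volume with value ≥ each bin
edge (0.1 Gy / 0.1 keV/µm default bin widths). LETd voxels never reached by
dose carry a sentinel recorded in grid metadata and are excluded, with the
excluded fraction reported. D_v is the minimum dose of the hottest v cm³
(voxel volumes = spacing product; the partial last voxel by linear
interpolation on the sorted curve); V_x is the percent of structure at or
above x Gy.

Gamma analysis is global: the dose criterion is a percentage of the
reference maximum, the low-dose threshold (default 5%) applies to the
reference grid, and the evaluated grid is interpolated trilinearly at
offsets on a 0.5 mm lattice within a search radius capped at 3×DTA. Offsets
are visited in shells of increasing distance with early termination once the
distance term alone exceeds the running minimum, which makes the identity
and near-identity cases fast. An optional auto-alignment analog applies the
integer-voxel rigid shift (±2 voxels per axis) minimizing the mean squared
dose difference before the comparison. Swapping reference and evaluated
changes the result (global normalization and threshold follow the
reference); on smooth fields the asymmetry stays within a few percentage
points.

## Numerical choices

* **Bragg-curve quadrature.** The Gaussian expectation of S has an
  integrable endpoint singularity; the substitution u = (r − z)^(1/p)
  removes it exactly, leaving a smooth integrand evaluated with a 257-point
  trapezoidal rule across the ±8σ support. Verified against a 10⁶-sample
  Monte Carlo estimate to <0.5% of the peak.
* **MC stepping.** Step length is half the smallest voxel spacing, capped at
  1 mm; the final step is truncated at the sampled range and deposits the
  full residual energy, so energy bookkeeping is exact when straggling is
  off (with straggling, the sampled effective initial energy scatters around
  the nominal one, and conservation holds in the mean).
* **Per-step LET.** The mean of entry and exit stopping power, except the
  final truncated step, where the exit value diverges; that step uses the
  exact step average ΔE/ΔWET. All per-step LET is capped at the stopping
  power of a proton at the transport energy cutoff (default 1 MeV, a cap of
  ≈25.7 keV/µm — the physical LET at that energy). Without the cap the
  continuous model assigns unbounded LET to single track-end deposits,
  which has no physical counterpart and leaves the RBE models' fitted
  domains.
* **Voxel-mean reporting.** The analytic engine integrates the lateral
  Gaussian over each voxel's lateral extent (error-function differences) and
  Simpson-subsamples the depth direction (3 points per voxel), so both
  engines report voxel-mean dose and converge to each other as statistics
  grow.
* **Range metrics.** R100 is the depth of the maximum sample (smallest depth
  on ties); R90/R80/R20 are the first crossings distal to the peak, located
  by linear interpolation between bracketing samples; a level never crossed
  raises an error naming the level. Metrics are invariant under uniform
  dose scaling.
* **Commissioning fits.** Linear (energy), cubic (energy spread) and quartic
  (spot FWHM) least squares, computed in numpy's scaled-domain polynomial
  basis for conditioning; fitted spread and FWHM must be positive across the
  validity interval or the fit is rejected.
* **Geometry.** Voxel indexing is 0-based with the voxel-center convention
  world = origin + (index + 0.5)·spacing; depths are cm internally, grid
  coordinates mm. WET ray tracing splits the ray exactly at voxel boundaries
  and is additive over concatenated segments to 10⁻⁹.

## Synthetic phantoms and what passing tests show

The fixture generator produces the three study geometries: a 30 cm water
tank (the depth may be extended past the nominal side so that the
highest-energy beam, whose analytic range of 31.1 cm slightly exceeds 30 cm,
stops inside the scoring grid); layered slab phantoms with air/lung/water/
soft-tissue/bone at declared HU values; and a toy thorax — 6 cm of
soft-tissue "breast" bulk containing an ellipsoidal CTV, an 8 mm bone band
(rib) at its distal edge, lung beyond, with seeded HU texture and disjoint
CTV/rib/lung masks (rib volume well above 0.5 cm³ so D_0.5cm³ is defined).

These phantoms emulate the *geometry* of a tangential breast field — a
target in front of rib and lung — not patient anatomy: there is no
respiratory structure, no CT noise model beyond Gaussian HU texture, no
positioning uncertainty. Tests passing on them demonstrate that the
transport, LETd scoring, RBE arithmetic and metric extraction are correct
and self-consistent; they do not validate clinical dose accuracy, which
would require a full-physics MC code and measured beam data.

## Problem sizes

The range-agreement check runs 15 monoenergetic beams (48.08–221.07 MeV,
10⁵ primaries each) through the water tank at 10×10×1 mm scoring resolution
and compares the distal R80 of each integrated depth-dose curve against
a·E^p; with these statistics the mean absolute deviation is well under
0.1 mm. Central-axis MC-vs-analytic comparisons use 2.5 mm lateral voxels
and 10⁵ primaries. The end-to-end thorax demonstrations use 4 mm voxels and
3–5·10⁴ primaries — enough for stable D_v/V_x metrics on the toy geometry.

## Known limitations

* No nuclear interactions or secondaries: the entrance-to-peak dose ratio is
  lower than measured IDDs, and LETd omits secondary-proton contributions.
* Multiple Coulomb scattering is a parametric lateral width in the analytic
  engine only; the MC transports straight rays, so lateral penumbra in
  heterogeneous media is approximate and halo effects are absent.
* The power-law stopping power is least accurate at very low residual
  energies (hence the LET cutoff) and below ~10 MeV total energy.
* The HU→density fixture curve is a surrogate; absolute doses through bone
  and lung inherit its anchors.
* Gamma analysis is global-normalization only; local-dose gamma is not
  implemented.
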