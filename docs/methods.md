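# Methods

## Scope

`helixtemp` packages the analysis machinery needed to ask how the twist of a
nucleic-acid double helix responds to temperature, from three directions:

1. **Duplex trajectory geometry** — base-pair reference frames, local and
   helical twist, helical rise, and a global end-to-end twist for snapshot
   ensembles such as MD trajectories.
2. **Magnetic-tweezer traces** — rotation–extension curves whose Gaussian peak
   center tracks the torsionally relaxed state of a kilobase tether across
   temperature.
3. **Continuum models** — the high-force inextensible wormlike chain (WLC) for
   extension changes, and a quadratic twist–groove free-energy model for
   entropy-driven groove/twist coupling.

Seeded synthetic generators stand in for the raw data (MD snapshots, tweezer
recordings, free-energy surfaces), with full ground truth returned so that
every downstream stage is testable without any external download.

## Base-pair frames and twist definitions

A base frame is fitted by least-squares (Kabsch) superposition of an embedded
standard-base template (planar heavy atoms of A/C/G/T/U in the standard
reference frame; x toward the major groove, y toward the reference strand,
z along the helix). A pair frame is the geodesic mean of the reference-strand
base frame and the y,z-flipped complementary base frame; its origin is the
midpoint.

**Local (mean-plane) twist.** For frames i and j, the plane normal is the
normalized mean of the two z-axes. Each x-axis is carried into that plane by
the *minimal hinge rotation* taking its own z onto the normal; the twist is
the signed angle between the carried x-axes about the normal. We deliberately
use the hinge rotation rather than orthogonal projection of the x-axes: the
hinge construction (as in the 3DNA local twist) makes the angle change by
*exactly* the offset when either frame is rotated about its own z-axis.
Orthogonal projection distorts the in-plane angle elliptically (≈0.1° at a
10° axis tilt) and would break the exact offset-rotation invariance of
end-to-end twist changes that the experiment-mimicking definition relies on.

**Screw (helical) parameters.** Each step's relative rigid transform is
decomposed into a rotation h-twist about the screw axis and a translation
h-rise along it. Below |h-twist| = 0.01° the axis direction is numerically
unstable and the pure-translation branch is used (h-twist = 0, axis along the
step translation).

**End-to-end twist.** The end frames of an analyzed fragment are the pair
frames of the terminal analyzed pairs projected (orientation-only; origins
kept) onto their local helical axes, each axis being the normalized mean of
the two adjacent step screw axes. The raw mean-plane angle between the end
frames is defined mod 360°, while ~27 analyzed base pairs accumulate ~850°;
the angle is therefore unwrapped by adding the multiple of 360° nearest the
sum of local mean-plane twists over the fragment. Any unwrap convention
cancels in temperature differences; this one also makes the noiseless ideal
helix close exactly (end-to-end twist = h-twist sum = steps x twist).

Analyzed ranges are closed, 1-based intervals excluding three pairs at each
duplex end, which guarantees every analyzed end pair has two flanking steps.

## Filtering, errors, slopes

A Watson–Crick hydrogen bond is present when the donor–acceptor heavy-atom
distance is strictly below 4 Å (A·T/A·U two bonds, G·C three). A snapshot
passes the filter only if every pair in the analyzed range is intact;
filtering removes snapshots, never individual pairs.

The mean of a twist series carries a *half-trajectory error*: the mean
absolute difference between the whole-series mean and the means of its two
halves, split at the midpoint (odd lengths give the extra snapshot to the
first half). It is a diagnostic, not a fit weight.

Twist–temperature slopes come from unweighted ordinary least squares of the
per-temperature mean twist on temperature (≥3 temperatures). The normalized
slope divides by the number of *steps* spanned and scales to 1000, giving
°/(°C·kbp); steps rather than pairs because twist is additive over steps (the
~4% step/pair difference for a ~27-bp fragment is noted in reports). Reported
errors are twice the slope standard deviation (~95% confidence). The
slope-vs-rise relation across duplex variants uses the same OLS machinery
with R² and an interpolation at a queried rise (e.g. the consensus 2.8 Å).

## Tweezer pipeline

Replicate rotation–extension sweeps sharing a turns grid are averaged
pointwise (display-style decimation is provided separately). The averaged
curve is fitted with `baseline + A exp(-(n-c)²/2w²)` by nonlinear least
squares, initialized from the argmax and second moment; the center
uncertainty comes from the fit covariance. The baseline term is included
because real traces have a nonzero minimum extension; noiseless synthetic
tests pass with baseline 0.

Peak centers are re-zeroed per tether at the reference temperature (25 °C)
and pooled into a single OLS of center change on temperature across tethers.
The slope in turns/°C converts to °/(°C·kbp) via 360°/turn divided by the
tether length in kbp; decreasing center with temperature means unwinding and
carries a negative sign.

## Wormlike chain

For forces with f·P ≫ k_BT the inextensible WLC obeys
z/L = 1 − √(k_BT / 4fP) with P = A_b/(k_BT), i.e.
z/L = 1 − k_BT/(2√(f·A_b)). k_B is fixed at 1.380649×10⁻² pN·nm/K; the
familiar 4.14 pN·nm at 300 K appears at two-decimal rounding. A soft warning
is raised when f·P < 4 k_BT (the inequality is qualitative; the hard error
fires only when z/L leaves (0, 1)). Two closed-form inversions cover the
limiting mechanisms for an extension drop between two temperatures: rigidity
change at fixed contour length, and contour-length change at fixed rigidity.
Both are exact inverses of the forward relation (round trips verified to
1e-10). At the canonical inputs (0.64→0.61 μm, 318→323 K, 0.3 pN, 248
pN·nm²) the fixed-contour inversion gives 197.8 ≈ 198 pN·nm² (a 20% drop) and
the fixed-rigidity inversion a 4.2% shortening — reported unrounded, slightly
below the ~5% suggested by the raw extension ratio because the thermal-energy
factor also changes between the two states.

## Twist–groove model

The free energy of the major-groove width G is modeled as
F(G,T) = U(G) − T·S(G) with temperature-independent quadratic U and S.
Fitting F at two temperatures and subtracting coefficientwise yields S
exactly (quadratics are closed under this algebra). The groove minimum
G0(T) = argmin F(G,T) then shifts at the analytic rate
(a_F·b_S − a_S·b_F)/(2a_F²) at the anchor temperature, and an elastic
twist–groove coupling converts the shift into a twist change
Δω = −(k_ωG/k_ω)·ΔG (the groove stiffness k_G cancels at fixed ΔG).
Temperatures may be given in °C or K wherever only differences enter.
Three ΔG estimators (subtracted minima plus the analytic rate at each anchor)
are reported with their average.

Because a quadratic entropy makes any straight-line fit to S(G)
window-dependent and arbitrary — symmetric windows around the vertex give slope zero, shifted
windows do not — linear entropy fits are always accompanied by the
t-statistic of the quadratic term and a significance flag.

## Synthetic data: what it emulates, what it does not

The helix generator composes per-step rigid transforms: rotation
R_z(twist)·R_x(tilt_x)·R_y(tilt_y) followed by a rise translation along the
local z. Step twist is Gaussian around a mean with a linear temperature trend
(reference 27 °C, the center of the simulated 7–47 °C design); rise and the
two tilt components are independent Gaussians. Defaults are one-time choices
representing the study conditions: the 33-bp reference sequence (RNA form),
32.7°/step and 2.8 Å/step (consensus A-form dsRNA), and fluctuation scales
(twist 4°, rise 0.2 Å, tilt 2° per step) chosen as realistic magnitudes for
~µs duplex ensembles — the sources state no fluctuation values, so these are
free parameters of the generator, not measurements. Broken pairs are planted
as independent per-(snapshot, pair) Bernoulli events realized by displacing
the complementary base 2.5 Å along the hydrogen-bond direction, which puts
every donor–acceptor distance at least 1 Å beyond the 4 Å cutoff; the default
rate is 0.

Each base is a rigid planar heavy-atom model placed exactly in the pair
frame, so the generator omits: intra-pair deformations (propeller, buckle —
hydrogen-bond distances are noise-free by construction), sequence-dependent
step parameters, backbone and sugar atoms, bending correlations and
autocorrelation in time (snapshots are i.i.d.). Passing recovery tests
therefore demonstrates the correctness of the analysis chain, not force-field
realism; in particular the ~80% kept fraction reported for real simulated
trajectories depends on force-field fluctuations and is treated as
qualitative only.

The tweezer generator produces Gaussian-shaped curves (default width 8 turns,
amplitude 0.35 μm over a 0.29 μm baseline on a −20..+20 turns grid) with
i.i.d. extension noise of 5 nm, approximating a 10×-averaged recording of a
3.3 kbp tether at ~0.3 pN; drift, bead-tracking artifacts and
plectoneme-buckling asymmetries are not modeled.

## Numerical choices

- Unwrap ties (exact half-multiples) resolve by `round`, i.e. toward even;
  unreachable in practice.
- Near-degenerate screw steps fall back to pure translation below 0.01°.
- Frame validation requires orthonormal triads (1e-6) and det +1.
- Gaussian peak fits raise a diagnostic error carrying the initialization if
  they do not converge; a negative fitted width is reflected (the model is
  even in w).
- The per-temperature generator RNG derives from (seed, temperature) through
  `numpy.random.SeedSequence`, so ensembles at different temperatures are
  decorrelated while identical inputs are bit-identical.
- Problem sizes used by the shipped recovery studies: 100 seeds of 6 tethers
  × 6 temperatures for the tweezer pipeline, 25 seeds of 200 snapshots × 5
  temperatures for the frame-ensemble slope, 1000 random rigid transforms for
  the screw-decomposition cross-check. These sizes give Monte-Carlo standard
  errors comfortably below the tested tolerances.

## Known limitations

- No Curves+-style smoothed helical axis, and no roll/tilt/slide/shift or
  intra-pair parameters; the geometry layer is deliberately limited to what
  the twist analysis needs.
- The WLC layer is inextensible and torsionally uncoupled; enthalpic
  stretching and plectoneme mechanics are out of scope.
- The groove model is unit-agnostic: it propagates whatever units the
  supplied surface carries and makes no claim about externally digitized
  datasets.
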