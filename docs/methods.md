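# Methods

`sobpkit` is a one-dimensional water-phantom simulator for proton
spread-out Bragg peaks (SOBPs). It exists to study *range modulation*:
deliberately splitting a beam's dose across two or three copies with
slightly different ranges so that the distal falloff is smeared and the
elevated relative biological effectiveness (RBE) at the end of range is
diluted. Everything below is computed on depth-dose curves over a
uniform grid of water-equivalent depth; no patient geometry, lateral
profiles or 3-D dose are modelled.

## Pristine Bragg peak model

A single proton energy is represented by the Bragg-Kleeman range-energy
power law. Differentiating `R = alpha * E^p` gives the straggling-free
stopping kernel

    d0(z; R) = (R - z)^(1/p - 1),   0 <= z < R,   else 0,

with `p = 1.77` for protons in water. The kernel's integrable
divergence at `z = R` is the Bragg peak. Range straggling is modelled
as a Gaussian spread of the stopping depth with standard deviation
`sigma(R) = 0.012 * R^0.935` mm (about 1.3 mm at `R = 150` mm), and the
straggled curve is the convolution

    D(z) = int_{R-6s}^{R+6s} d0(z; r) phi(r; R, s) dr.

Because the integrand is singular at `r = z`, the quadrature
substitutes `u = (r - z)^(1/p)`, after which the integrand
`p * phi(z + u^p)` is smooth; 96-node Gauss-Legendre then converges far
below the 1e-4 relative level the tests assert (halving the node count
moves no point of the default curve by more than 1e-4 relative).
Curves are normalized to a maximum of 1; absolute dose lives in the
SOBP weights. The model deliberately omits nuclear-interaction buildup,
the low-dose halo, and any beam energy spread — consequences are noted
under *Limitations*.

`sigma` uses a `None` sentinel meaning "follow the default rule", so a
range shift applied by a modulation scheme automatically recomputes the
straggling width from the shifted range, while an explicitly set width
is preserved.

## SOBP composition and plateau weights

An SOBP places `num_peaks` pristine peaks at nominal ranges
`distal_range - k * peak_spacing` (defaults: 4 peaks, 6 mm spacing — a
fixed property of the emulated delivery system — distal range 150 mm).
The plateau is the interval from the shallowest nominal range to the
distal range, shrunk by a 1 mm margin at each end; weights are solved
by nonnegative least squares (`scipy.optimize.nnls`) against a flat
target of 100 arbitrary units on the plateau grid points, so all
reported doses read as percentages of prescription. Exactly duplicate
peaks make the design singular; the solver groups them, warns, and
splits the group weight equally (the minimum-Euclidean-norm minimizer,
a deterministic tie-break). A single-peak "SOBP" is handled directly:
its weight is the prescription divided by the curve maximum.

A consequence worth stating plainly: with peaks whose only width comes
from range straggling (~1.3 mm sigma), a 6 mm spacing leaves deep
valleys between peak maxima and a sag at the distal plateau edge, and
the NNLS-optimal plateau of the default beam retains a peak-to-trough
flatness of roughly 33% (the demo prints the exact value). This is not
a solver artifact — no nonnegative weighting of this peak-model class
flattens that plateau to the few-percent level — but a property of the
simplified peak model; clinical delivery systems add beam energy spread
and ridge-filter broadening that this model intentionally leaves out.
Metrics that compare deliveries of the *same* beam (the package's
purpose) are unaffected by the ripple's absolute size.

## Distal-edge RBE model

Planning practice takes proton RBE as a uniform 1.1; measured data show
it rising over the last few millimetres of each peak. The package uses
an analytic hyperbolic-tangent ramp per pristine peak `k`:

    RBE_k(z) = b * (1 + a * s((z - z_k)/lambda)),   s(x) = (1 + tanh x)/2

with baseline `b = 1.1`, saturation fraction `a = 0.35` and
characteristic length `lambda = 2` mm. `z_k` is the depth of the
*straggled* pristine curve's maximum (located on an internal 0.02 mm
grid), not the nominal range. The RBE-weighted dose applies each ramp
to its own peak's dose before summation:

    D_bio(z) = sum_k w_k * D_k(z) * RBE_k(z).

Two conventions were genuinely open and are resolved as follows:

* "saturating at 35%" is read as multiplicative excess over the
  baseline, so the distal asymptote is `1.1 * 1.35 = 1.485`. This keeps
  "35%" interpretable as a percent increase in biological effect; the
  additive reading (asymptote 1.45) is reachable by setting
  `saturation_fraction = 0.45/1.1`.
* the ramp is half-range (0 to +35%), so the proximal plateau is
  exactly the uniform 1.1; a full-range ramp would contradict a uniform
  proximal RBE.

Setting `saturation_fraction = 0` recovers uniform-1.1 planning exactly
and is used as a degenerate-model check throughout the tests.

## Range-modulation schemes

A scheme is a list of `(range_shift, weight_fraction)` pairs with
positive fractions summing to 1 and distinct shifts.

* two-way: `[(0, 1/2), (-delta, 1/2)]`, default `delta = 3` mm — half
  the 6 mm pristine-peak spacing;
* three-way: `[(0, 1/3), (-step, 1/3), (-2*step, 1/3)]`, default
  `step = 2` mm, i.e. shifts of 2 and 4 mm.

Shifts are *negative* (shallower) by default: the point of the
technique is to let a beam stop short of, never through, a downstream
organ at risk. A `forward=True` flag flips the sign for exploration.
Applying a scheme shifts every pristine peak's nominal range (with
sigma recomputed under the default rule, since a range change on a real
delivery system changes the straggling) and scales the weights by the
fraction; the combined physical and biological doses are sums over the
sub-beams. The identity scheme reproduces the unmodulated curves
bit-for-bit.

## Metrics

All reference levels are anchored on the unmodulated beam so reports
for different schemes are comparable:

* plateau reference = mean physical dose over the plateau;
* flatness = `100 * (max - min)/mean` over a region (percent,
  scale-invariant);
* "range" = R90, the deepest crossing of 90% of the reference on the
  distal side, by linear interpolation (R80 available via the
  `fraction` argument);
* biologically effective range uses the reference `baseline *
  plateau_reference`, so the extension `r90_bio - r90_phys` measures
  the distal RBE ramp and is exactly 0 when the saturation is 0;
* the terminal window is `r90_phys +- 5` mm (configurable) around the
  *unmodulated* physical R90;
* terminal mean RBE = delivered biological dose divided by the
  *planned* (unmodulated) physical dose, summed over the window. For an
  unmodulated delivery this is the ordinary dose-weighted mean of
  `D_bio/D_phys`; for a modulated one it is the effective RBE the
  plan's terminal region actually receives. This is the quantity the
  technique reduces. (Normalizing instead by the modulated physical
  dose produces a ratio that *rises* under modulation — the pulled-back
  copy carries its own saturated-RBE terminal region into the window —
  and so cannot express the mitigation at all; the tests verify the
  orderings under the planned-dose definition.)
* distal hotspot ratio = maximum biological dose from the plateau
  onward, relative to the biological plateau level;
* `dose_beyond` = integral physical dose beyond the planned R90 and
  beyond offsets of 1, 2, 3 and 5 mm — the tail an organ at risk
  downstream would absorb.

`compare` reports per-metric deltas (modulated minus unmodulated) with
`improved` / `worsened` / `unchanged` flags at a 1e-6 tolerance; R90
positions are locations, not qualities, and are flagged
`changed`/`unchanged` only.

## Numerical choices

* depth grid: 0.1 mm spacing (0.5 mm enforced maximum), default span
  `[0, distal_range + 10]` mm — 1651 points for the canonical beam;
* quadrature: 96 Gauss-Legendre nodes after the singularity-removing
  substitution; integration window `R +- 6 sigma`, outside which the
  curve is exactly zero;
* peak-maximum location: argmax on an internal 0.02 mm grid, cached per
  peak; for `sigma = 0` the divergent kernel's maximum is the last grid
  point below `R`;
* NNLS tie-break for duplicate peaks: equal split within each duplicate
  group;
* uniform-grid check at 1e-9 relative; curve values validated
  nonnegative; undefined ranges propagate as NaN in reports and as an
  `undefined` sentinel in report files.

## What the fixtures emulate — and what they do not

The canonical fixtures (4-peak/6 mm/150 mm SOBP, its two-way and
three-way modulated deliveries, and a single pristine peak) emulate a
uniform-scanning delivery of a mid-range clinical beam. They do not
emulate: beam energy spread (plateau ripple is therefore exaggerated),
nuclear buildup and halo dose (entrance dose is underestimated),
lateral penumbra, tissue heterogeneity, or any LET- or
fraction-size-dependent RBE (the tanh ramp is an illustrative analytic
stand-in, not a mechanistic model). Passing tests therefore demonstrate
the *relative* behaviour of range modulation — falloff smearing, dose
and effective-RBE reduction in the terminal window, the ~0.5 mm
biological range extension of this model — not absolute dosimetry of
any particular machine.

## Known limitations

* The plateau-flatness absolute value is dominated by the missing
  beam-energy-spread term (see above).
* The biological range extension depends on the falloff sharpness; with
  the default straggling rule it is ~0.5 mm, at the low end of the
  1-2 mm usually quoted for clinical falloff widths.
* Range modulation worsens *physical* plateau flatness and the distal
  falloff sharpness by construction; the package quantifies, but does
  not judge, that trade.
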