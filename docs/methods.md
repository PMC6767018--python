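# Methods

This note records the models `actispec` implements, the defaults it ships,
and the choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Decay kinetics

The bundled chain is Ac-225 → Fr-221 → At-217 → Bi-213 → (97.8 % Po-213 /
2.2 % Tl-209) → Pb-209 → Bi-209 (sink), with working half-lives 10 d,
4.9 min, 32.3 ms, 46 min, 4.2 µs, 2.16 min, 3.23 h. The gamma emitters use
the rounded values (10 d / 4.9 min / 46 min) so that the stated equilibrium
behavior is reproduced exactly; a user table with evaluated-data precision
can be substituted via `load_chain`.

Abundances are solved in closed Bateman form with branching,
N_i(t) = Σ_j c_ij·e^(−λ_j t), via the standard coefficient recursion
c_ij = (Σ_p b_{p→i} λ_p c_pj)/(λ_i − λ_j). A numerical ODE treatment was
rejected because At-217 and Po-213 give the system a stiffness ratio of
~10¹²; the stiff integrator survives only as a test oracle (agreement to
1e−6 relative for the three gamma emitters over 12 h). Degenerate decay
constants (none occur in the bundled chain) are handled by a 1e−9 relative
jitter, numerically indistinguishable from the exact confluent limit at
float64 precision.

"Time to secular equilibrium" has no canonical threshold, so the tolerance
is a required argument. Two references are offered: the ratio's own
asymptote r∞ = lim A_d/A_p (appropriate for "within x of equilibrium")
and unity (appropriate for "daughter tracks parent"). The search uses a
1-minute grid over 24 h by default and returns the first grid time after
which the criterion holds at every later grid point.

## Photon transport

Analog Monte Carlo with photons only; secondary electrons deposit their
energy at the interaction site. At well-counter energies (≤ 662 keV) the
electron ranges in NaI are sub-millimetre and bremsstrahlung yield is far
below one percent, so local deposition is the appropriate level of detail
for 12.5 keV analyzer bins.

* **Geometry.** Axially symmetric cells compiled onto an (r, z) grid
  partition of a bounding cylinder; gaps are air, the NaI boxes are the
  scoring region. Default dimensions: 2.54 cm crystal radius and 5.08 cm
  height (2″ × 2″), 16 mm well bore, 38 mm well depth, 1.6 mm MgO
  reflector, 1 mm Al housing, 1.2 cm Pb side shield, a 30 mm Al cylinder
  standing in for the photomultiplier, and a polyethylene tube (5 mL
  nominal) holding a 1.00 mL water column as the source volume. Only the
  crystal size, shield, tube volumes and PMT diameter are published for the
  modeled instrument; the rest are explicit configuration parameters and
  nothing in the analysis depends on their exact values.
* **Cross sections.** Per-element mass attenuation is evaluated in code
  and tabulated per material on a log grid (10–800 keV, log-log
  interpolation): incoherent scattering from the exact integrated
  Klein–Nishina cross section (free electrons; binding neglected),
  photoelectric absorption from a Z^3.8/E³ power law anchored to iodine at
  100 keV with K-edge jumps for I (33.2 keV) and Pb (88 keV), coherent
  scattering from a Z^2.5/E² law anchored to water. This puts the partials
  within a few tens of percent of evaluated data — adequate for response
  *shape* — and every quantitative transport check in the suite is
  self-consistent (the closed-form oracle uses the same table).
* **Sampling.** Source positions uniform in the water column, directions
  isotropic, line energies proportional to activity × intensity. Compton
  scattered energies are drawn by direct rejection against the exact
  Klein–Nishina ε-density (ε + 1/ε − sin²θ on [1/(1+2k), 1]) — equivalent
  in distribution to the classic composition–rejection scheme but simpler
  to vectorize and verify. Rayleigh scattering (on by default) redirects
  with the Thomson 1 + cos²θ law instead of form-factor data; it carries
  no energy and is a percent-level effect here. Histories terminate on
  escape, absorption, or at the 10 keV cutoff (terminal local deposit).
* **Tally.** One history is one emitted photon; the per-bin expectation is
  scaled by Σ A·Y_tot·t_live/n_histories, and per-bin relative errors are
  1/√(raw tally). Identical seed and configuration reproduce spectra bit
  for bit; batches are processed in 250 k-photon chunks for cache locality.

The 1 keV "high-definition" tally attributes overlapping emissions to
nuclides and supports kinematic checks (the 661.6 keV Compton edge at
477.3 keV). The edge locator uses a midpoint-crossing estimate between
continuum plateaus rather than a steepest-gradient search, which is not
robust to bin-level counting noise.

## Gaussian energy broadening

FWHM(E) = a + b·√(E + c·E²). The parameter set carries an explicit energy
unit, default **MeV**: the shipped default parameters (a = 0.005616,
b = 0.0521, c = 2.027) give ≈ 10.6 % resolution at 662 keV, the expected
scale for a NaI well counter, whereas a keV reading of the same numbers
would not. Fitting is nonlinear least squares (initial a = min FWHM,
c = 1, b from the extreme points); R² is reported and a constant-FWHM
dataset degrades gracefully to (a = mean, b = c = 0).

Smearing is deterministic by default: each source bin's mass is spread
with the Gaussian of σ(E_center) integrated over destination bins. The
sub-zero tail accumulates in the lowest bin (a recorded pulse height
cannot be negative); only the tail beyond the top edge is lost, so totals
are conserved to well under 0.1 % for the spectra of interest. A
stochastic mode (per-count energy jitter) exists for fixture realism.
Per-bin statistical errors are carried through smearing unchanged — an
approximation, since the kernel correlates neighbouring bins — and are
used only for the σ_MC estimate.

## Spectroscopy

Peaks are fitted with a Gaussian on a linear baseline inside windows of
±2.5 analyzer bins around 99.8, 218.1 and 440.5 keV; the net area is the
Gaussian integral with uncertainty from the fit covariance. Because those
windows span only five or six bins, a free five-parameter fit is
under-determined under counting noise; when the resolution calibration is
supplied, σ is fixed to the calibrated value at the window center (the
amplitude then carries the area uncertainty). This is the standard
stabilization when FWHM(E) is known and reduces the area estimator's
spread by an order of magnitude in the bundled fixtures.

Activity follows A = f·N/(t·ε·Y) with Y = 0.010/0.114/0.259 per alpha
decay for Ac-225/Fr-221/Bi-213. The instrument-specific calibration
factor f defaults to 1 and is never folded into the formula. Dead time is
nonparalyzable, estimated by the exact two-source solution (the
first-order formula is available for cross-checking at small losses) and
applied or corrected on the *total* spectrum rate with proportional
thinning across bins — the single-channel-analyzer picture in which
losses are rate-driven and energy-independent. Rates are corrected before
peak fitting, after background subtraction.

## Matching and the response curve

The comparison statistic is the mean percent difference over analogous
bins with the symmetric denominator, 200·(s−m)/(s+m); bins where both
spectra fall below 10 counts are excluded (configurable), since the
idealized detector model is least trustworthy in the low-count region.
The sweep regression needs a signed quantity to have an x-intercept, so
the fit uses the signed form (simulated − measured) while match quality
is reported as the absolute form.

Two procedural details matter numerically:

* The per-bin statistic saturates at ±200, so over a wide sweep the
  signed mean is concave in activity and a single straight-line fit
  overshoots the root by several percent. After the first ±50 % sweep
  (7 points) a second ±15 % sweep recentered on the first x-intercept is
  fitted by default, cutting the curvature bias to the few-per-mille
  level. Single-pass behavior is available (`refine_fraction=None`).
* When dead-time losses are large the matched activity lies far below the
  ion-chamber guess and a symmetric sweep around the guess never changes
  sign. The default is the conservative error ("bracket wider"); an
  opt-in `auto_expand` recenters geometrically, which the response-curve
  driver uses.

σ_NaI and σ_MC are obtained by propagating, respectively, Poisson noise
of the measured bins and the simulation's per-bin tally errors into the
mean signed difference and dividing by the fitted slope; σ_MC falls as
1/√histories. The total is the quadrature sum with the ion-chamber σ_IC.
The response curve is kept pointwise with linear interpolation — no
parametric saturation model is imposed.

## Synthetic fixtures

`make_measured_spectrum` composes the forward model: ideal transport
spectrum → deterministic broadening → dead-time thinning of the total
rate → per-bin Poisson sampling → additive background. Defaults mirror
the emulated measurement conditions: 30 s live time, τ = 4.6 × 10⁻⁵ s,
flat 150 counts/min background (an exponential shape is available), and
a six-sample ladder of ion-chamber readings 70.3–447.7 kBq with the three
gamma emitters at equal (equilibrium) activities, one third of the summed
reading each. Every fixture is bit-reproducible from (config, seed), and
the generating truth is stored in the spectrum metadata.

What the fixtures do *not* emulate: pulse pile-up continua, gain drift,
cascade-summing coincidences, detector impurities, and any mismatch
between the modeled and the real instrument geometry. Passing recovery
tests therefore demonstrates internal consistency of the pipeline — that
the analysis inverts the forward model it claims to invert — not field
accuracy for a particular physical detector, which requires the usual
source-based calibrations.

## Problem sizes

Deterministic checks (kinetics, calibration fits, dead-time algebra) run
on 1-minute/24 h grids and five-point calibration sets. Stochastic
validations use 10⁵ histories for the attenuation oracle, 10⁶ for the
Compton-edge and activity-recovery checks (the matched activity is
required within 3 % of truth there), and ~1.2 × 10⁵ histories per sweep
point across the six-sample ladder for the saturation property — sizes
chosen so the statistical noise sits comfortably below each check's
tolerance while the full suite stays in the minutes range.

## Known limitations

* Photoelectric/coherent cross sections are power-law evaluations, not an
  evaluated-data library; absolute peak efficiencies are indicative only.
* No electron transport, fluorescence escape (off by default), or
  coincidence summing; iodine K-escape is invisible at 12.5 keV binning
  but matters for 1 keV spectroscopy below ~150 keV.
* The bundled photon line list is compact (principal lines at the
  quantification energies plus the strongest secondaries), not a complete
  evaluation; users with stricter needs should supply their own table.
* Dead-time thinning is energy-independent by construction; detectors
  with energy-dependent processing chains violate this assumption.
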