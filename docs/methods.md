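# Methods

This note records the models, parameter choices and numerical decisions
behind `tendonmech`, and what the synthetic-data validation does and does
not demonstrate about real fascicle data.

## Tensile property derivation

The pipeline assumes quasi-static, rate-independent engineering stress and
strain: sigma = P/A with the fascicle modelled as a circular cylinder
(A = pi d^2/4 from the mean of repeated thickness readings) and
eps = x/L0. No viscoelasticity, grip-compliance or cross-section
non-circularity correction is applied.

**Zeroing.** The specimen is stretched from slack, so the early record is
noise around zero load. The origin is the first sample whose load is at or
above `load_cutoff_fraction` (default 0.01) of the maximum load; the
comparison is `>=` so the choice is deterministic on plateaus. L0 is the
absolute grip-to-grip displacement at that sample; displacement and load
are then offset to zero there. Subtracting the cutoff load biases all
stresses down by about 1% of sigma_U — visible in the worked example — and
truncating the sub-cutoff toe shifts strains by the small cut strain. A
manual truncation mode (`loadat1percent=False` with a caller-supplied
start index) exists for traces whose low-load noise defeats the automatic
cutoff. Traces whose load never reaches the cutoff, or with non-positive
L0, are rejected rather than repaired.

**Yield detection.** dsigma/deps is evaluated by central finite
differences (one-sided at the ends) of a least-squares polynomial of
degree `orderpoly` (2-7, default 5) fitted to the stress-strain samples
from the origin to the maximum-stress index. Smoothing before
differencing is essential on noisy data: finite differences of the raw
record amplify sensor noise by 1/delta_eps and inflate the maximum-slope
estimate by tens of percent. The cost is resolution: a global degree-5
polynomial cannot track a slope transition much sharper than its own
bandwidth, so on an artificially sharp sigmoid it localises the yield
point to within a grid step but underestimates the peak slope. On curves
whose pre-peak segment is polynomial-smooth (the synthetic family below,
and typical fascicle curves) the stiffness estimate is accurate to a few
percent. Numerical ties in the derivative (exactly linear data) break to
the earliest index; a yield point on the fit boundary attaches a warning.
Yield stress and strain are read from the fitted polynomial, not the raw
samples.

**Rupture and energies.** r is the last sample with eps <= `laststrainpt`
when that estimate lies beyond the maximum-stress strain, else the final
sample (with a warning when the estimate is below eps at maximum stress).
Strain-energy densities use the trapezium rule over segments sharing
endpoint samples, so u_F = u_P + u_R and u_0 = u_Y + u_F hold exactly in
floating point. Aggregation averages specimens within a mouse, then mice
within an age group; the group SEM uses n = mice, treating fascicle
segments as technical replicates whose variance is not propagated upward.

**Units.** Load is recorded in gram-force; stress uses
sigma[MPa] = P[g] x 9.80665e-3 / A[mm^2] (standard gravity), exposed in
the analysis config. The raw mV transducer columns are read and carried
through untouched; the pipeline trusts the pre-converted mm/gram columns.

## Fibril structure

Diameters are equivalent-circle: D = sqrt(4 a_f/pi), the exact inverse of
a_f = pi D^2/4. Per-image area fraction counts clipped boundary fibrils
(their clipped area); boundary fibrils are excluded from the diameter
histogram because a clipped area underestimates D. Histogram bins are
right-open [k w, (k+1) w) with w = 20 nm by default — boundary diameters
deterministically land in the upper bin — but readers honour whatever
edges a sheet declares. The two-stage image selection (uniform random
tags, stable sort, N_c ~ uniform{4..11}) is a pure function of (pool,
seed). No shrinkage correction for TEM processing is applied; reported D
and rho carry that bias.

## Mixture fitting by simulated annealing

The objective is the residual sum of squares between the normalised
histogram and the composite of unit-amplitude Gaussians on bin centres,
with amplitudes solved per proposal by non-negative least squares
(amplitudes are proportions; a plain least-squares path exists behind a
flag). Annealing schedule defaults: initial temperature 0.5, reduction
factor 0.9, 100 temperature steps, at most 100 proposals and 10
Metropolis acceptances per step. Proposals draw a value through the
affine map A + B*u, u ~ uniform(0,1), per component (the classic
parameter-file coefficient pairs), clipped to the diameter limits; one
randomly chosen parameter (a mean or an SD) is redrawn per move, which
keeps the Metropolis chain local enough to matter — redrawing all four
parameters each move degrades the final objective several-fold. A
"success" is any Metropolis acceptance. The best-ever state is returned
(components sorted, D_D1 < D_D2), and the conventional second pass
re-centres the proposal ranges on the first estimates at a quarter of the
original width (seed advanced by one, so a shrink of 1 acts as an
independent replicate); the better of the two fits by objective is kept.
Default ranges derive from the histogram support: the occupied span is
split into equal per-component mean slices and SD proposals run from half
a bin width to a third of the span. No early-stopping criterion is added
beyond the fixed step count. With heavily overlapping subpopulations
(mean separation below roughly one pooled SD) the two-component fit is
weakly identified and recovered means can be biased — the synthetic
age-series shows this for its youngest group — which is a property of the
model, not the optimiser. An EM fit (scikit-learn) on raw diameters is
used in development as an independent cross-check, never as the
implementation.

## Uncertainty budgets and power

Add-in-quadrature: root-sum-of-squares of absolute uncertainties for sums,
of relative uncertainties (scaled by |Q|) for products; a squared variable
contributes its relative term twice as two independent entries, so
A = pi d^2/4 carries sqrt(2) delta_d/d. The alternative correlated
convention (2 delta_d/d) is about 40% larger; published worked values mix
both conventions, and this package applies the sqrt(2) form consistently.
The budget treats the gauge length L0 as nominal (delta L0 = 0) and, for
the area-fraction delta, conservatively assigns the summed fibril area the
single-fibril relative uncertainty. A Monte-Carlo propagation with
Gaussian input errors (1e5 draws) cross-checks the strain and stress
deltas to within 5%.

Welch power uses the noncentral t distribution with Welch-Satterthwaite
degrees of freedom, noncentrality |m1-m2|/sqrt(sd1^2/n1 + sd2^2/n2),
alpha = 0.05 default, one- or two-sided; SDs are recovered from reported
SEMs via SD = SEM sqrt(n). **Limitation:** the formula plugs the estimated
df in as fixed. At 3-4 subjects per group with strongly unequal variances
it overstates the true (simulated) power by 2-5 percentage points; the
package's Monte-Carlo power exposes this, one test asserts the bias
direction, and the calibration suite checks 0.02-level agreement at group
sizes of 6+, where the approximation is sound. Retrospective powers at
n = 3-4 should be read with that tolerance in mind.

## Synthetic-data generator

**Traces.** The pre-peak stress-strain segment is a single quintic with
six prescribed conditions: sigma(0) = 0, toe-start slope 0.2 E (the
smallest round fraction keeping the polynomial monotone at the default
landmarks), slope exactly E with zero curvature at eps_Y, zero slope and
value sigma_U at eps_U; after the peak, stress decays linearly to 20% of
sigma_U at the rupture strain. One smooth closed-form family was chosen
deliberately: every landmark and every strain-energy integral is analytic,
and the curve has no derivative corners for the polynomial-smoothing
derivative to round off, so end-to-end recovery isolates the pipeline's
own bias (zeroing offset, discretisation) rather than a model mismatch.
The yield stress is therefore a derived quantity of (E, eps_Y, eps_U,
sigma_U) rather than an independent dial. Defaults (E = 600 MPa,
sigma_U = 27 MPa, eps_Y = 0.05, eps_U = 0.09, rupture 0.13, L0 = 5 mm,
d = 0.3 mm, load noise SD 0.3 g) sit at adult mouse tail-tendon scales;
displacement advances at 0.067 mm/s sampled at 20 Hz, recorded as
absolute grip-to-grip travel with 0.5 mm of pre-taut slack. The mV signal
columns are affine maps of the physical columns (arbitrary gain/offset),
exercising the reader's contract without real calibration constants.
Individual specimens must satisfy E >= sigma_U/eps_U; published *group
means* of these quantities need not, so the age-series driver derives
eps_U = 2 sigma_U/E per group. What passing recovery tests do **not**
show: robustness to viscoelastic rate effects, grip slippage, mid-test
partial ruptures, or curves whose true shape departs from a smooth
monotone toe — real records fail in ways this family does not emulate.

**Diameters and fields.** Diameter samples draw from a two-Gaussian
mixture (defaults 100/250 nm, SDs 30/50, equal weight, n = 2000 — a
typical aged-tendon separation; negative draws are redrawn) with
per-draw component labels kept for oracle checks. Disc fields place
non-overlapping circles with mixture-drawn diameters uniformly over a
4x5 um^2 field by rejection sampling until the target area fraction is
reached; boundary-crossing discs are clipped against the frame (shapely,
128-segment circles) and their clipped area counted. The recorded rho is
the exact bookkept ratio. Sequential random placement jams near
rho ~ 0.55, so drivers target 0.45-0.5; the dense fractions of mature
tendon (0.76-0.85) are beyond this placement algorithm, and the 0.91
parameter cap is a validity bound, not an attainability claim.

## File formats

Raw traces use the tab-delimited five-column dialect (time ms, two mV
signal columns, displacement mm, load grams), period decimal separator
only; an optional header row is auto-detected. Derived sheets are CSV
mirrors of the deposited worksheet layouts (specimen columns A-O,
per-mouse A-L, per-group means+SEMs A-U; structural area-fraction and
bin/frequency/normalised-frequency sheets). Legacy binary spreadsheet
workbooks are out of scope; the run log is one timestamped key=value line
per analysis. Round trips through any writer/reader pair are lossless to
1e-9.

## Problem sizes in the shipped suites

The validation suites use 50 traces for mechanical recovery, 5 replicate
populations (n = 2000 each) for mixture recovery, 1e4 draws for the
Metropolis frequency check, 2e4 replicates per Monte-Carlo power, 1e5
draws for the budget cross-check, and one packed field of ~900 discs —
sizes at which every stochastic tolerance in the tests is a >=3-sigma
bound.
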