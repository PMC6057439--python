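# tendonmech

Tensile mechanics, collagen-fibril morphometry and metrology for
tail-tendon fascicle datasets from ageing mouse studies.

Tendon is a collagen-fibre composite whose mechanical behaviour changes
progressively with age. A standard way to quantify this is to stretch
individual tail-tendon fascicles to rupture, derive tensile properties
from the load-displacement record, and relate them to the collagen fibril
ultrastructure measured on transmission electron micrographs (TEM).
`tendonmech` implements that full analysis chain as a tested Python
library with a thin CLI, plus a ground-truthed synthetic-data generator so
every stage can be validated end to end without animal data.

## What it computes

**Tensile properties per fascicle specimen.** A slack-to-taut trace is
zeroed at a load cutoff of 1% of the maximum load; the grip-to-grip
displacement there defines the gauge length L0. The record is converted to
engineering stress and strain (sigma = P/A with A = pi d^2/4; eps = x/L0)
and four landmarks are located on the curve: origin O, yield point p (the
point of inflexion, where dsigma/deps — evaluated by finite differences of
a least-squares polynomial of degree 2-7 fitted from O to the maximum
stress — is largest; its slope is the stiffness E and its coordinates are
sigma_Y, eps_Y), maximum stress q (strength sigma_U at eps_U) and rupture
r. Strain-energy densities are trapezium-rule integrals over the segments:
resilience u_Y (O-p), plastic loading u_P (p-q), rupture u_R (q-r), with
u_F = u_P + u_R and u_0 = u_Y + u_F. Specimens (technical replicates) are
averaged per mouse, then per age group, with group SEM over mice.

**Fibril structure.** Equivalent-circle diameters D = sqrt(4 a_f / pi)
from traced cross-sectional areas; per-image area fraction
rho = sum(a_f) / field area (clipped boundary fibrils included); 20 nm
diameter histograms; and the two-stage randomised protocol that selects
N_c ~ uniform{4..11} micrographs per age group.

**Diameter subpopulations.** Fibril-diameter histograms are bimodal; a
two-component Gaussian mixture
`f(x) = sum_i amp_i exp(-(x-mu_i)^2 / 2 sigma_i^2)` is fitted to the
normalised histogram by simulated annealing (Metropolis acceptance,
initial temperature 0.5, reduction factor 0.9, 100 temperature steps, 100
configurations and 10 allowed successes per step) with amplitudes solved
by non-negative least squares at every proposal, followed by a refinement
run with narrowed proposal ranges. Components are reported sorted,
D_D1 < D_D2.

**Metrology.** Instrument uncertainties (displacement 0.01 mm, thickness
0.0025 mm, load 0.0001 g, TEM length 0.5 nm) propagate by add-in-quadrature
(`delta_Q = Q sqrt(sum (delta_a/a)^2)` for products, squared variables
contributing twice), with a Monte-Carlo cross-check; and Welch two-sample
power (unequal n and variance) from the noncentral t distribution with
Welch-Satterthwaite degrees of freedom.

## Worked example

```sh
$ tendonmech simulate trace --seed 1 --out mtt01_1_t1a.txt
wrote mtt01_1_t1a.txt (+ ground-truth sidecar)
$ tendonmech mech --input mtt01_1_t1a.txt --diameter 0.3 \
      --laststrainpt 0.14 --orderpoly 5 --load-at-1-percent y
wrote derived_parameters.csv: E=601.9 MPa, sU=26.68 MPa, u0=1.690 MPa
```

The simulated specimen was generated with a true stiffness of 600 MPa and
strength 27 MPa: the pipeline recovers E within 0.3% and sigma_U within
1.2% (the strength sits 1% low because zeroing subtracts the 1%-of-max
load offset). The sidecar JSON carries every true landmark so recovery can
be scored exactly. Power analysis works directly from published group
statistics (mean, SEM, n):

```sh
$ tendonmech power --mean1 26.6 --mean2 62.4 --sem1 3.2 --sem2 7.4 --n1 3 --n2 4
power = 0.9060
```

## Analysis scripts

`analysis/01_simulate_dataset.py` ... `05_uncertainty_power.py` rebuild a
full synthetic age-series study (8 age groups, 3-4 mice each, two fascicle
segments per mouse; per-group bimodal diameter populations and packed-disc
micrograph fields), derive and aggregate all properties, fit the diameter
subpopulations per group, and tabulate the uncertainty budget and
retrospective power contrasts. Each script prints what it found and writes
its tables under `results/`.

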