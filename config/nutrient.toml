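# Growth calibration for the nutrient compartment of the resource-partitioned
# treatment (high nutrients, low water): short primaries, dense lateral
# branching cascading to branching number 4.  Reverse-engineered from
# published per-order trait tables; an approximation, not a fit to raw data.
# Units: cm, days, degrees, g.

[calibration]
name = "nutrient"
max_order = 4

[order.0]
maxB = 10
r_mean = 0.9
r_sd = 0.08
lmax_mean = 9.0
lmax_sd = 1.2
la = 0.5
lb = 0.5
ln_mean = 0.18
ln_sd = 0.02
theta_mean = 5.0
theta_sd = 4.0
radius = 0.025
linear_density = 1.0e-3
tropism_sigma = 8.0

[order.1]
r_mean = 0.25
r_sd = 0.05
lmax_mean = 1.3
lmax_sd = 0.5
la = 0.4
lb = 0.3
ln_mean = 0.9
ln_sd = 0.15
theta_mean = 48.2
theta_sd = 7.0
radius = 0.015
linear_density = 3.0e-4
tropism_sigma = 15.0

[order.2]
r_mean = 0.15
r_sd = 0.03
lmax_mean = 0.55
lmax_sd = 0.25
la = 0.35
lb = 0.2
ln_mean = 0.5
ln_sd = 0.1
theta_mean = 55.5
theta_sd = 7.0
radius = 0.010
linear_density = 1.2e-4
tropism_sigma = 15.0

[order.3]
r_mean = 0.12
r_sd = 0.03
lmax_mean = 0.45
lmax_sd = 0.2
la = 0.25
lb = 0.2
ln_mean = 0.5
ln_sd = 0.1
theta_mean = 60.8
theta_sd = 7.0
radius = 0.008
linear_density = 1.0e-4
tropism_sigma = 15.0

[order.4]
r_mean = 0.1
r_sd = 0.02
lmax_mean = 0.5
lmax_sd = 0.2
la = 0.2
lb = 0.2
ln_mean = 1.0
theta_mean = 61.8
theta_sd = 7.0
radius = 0.007
linear_density = 1.0e-4
tropism_sigma = 15.0
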