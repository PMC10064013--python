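# Growth calibration for the water compartment of the resource-partitioned
# treatment (high water, no nutrients): long primaries, dense secondary
# emergence, then sharply reduced higher-order development (slow, short
# branching numbers 2-4).  Reverse-engineered from published per-order trait
# tables; an approximation, not a fit to raw data.
# Units: cm, days, degrees, g.

[calibration]
name = "water"
max_order = 4

[order.0]
maxB = 10
r_mean = 0.9
r_sd = 0.06
lmax_mean = 16.0
lmax_sd = 1.5
la = 0.5
lb = 0.5
ln_mean = 0.32
ln_sd = 0.03
theta_mean = 5.0
theta_sd = 4.0
radius = 0.03
linear_density = 1.15e-3
tropism_sigma = 6.0

[order.1]
r_mean = 0.18
r_sd = 0.05
lmax_mean = 0.9
lmax_sd = 0.35
la = 0.5
lb = 0.3
ln_mean = 0.9
ln_sd = 0.15
theta_mean = 53.0
theta_sd = 9.0
radius = 0.015
linear_density = 2.5e-4
tropism_sigma = 15.0

[order.2]
r_mean = 0.06
r_sd = 0.015
lmax_mean = 0.4
lmax_sd = 0.15
la = 0.25
lb = 0.15
ln_mean = 0.5
ln_sd = 0.1
theta_mean = 59.3
theta_sd = 7.0
radius = 0.010
linear_density = 1.2e-4
tropism_sigma = 15.0

[order.3]
r_mean = 0.06
r_sd = 0.015
lmax_mean = 0.25
lmax_sd = 0.1
la = 0.15
lb = 0.1
ln_mean = 0.5
ln_sd = 0.1
theta_mean = 60.9
theta_sd = 7.0
radius = 0.008
linear_density = 1.0e-4
tropism_sigma = 15.0

[order.4]
r_mean = 0.05
r_sd = 0.01
lmax_mean = 0.2
lmax_sd = 0.08
la = 0.1
lb = 0.1
ln_mean = 1.0
theta_mean = 62.3
theta_sd = 7.0
radius = 0.007
linear_density = 1.0e-4
tropism_sigma = 15.0
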