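# Growth calibration for both compartments of the resource-mixed treatment
# (water and nutrients available everywhere): intermediate between the
# nutrient and water calibrations.  Reverse-engineered from published
# per-order trait tables; an approximation, not a fit to raw data.
# Units: cm, days, degrees, g.

[calibration]
name = "mixed"
max_order = 4

[order.0]
maxB = 10
r_mean = 0.9
r_sd = 0.07
lmax_mean = 12.0
lmax_sd = 1.4
la = 0.5
lb = 0.5
ln_mean = 0.26
ln_sd = 0.025
theta_mean = 5.0
theta_sd = 4.0
radius = 0.028
linear_density = 9.0e-4
tropism_sigma = 7.0

[order.1]
r_mean = 0.25
r_sd = 0.05
lmax_mean = 1.1
lmax_sd = 0.4
la = 0.45
lb = 0.3
ln_mean = 0.9
ln_sd = 0.15
theta_mean = 51.5
theta_sd = 8.0
radius = 0.015
linear_density = 2.2e-4
tropism_sigma = 15.0

[order.2]
r_mean = 0.1
r_sd = 0.02
lmax_mean = 0.5
lmax_sd = 0.2
la = 0.3
lb = 0.2
ln_mean = 0.45
ln_sd = 0.1
theta_mean = 55.4
theta_sd = 7.0
radius = 0.010
linear_density = 1.1e-4
tropism_sigma = 15.0

[order.3]
r_mean = 0.09
r_sd = 0.02
lmax_mean = 0.35
lmax_sd = 0.15
la = 0.2
lb = 0.15
ln_mean = 0.5
ln_sd = 0.1
theta_mean = 65.3
theta_sd = 7.0
radius = 0.008
linear_density = 1.0e-4
tropism_sigma = 15.0

[order.4]
r_mean = 0.08
r_sd = 0.015
lmax_mean = 0.3
lmax_sd = 0.12
la = 0.15
lb = 0.15
ln_mean = 1.0
theta_mean = 61.4
theta_sd = 7.0
radius = 0.007
linear_density = 1.0e-4
tropism_sigma = 15.0
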