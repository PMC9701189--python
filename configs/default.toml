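# Default configuration (mirrors the built-in defaults; every value here can
# be edited and passed via `oxfire sweep --config ...` or load_config()).
#
# NOTE on provenance: the per-PFT base ignition efficiencies (ieff_base) and
# the heat-of-combustion coefficients alpha/beta are PLACEHOLDER values
# chosen per growth form, not published per-PFT constants.  beta is a
# complete-combustion (bomb-calorimeter-like) heat, and alpha is set so that
# alpha/20.95 + beta equals a conventional natural-fire heat of combustion at
# present-day oxygen (trees 17500, grasses 16500 kJ/kg).

[world]
n_lat = 36
n_lon = 18

# Per-band overrides (bands are latitudinal climate archetypes; longitude
# variants such as the savanna sector of the tropics are configured in code).
[world.bands.tropics]
p_annual = 2200.0            # mm/yr
wet_prob = 0.65              # annual-mean wet-day probability
lightning_per_km2_yr = 25.0

[world.bands.subtropics_arid]
p_annual = 280.0
lightning_per_km2_yr = 4.0

[world.bands.midlatitude]
p_annual = 760.0
season_conc = -0.90          # winter-wet, summer-dry
lightning_per_km2_yr = 6.0

[world.bands.high_latitude]
p_annual = 550.0
rh_base = 0.82               # low evaporative demand keeps fuels moist

[fire]
oxygen_effects = true        # false: evaluate every oxygen scaling at PAL
pi_floor = 1.0               # % ignition rating defining the moisture cap
ground_strike_fraction = 0.2
fire_duration_min = 240.0
base_ros = 8.0               # m/min, dry calm reference
wind_coeff = 0.5
bulk_density_ref = 20.0      # kg/m3
intensity_survival = 50.0    # kW/m
mortality_intensity_ref = 600.0
nesterov_rain_reset = 3.0    # mm/day
nesterov_scale = 5000.0
tau_fine = 2.0               # days
tau_woody = 15.0
moisture_floor = 5.0         # % dry mass
moisture_scale = 220.0
me_native = [30.0, 32.0, 34.0, 40.0, 20.0]   # % dry mass per fuel class
burn_scar_efolding_days = 150.0

[vegetation]
fpc_max = 0.95
tree_precip_base = 250.0     # mm/yr
tree_precip_span = 300.0
forest_threshold = 0.60      # tree cover defining forest

[experiment]
# The sweep: present-day level plus whole-percent steps up to 35 % vol.
o2_levels = [20.95, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35]
spinup_years = 200           # scaled-down spin-up; raise for slow equilibria
record_years = 10            # final decade averaged as output
no_fire_baseline = true
drift_tolerance = 0.02
moisture_band_edges = [20.0, 40.0, 60.0]     # % dry mass

# Example per-PFT override (placeholder constants, see note above):
# [pfts.boreal_needle_evergreen]
# ieff_base = 0.05
# susceptibility = 0.60
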