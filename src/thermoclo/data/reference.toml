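# Packaged reference scenario: the five-garment upper-body experiment.
# A standing subject (1.7 Met) in a 25 degC room with a 20 degC mean radiant
# temperature and 0.25 m/s air movement, wearing a plain cotton shirt whose
# average skin-to-fabric air gap (ease allowance) varies from 0.5 to 1.95 cm
# with garment size.  All blocks can be overridden via user config.

[fabric]
fiber = "cotton"
areal_density_g_m2 = 126.0
thickness_mm = 0.312
insulation_clo = 0.155
vapor_permeation_efficiency = 0.34
specific_heat_J_kgK = 1300.0
emissivity = 0.90

# average air-gap (ease allowance) thickness per garment size, metres,
# applied uniformly to every clothed segment
[garments]
A = 0.005
B = 0.008
C = 0.0115
D = 0.0155
E = 0.0195

[environment]
air_temperature_c = 25.0
radiant_temperature_c = 20.0
air_speed_m_s = 0.25
relative_humidity = 0.5

# per-segment skin/outer-surface convective and radiant coefficients,
# W/(m2 K), manikin-style values for ~0.25 m/s air movement
[surface]
h_c = [3.7, 3.0, 2.9, 3.0, 3.4, 3.4, 3.8, 3.8, 4.1, 4.1, 3.6, 3.6, 4.0, 4.0, 4.2, 4.2]
h_r = [4.1, 4.5, 4.4, 4.2, 4.8, 4.8, 4.9, 4.9, 3.9, 3.9, 4.6, 4.6, 5.4, 5.4, 4.2, 4.2]
skin_emissivity = 0.95

[scenario]
metabolic_rate_w_m2 = 100.4   # 1.7 Met, standing
duration_s = 1800.0           # thirty-minute run
time_step_s = 0.1             # fixed-step RK4 default
output_interval_s = 60.0
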