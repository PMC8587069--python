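# Packaged default body registry for the 16-segment, 65-node thermal model.
# Segment surface areas A_n/A_cl, segment heights and set-point temperatures are
# the published anthropometric tables for the segmented thermal manikin this
# model family is built around.  Node heat capacities, basal metabolic rates,
# basal blood-flow conductances and inter-layer conductances follow the classical
# Stolwijk multi-node structure; the numerical values here are reconstructed from
# standard segment masses, tissue specific heats and perfusion-metabolism
# coupling (see docs/methods.md).  Every value can be overridden via config.
# Units: areas m2, heights m, capacities Wh/degC, rates W, conductances W/K,
# temperatures degC.

[blood]
capacity_whK = 2.610
t_set = 36.7

[[segments]]
index = 1
name = "Head"
a_n = 0.14
a_cl = 0.14
height = 0.1894
clothed = false
c_whK = [3.01, 0.453889, 0.388194, 0.219778]
q_basal = [13.325866, 0.205013, 0.102507, 0.115176]
bf_basal = [11.993279, 0.184512, 0.092256, 0.524345]
d_cond = [0.84, 1.12, 1.4]
t_set = [36.9, 36.1, 35.8, 35.6]
t_init_clothing = [35.6, 35.6]

[[segments]]
index = 2
name = "Chest"
a_n = 0.175
a_cl = 0.1886
height = 0.5504
clothed = true
c_whK = [4.06875, 3.926667, 0.710417, 0.380267]
q_basal = [17.426132, 2.050133, 0.102507, 0.14397]
bf_basal = [15.683519, 1.84512, 0.092256, 0.655431]
d_cond = [1.575, 1.225, 1.225]
t_set = [36.5, 36.2, 34.5, 33.6]
t_init_clothing = [31.5, 29.2]

[[segments]]
index = 3
name = "Back"
a_n = 0.161
a_cl = 0.1735
height = 0.5023
clothed = true
c_whK = [4.06875, 3.926667, 0.710417, 0.380267]
q_basal = [10.250666, 2.050133, 0.102507, 0.132452]
bf_basal = [9.225599, 1.84512, 0.092256, 0.602996]
d_cond = [1.449, 1.127, 1.127]
t_set = [36.5, 35.8, 34.4, 33.2]
t_init_clothing = [31.5, 29.2]

[[segments]]
index = 4
name = "Pelvis"
a_n = 0.221
a_cl = 0.2347
height = 0.2134
clothed = true
c_whK = [5.90625, 5.7, 1.03125, 0.552]
q_basal = [22.551465, 2.562667, 0.102507, 0.181814]
bf_basal = [20.296319, 2.3064, 0.092256, 0.827715]
d_cond = [1.989, 1.547, 1.547]
t_set = [36.3, 35.6, 34.5, 33.4]
t_init_clothing = [31.4, 29.0]

[[segments]]
index = 5
name = "L-shoulder"
a_n = 0.096
a_cl = 0.102
height = 0.175
clothed = true
c_whK = [0.583333, 1.52, 0.166667, 0.122667]
q_basal = [0.61504, 0.46128, 0.030752, 0.078978]
bf_basal = [0.553536, 0.415152, 0.027677, 0.359551]
d_cond = [0.768, 0.576, 0.672]
t_set = [35.8, 34.6, 33.8, 33.4]
t_init_clothing = [31.4, 29.0]

[[segments]]
index = 6
name = "R-shoulder"
a_n = 0.096
a_cl = 0.102
height = 0.175
clothed = true
c_whK = [0.583333, 1.52, 0.166667, 0.122667]
q_basal = [0.61504, 0.46128, 0.030752, 0.078978]
bf_basal = [0.553536, 0.415152, 0.027677, 0.359551]
d_cond = [0.768, 0.576, 0.672]
t_set = [35.8, 34.6, 33.8, 33.4]
t_init_clothing = [31.4, 29.0]

[[segments]]
index = 7
name = "L-arm"
a_n = 0.063
a_cl = 0.0669
height = 0.4735
clothed = true
c_whK = [0.413194, 1.076667, 0.118056, 0.086889]
q_basal = [0.410027, 0.358773, 0.030752, 0.051829]
bf_basal = [0.369024, 0.322896, 0.027677, 0.235955]
d_cond = [0.504, 0.378, 0.441]
t_set = [35.5, 34.8, 34.7, 34.6]
t_init_clothing = [32.5, 30.5]

[[segments]]
index = 8
name = "R-arm"
a_n = 0.063
a_cl = 0.0669
height = 0.4735
clothed = true
c_whK = [0.413194, 1.076667, 0.118056, 0.086889]
q_basal = [0.410027, 0.358773, 0.030752, 0.051829]
bf_basal = [0.369024, 0.322896, 0.027677, 0.235955]
d_cond = [0.504, 0.378, 0.441]
t_set = [35.5, 34.8, 34.7, 34.6]
t_init_clothing = [32.5, 30.5]

[[segments]]
index = 9
name = "L-hand"
a_n = 0.05
a_cl = 0.05
height = 0.195
clothed = false
c_whK = [0.145833, 0.211111, 0.052083, 0.076667]
q_basal = [0.205013, 0.051253, 0.010251, 0.041134]
bf_basal = [0.184512, 0.046128, 0.009226, 0.187266]
d_cond = [0.5, 0.4, 0.45]
t_set = [35.4, 35.3, 35.3, 35.2]
t_init_clothing = [35.2, 35.2]

[[segments]]
index = 10
name = "R-hand"
a_n = 0.05
a_cl = 0.05
height = 0.195
clothed = false
c_whK = [0.145833, 0.211111, 0.052083, 0.076667]
q_basal = [0.205013, 0.051253, 0.010251, 0.041134]
bf_basal = [0.184512, 0.046128, 0.009226, 0.187266]
d_cond = [0.5, 0.4, 0.45]
t_set = [35.4, 35.3, 35.3, 35.2]
t_init_clothing = [35.2, 35.2]

[[segments]]
index = 11
name = "L-thigh"
a_n = 0.209
a_cl = 0.222
height = 0.449
clothed = true
c_whK = [2.065972, 5.383333, 0.590278, 0.434444]
q_basal = [1.332587, 1.025067, 0.030752, 0.171941]
bf_basal = [1.199328, 0.92256, 0.027677, 0.782772]
d_cond = [1.672, 1.254, 1.463]
t_set = [35.8, 35.2, 34.4, 33.8]
t_init_clothing = [31.8, 29.0]

[[segments]]
index = 12
name = "R-thigh"
a_n = 0.209
a_cl = 0.222
height = 0.449
clothed = true
c_whK = [2.065972, 5.383333, 0.590278, 0.434444]
q_basal = [1.332587, 1.025067, 0.030752, 0.171941]
bf_basal = [1.199328, 0.92256, 0.027677, 0.782772]
d_cond = [1.672, 1.254, 1.463]
t_set = [35.8, 35.2, 34.4, 33.8]
t_init_clothing = [31.8, 29.0]

[[segments]]
index = 13
name = "L-leg"
a_n = 0.112
a_cl = 0.1189
height = 0.428
clothed = true
c_whK = [0.996528, 2.596667, 0.284722, 0.209556]
q_basal = [0.717547, 0.512533, 0.030752, 0.092141]
bf_basal = [0.645792, 0.46128, 0.027677, 0.419476]
d_cond = [0.896, 0.672, 0.784]
t_set = [35.6, 34.4, 33.9, 33.4]
t_init_clothing = [31.6, 29.3]

[[segments]]
index = 14
name = "R-leg"
a_n = 0.112
a_cl = 0.1189
height = 0.428
clothed = true
c_whK = [0.996528, 2.596667, 0.284722, 0.209556]
q_basal = [0.717547, 0.512533, 0.030752, 0.092141]
bf_basal = [0.645792, 0.46128, 0.027677, 0.419476]
d_cond = [0.896, 0.672, 0.784]
t_set = [35.6, 34.4, 33.9, 33.4]
t_init_clothing = [31.6, 29.3]

[[segments]]
index = 15
name = "L-foot"
a_n = 0.056
a_cl = 0.056
height = 0.2565
clothed = false
c_whK = [0.320833, 0.464444, 0.114583, 0.168667]
q_basal = [0.256267, 0.051253, 0.010251, 0.04607]
bf_basal = [0.23064, 0.046128, 0.009226, 0.209738]
d_cond = [0.56, 0.448, 0.504]
t_set = [35.1, 34.9, 34.4, 33.9]
t_init_clothing = [33.9, 33.9]

[[segments]]
index = 16
name = "R-foot"
a_n = 0.056
a_cl = 0.056
height = 0.2565
clothed = false
c_whK = [0.320833, 0.464444, 0.114583, 0.168667]
q_basal = [0.256267, 0.051253, 0.010251, 0.04607]
bf_basal = [0.23064, 0.046128, 0.009226, 0.209738]
d_cond = [0.56, 0.448, 0.504]
t_set = [35.1, 34.9, 34.4, 33.9]
t_init_clothing = [33.9, 33.9]

[control]
passive_only = false
sweat_gain_core = 190.0        # W/K of head-core warm error
sweat_gain_skin = 20.0         # W/K of integrated warm-skin signal
dilation_gain_core = 75.0      # W/K skin-blood conductance per K warm core error
dilation_gain_skin = 5.0
constriction_gain_core = 0.5   # 1/K
constriction_gain_skin = 0.05
shiver_gain = 20.0             # W per K(core) x K(skin) of cold error product
shiver_max = 350.0
q10_coefficient = 10.0         # local sweat multiplier 2^(err_skin/q10)
bf_skin_min = 0.05             # W/K floor on skin-blood conductance
work_bf_coupling = 1.0         # extra muscle-blood W/K per W of work/shivering
skin_weights = [0.074906367, 0.093632959, 0.086142322, 0.118245051, 0.051364366, 0.051364366, 0.033707865, 0.033707865, 0.026752274, 0.026752274, 0.111824505, 0.111824505, 0.059925094, 0.059925094, 0.029962547, 0.029962546000000034]
sweat_distribution = [0.074906367, 0.093632959, 0.086142322, 0.118245051, 0.051364366, 0.051364366, 0.033707865, 0.033707865, 0.026752274, 0.026752274, 0.111824505, 0.111824505, 0.059925094, 0.059925094, 0.029962547, 0.029962546000000034]
dilation_distribution = [0.074906367, 0.093632959, 0.086142322, 0.118245051, 0.051364366, 0.051364366, 0.033707865, 0.033707865, 0.026752274, 0.026752274, 0.111824505, 0.111824505, 0.059925094, 0.059925094, 0.029962547, 0.029962546000000034]
work_distribution = [0.0, 0.1, 0.1, 0.2, 0.025, 0.025, 0.015, 0.015, 0.005, 0.005, 0.15, 0.15, 0.1, 0.1, 0.005, 0.005]
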