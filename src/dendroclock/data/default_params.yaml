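k1: 0.05
k2: 1.7
alpha_store: 0.15
beta: 45.0
gamma: 2.25
h: 0.45
n: 4.0
B_Ca: 0.05
pka_gain: 10.0
x_init_on_CS: 25.0
ca_window: 2.0
gi_a: 1.0
gi_b: 1.9
gi_rise_window: 1.2
gi_off_time: 2.0
r1_bl: 1.0e-05
r_cag: 13.0
K_ca_AC: 0.9
K_Gi: 0.2
r2_bl: 0.6
r_ca: 0.05
k8: 300.0
k10: 400.0
km: 20.0
ka7: 0.0125
k7: 0.0002
k13: 0.005
k14: 0.2
km2: 2.0
k15: 0.05
r5: 0.001
r6: 0.3
z_threshold: 0.1
r3_bl: 0.19
K_ca_RGS: 0.2
r4: 0.5
K_g: 0.5
gs_amplitude: 5.0
gs_window: 0.2
AC_total: 0.1
PKA_total: 1.0
PDE_total: 5.1
init_ACi: 0.1
init_cAMP: 1.9
init_PKAi: 1.0
init_PDE: 0.1
_meta:
  status: re-calibrated, non-authoritative
  note: Derived with dendroclock.calibration against the qualitative and printed quantitative
    behaviours of the cascade; not transcribed from any published table.
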