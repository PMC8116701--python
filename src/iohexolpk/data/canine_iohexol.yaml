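# Final population PK estimates for iohexol plasma clearance in dogs.
# Clearances L/min/kg, volumes L/kg, beta_creat dl/mg, creat_center mg/dl;
# omegas are SDs of the log-scale random effects; sigma_prop is the
# proportional residual-error coefficient.
theta_cl: 0.00212
theta_v1: 0.163
theta_v2: 0.058
theta_q: 0.0034
beta_ckd: -0.379
beta_creat: -0.421
creat_center: 1.47
omega_cl: 0.208
omega_v1: 0.248
omega_v2: 0.199
sigma_prop: 0.0617
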