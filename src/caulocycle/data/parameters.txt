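# Best-fit kinetic parameter set for the Caulobacter crescentus cell-cycle model.
# Flat key = value format; units are min^-1 for rate constants, dimensionless (a.u.)
# for binding constants (J), scaling constants (Theta) and pool sizes.

# --- DNA replication and methylation ---
ks_Ini       = 3.104e-4
kelong       = 6.53e-3
Pelong       = 0.05
km_Cori      = 1.5637
km_ccrM      = 2.2763
km_ctrA      = 1.4645
Ja_Ini       = 1.0
Ji_Ini       = 1.4565
Jm_Cori      = 0.95
Jm_ccrM      = 0.95
Jm_ctrA      = 0.95
Theta_CtrA   = 6.0
Theta_DnaA   = 0.5
Theta_Cori   = 0.308

# --- mRNA transcription / decay ---
ks_IccrM     = 0.1105
kd_IccrM     = 0.0696
ks_ccrM      = 0.2557
kd_ccrM      = 0.1005
ks_dnaA      = 0.199
kd_dnaA      = 0.0693
ks_gcrA      = 5.4235
kd_gcrA      = 0.7342
ks1_ctrA     = 1.0035
ks2_ctrA     = 0.0937
kd_ctrA      = 0.0983
ks_sciP      = 0.583
kd_sciP      = 0.0523
Ja_ccrM_CtrA = 5.0
Ji_ccrM_SciP = 6.0
Ji_dnaA_GcrA = 3.0
Ja_gcrA_DnaA = 1.25
Ji_gcrA_CtrA = 5.0
Ja_ctrA_CtrA = 5.0
Ja_ctrA_GcrA = 3.0
Ji_ctrA_CtrA = 8.0
Ji_ctrA_SciP = 8.0
Ja_sciP_CtrA = 5.0

# --- master regulator proteins ---
ks_DnaA      = 0.0787
kd_DnaA      = 0.07
ks_GcrA      = 0.032
kd_GcrA      = 0.022
ks_CcrM      = 0.0834
kd_CcrM      = 0.07
ks_SciP      = 0.1294
kd_SciP      = 0.0673
ks_CtrA      = 0.0404
kd_CtrA      = 0.002
kd_CtrA_ClpXP   = 0.053
kphos_CtrA   = 4.2919
kdephos_CtrA = 0.113
kphos_CckA   = 1.027
kdephos_CckA = 0.9242
Jd_CtrA_ClpXP   = 4.0

# --- protease complexes, c-di-GMP and phosphotransfer ---
k1_plus      = 0.6072
k1_minus     = 3.3013
k2_plus      = 1.4375
k2_minus     = 0.8164
k3_plus      = 170.4913
k3_minus     = 2.3133
kphos_PleD   = 0.046
kdephos_PleD = 0.0414
ks_CpdR      = 1.2227
kd_CpdR      = 1.6152
kphos_CpdR   = 1.1239
kdephos_CpdR = 1.3854
ks_RcdA      = 0.1642
kd_RcdA      = 0.2323
ks_cdG       = 0.0099
kd_cdG       = 0.9893
ks_PleD      = 0.0956
kd_PleD      = 0.1314
ks_PdeA      = 0.012
kd_PdeA      = 0.5161
Ja_CpdR_CtrA = 15.0
Jd_CpdR      = 6.0
Ja_RcdA_CtrA = 15.0
Jd_RcdA      = 2.0
Ja_PdeA_CtrA = 5.0
Jd_PdeA      = 5.0
Ja_PleD_CtrA = 2.5
Ji_cdG_cdG   = 0.2
CckA_T       = 0.3
ClpXP        = 1.0
alpha_PdeA   = 7.0
alpha_PleD   = 1500.0
alpha_cdG    = 10.0

# --- PleC forcing function (fitted to cell-cycle western blots; radians) ---
plec_A1      = 80.09
plec_omega   = 0.013
plec_phi1    = 1.74
plec_A2      = 78.77
plec_phi2    = 4.85

# --- discrete-event machinery ---
ks_Zring_on          = 0.011
elong_at_initiation  = 0.1
elong_ccrM_locus     = 0.2
elong_ctrA_locus     = 0.375
elong_termination    = 1.0
zring_division       = 1.0
target_period        = 150.0
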