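# Optimization search box: 47 free parameters with lower/upper bounds and starting point.
# columns: name lower upper start
km_Cori       0.35      5.6      1.4
km_ccrM       0.35      5.6      1.4
km_ctrA       0.35      5.6      1.4
ks_IccrM      0.025     0.4      0.1
kd_IccrM      0.016675  0.2668   0.0667
ks_ccrM       0.064     1.024    0.256
kd_ccrM       0.02      0.32     0.08
ks_dnaA       0.0605    0.968    0.242
kd_dnaA       0.015     0.24     0.06
ks_gcrA       1.4       22.4     5.6
kd_gcrA       0.15      2.4      0.6
ks_sciP       0.125     2.0      0.5
kd_sciP       0.01      0.16     0.04
ks1_ctrA      0.2475    3.96     0.99
ks2_ctrA      0.0225    0.36     0.09
kd_ctrA       0.02075   0.332    0.083
ks_DnaA       0.01625   0.26     0.065
ks_GcrA       0.007     0.112    0.028
ks_CcrM       0.02125   0.34     0.085
ks_SciP       0.0295    0.472    0.1183
kd_SciP       0.015     0.24     0.06
ks_CtrA       0.0108    0.1728   0.0432
kd_CtrA_ClpXP 0.015     0.24     0.06
k1_plus       0.15      2.4      0.6
k1_minus      0.75      12.0     3.0
ks_CpdR       0.175     2.8      0.7
kd_CpdR       0.375     6.0      1.5
kdephos_CpdR  0.25      4.0      1.0
kphos_CpdR    0.25      4.0      1.0
k2_plus       0.275     4.4      1.1
k2_minus      0.25      4.0      1.0
ks_RcdA       0.0375    0.6      0.15
kd_RcdA       0.05      0.8      0.2
k3_plus       35.0      560.0    140.0
k3_minus      0.5       8.0      2.0
ks_cdG        0.0025    0.04     0.01
kd_cdG        0.25      4.0      1.0
ks_PleD       0.025     0.4      0.1
kd_PleD       0.0375    0.6      0.15
kphos_PleD    0.01      0.16     0.04
kdephos_PleD  0.01      0.16     0.04
ks_PdeA       0.0025    0.04     0.01
kd_PdeA       0.125     2.0      0.5
kphos_CtrA    1.25      20.0     5.0
kdephos_CckA  0.25      4.0      1.0
kdephos_CtrA  0.025     0.4      0.1
kphos_CckA    0.25      4.0      1.0
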