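# Initial values of model variables: a newborn swarmer cell at t = 0 min.
# IccrM (transcriptional delay intermediate) has no published initial value; it is
# started at 0 and washes out during the discarded transient.

# DNA variables
Ini     = 0.0383
Elong   = 0.0
Zring   = 0.0
hCori   = 0.0
hccrM   = 0.0
hctrA   = 0.0

# mRNA variables
IccrM   = 0.0
ccrM    = 0.173
dnaA    = 3.154
gcrA    = 4.525
sciP    = 6.335
ctrA    = 0.658

# master regulator proteins
CcrM    = 0.435
DnaA    = 2.638
GcrA    = 3.841
SciP    = 12.485
CtrA    = 1.973
CtrAP   = 3.960

# protease complex variables
CckAP    = 0.042
Complex1 = 0.211
CpdR     = 1.045
CpdRP    = 0.042
Complex2 = 0.187
RcdA     = 0.789
Complex3 = 3.407
PleD     = 0.526
PleDP    = 0.663
PdeA     = 0.228
cdG      = 0.511

# discrete bookkeeping
DNA     = 1.0
Count   = 1
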