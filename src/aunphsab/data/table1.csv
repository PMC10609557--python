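ligand,mu_eV,eta_eV
octanethiol,-1.92,5.42
butanethiol,-1.91,5.43
12-mercaptododecanoic acid methylester,-2.20,4.86
ethanethiol,-1.91,5.47
methanethiol,-1.96,5.42
citrate(COO−)3,-1.56,6.95
thioethanegenistein,-3.32,2.83
thioabiraterone,-3.10,3.57
thiogenistein,-3.41,3.03
acetate,-2.32,6.79
citrate(COO−)2 (-H-),-2.66,6.00
citrate(COO−)2 (--H),-2.55,6.55
citrate(COO−)1 (-HH),-3.19,6.03
citrate(COO−)1 (H–H),-3.25,6.50
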