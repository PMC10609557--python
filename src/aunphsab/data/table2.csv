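ligand,dE_inf_kcal,dE_r_kcal,r_ref_A
octanethiol,-31.6,-37.1,2.88
butanethiol,-31.5,-37.2,2.88
ethanethiol,-31.4,-37.1,2.88
methanethiol,-30.9,-36.6,2.88
12-mercaptododecanoic acid methylester,-30.2,-35.3,2.88
citrate(COO−)3,-29.4,-36.8,2.88
thioethanegenistein,-24.4,-26.9,2.88
thioabiraterone,-23.0,-27.6,2.88
thiogenistein,-21.2,-25.1,2.88
acetate,-20.2,-28.8,2.88
citrate(COO−)2 (-H-),-18.5,-27.0,2.88
citrate(COO−)2 (--H),-18.3,-27.1,2.88
citrate(COO−)1 (-HH),-12.8,-22.1,2.88
citrate(COO−)1 (H–H),-11.3,-21.1,2.88
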