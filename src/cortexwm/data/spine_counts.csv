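# Spine counts of layer 2/3 pyramidal basal dendrites per area (young macaque),
# with multiplicative age-correction factors for data from older animals.
# Areas listed in anatomical-hierarchy order; missing entries are blank.
area,spine_count,age_factor
V1,643,1
V2,1201,1
V4,2429,1
DP,,
MT,2077,1
8m,3200,1.30
5,4689,1
8l,3200,1.30
2,,
TEO,4812,1
F1,,
STPc,8337,1
7A,2572,1
46d,6600,1.15
10,6488,1.15
9/46v,7800,1.15
9/46d,7800,1.15
F5,,
TEpd,7260,1
PBr,,
7m,2294,1.30
LIP,2316,1
F2,,
7B,6841,1
ProM,,
STPi,8337,1
F7,,
8B,,
STPr,8337,1
24c,6825,1.15
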