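# Segment mass as a fraction of total body mass (one value per single segment;
# paired segments such as thigh apply the fraction to each side).
# Source: Dempster cadaver proportions as tabulated by Winter,
# "Biomechanics and Motor Control of Human Movement", 4th ed., Table 4.1.
segment,fraction
head_neck,0.081
trunk,0.497
upper_arm,0.028
forearm,0.016
hand,0.006
thigh,0.100
shank,0.0465
foot,0.0145
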