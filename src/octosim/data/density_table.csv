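# octosim density table v1
# Measured synaptic puncta densities on octopus cells (puncta per 100 um^2
# of membrane), tabulated separately for soma and dendrites.
# SGN_Ia = SGN_total - SGN_Ibc per compartment (subtraction recipe).
population,compartment,density
SGN_total,soma,13.3
SGN_total,dendrite,10.7
SGN_Ia,soma,8.4
SGN_Ia,dendrite,6.6
SGN_Ibc,soma,4.9
SGN_Ibc,dendrite,4.1
glycinergic,soma,1.8
glycinergic,dendrite,4.2
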