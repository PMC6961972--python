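tract,mean_fa,da_frac_fa
anterior_thalamic_radiation,0.36,0.012
cingulum_cingulate,0.45,-0.018
arcuate_fasciculus,0.42,0.020
uncinate_fasciculus,0.38,-0.010
inferior_longitudinal_fasciculus,0.40,0.008
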