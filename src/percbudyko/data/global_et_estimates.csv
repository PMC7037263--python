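label,et_over_p,cohort
global_reanalysis_a,0.639,post-1995
global_reanalysis_b,0.634,post-1995
global_mapping,0.62,post-1995
terrestrial_a,0.59,post-1995
terrestrial_b,0.61,post-1995
terrestrial_c,0.61,post-1995
terrestrial_d,0.61,post-1995
terrestrial_e,0.67,post-1995
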