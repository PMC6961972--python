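test,domain,mean,sd,higher_is_better,domain_loading
matrix_reasoning,visuospatial,13.52,4.93,1,0.72
block_design,visuospatial,34.38,10.01,1,0.78
spatial_span,visuospatial,14.79,2.72,1,0.62
nart,crystallised,34.66,8.10,1,0.82
wtar,crystallised,41.27,6.94,1,0.80
verbal_fluency,crystallised,43.55,12.78,1,0.58
verbal_paired_associates,verbal_memory,27.57,9.48,1,0.70
logical_memory,verbal_memory,75.03,17.84,1,0.68
digit_span_backwards,verbal_memory,7.88,2.31,1,0.55
symbol_search,processing_speed,24.88,6.05,1,0.76
digit_symbol,processing_speed,56.68,11.79,1,0.80
inspection_time,processing_speed,111.78,10.95,1,0.56
four_choice_rt,processing_speed,0.64,0.08,-1,0.66
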