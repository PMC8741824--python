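field,light_conditions,background,weed_density_per_m2,transect_length_m,fov_width_m
HEN1,day,canola stubble on red-orange soil,3.1,50,1.0
HEN2,day,heavy wheat stubble on red soil,9.3,50,1.0
WAG1,day,lupin stubble on red-orange soil,18.7,50,1.0
WAG2,day,grazed barley stubble,3.3,50,1.0
COB1,day,dark brown soil freshly tilled,9.8,50,1.0
NIGHT1,night,canola stubble,9.6,50,1.0
NIGHT2,night,dark brown soil freshly tilled,7.8,50,1.0
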