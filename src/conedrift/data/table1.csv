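participant,density_cones_deg2,nyquist_arcsec,velocity_arcmin_s,velocity_cones_s,drift_length_600ms_arcmin,drift_variance_arcmin2,seeing_area_deg2,seeing_count,isoa_cdc_offset_arcmin
P1,11749,30.9,17.5,31.2,10.2,1925,0.18,1793,7.2
P2,13883,28.4,11.9,23.9,6.9,321,0.11,1422,1.2
P3,15005,27.4,12.5,27.6,7.6,129,0.08,1140,0.94
P4,15466,26.9,16.1,36.2,10,98,0.13,1677,4
P5,16016,26.5,10,22.1,5.9,26,0.07,1043,2
P6,17000,25.7,10.4,23.9,6.3,40,0.1,1476,0.86
P7,17971,25,14,31.1,8.2,280,0.19,2690,4.8
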