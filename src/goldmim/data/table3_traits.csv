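species_id,biting_frequency,sprays_chemicals,n_spines,total_spine_length_mm,cuticle_thickness_mm,body_size_mm,mandible_size_mm,gland_area_mm2
P. ammon,0.1,1,4,3.54,0.04,9.04,1.00,2.84
P. vermiculosa,0,1,6,2.96,0.03,5.98,0.71,1.62
C. aeneopilosus,0.3,1,0,0,0.02,8.04,0.84,2.43
D. nigricans,0,0,0,0,0.02,7.40,0,0.57
M. luctuosa,0,0,0,0,0.02,7.04,0,0
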