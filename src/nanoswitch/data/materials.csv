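material,eps_inf,center_cm1,strength,damping_cm1
air,1.0,,,
si,11.7,,,
sin_membrane,4.1,950,2.5,80
d2o,1.7,1550,0.4,600
lipid_trans,2.1,1466,0.010,15
lipid_trans,2.1,1496,0.012,15
lipid_trans,2.1,1603,0.020,12
lipid_trans,2.1,1740,0.030,15
lipid_cis,2.1,1466,0.005,15
lipid_cis,2.1,1496,0.006,15
lipid_cis,2.1,1603,0.008,12
lipid_cis,2.1,1740,0.030,15
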