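name,r0,lnc_top,vcmax25_top,r1,r2,kn_a,kn_b_default,sla,leaf_lifespan,h1,h2,c1,c2,l1,l2,s1,s2,background_mort_rate,cstarv_mort_max,storage_target_fraction,recruitment_rate,ci_over_ca,quantum_yield,stem_maint_rate
broadleaf_evergreen_tropical,1.62,1.8,41,0.2061,-0.0402,0.00963,2.43,15,1.5,2,0.6,0.2,1.3,0.08,1.3,0.07,2.5,0.014,0.2,1,100,0.7,0.08,1e-06
light_demander,2.2,1.9,50,0.2061,-0.0402,0.00963,2.43,30,1,2,0.6,0.2,1.3,0.04,1.3,0.05,2.5,0.02,0.2,0.6,100,0.7,0.08,1e-06
shade_tolerant,1.2,1.8,35,0.2061,-0.0402,0.00963,2.43,14,2.5,2,0.6,0.2,1.3,0.08,1.3,0.09,2.5,0.008,0.2,1.2,100,0.7,0.08,1e-06
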