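# Nominal material properties for the dose engine.
# density in g/cm^3; z_over_a is the mean ratio of atomic number to mass number
# (electrons per atomic mass unit), used for Klein-Nishina electron densities.
name,density,z_over_a
air,0.0012,0.4992
water,1.000,0.5551
soft_tissue,1.060,0.5500
lung,0.260,0.5500
pmma,1.190,0.5394
bone_cortical,1.920,0.5148
aluminum,2.699,0.4818
tungsten,19.30,0.4025
lead,11.35,0.3958
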