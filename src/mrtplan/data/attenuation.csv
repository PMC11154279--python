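# Mass attenuation (mu_over_rho) and mass energy-absorption (mu_en_over_rho)
# coefficients in cm^2/g, transcribed from standard photon cross-section
# compilations and rounded to four significant figures.  High-Z absorbers
# (tungsten, lead) carry extra grid points bracketing their K edges
# (69.5 keV and 88.0 keV) so that log-log interpolation preserves the jump.
# mu_en values for tungsten and lead are nominal (these materials are used as
# absorbers, never as dose-scoring media).
material,energy_kev,mu_over_rho,mu_en_over_rho
air,10,5.120,4.742
air,15,1.614,1.334
air,20,0.7779,0.5389
air,30,0.3538,0.1537
air,40,0.2485,0.0683
air,50,0.2080,0.0410
air,60,0.1875,0.0304
air,80,0.1662,0.0241
air,100,0.1541,0.0234
air,150,0.1356,0.0250
air,200,0.1233,0.0268
air,300,0.1067,0.0288
water,10,5.329,4.944
water,15,1.673,1.374
water,20,0.8096,0.5503
water,30,0.3756,0.1557
water,40,0.2683,0.0695
water,50,0.2269,0.0422
water,60,0.2059,0.0319
water,80,0.1837,0.0262
water,100,0.1707,0.0256
water,150,0.1505,0.0277
water,200,0.1370,0.0297
water,300,0.1186,0.0319
soft_tissue,10,5.356,4.964
soft_tissue,15,1.693,1.396
soft_tissue,20,0.8205,0.5614
soft_tissue,30,0.3783,0.1591
soft_tissue,40,0.2698,0.0710
soft_tissue,50,0.2276,0.0430
soft_tissue,60,0.2065,0.0325
soft_tissue,80,0.1842,0.0265
soft_tissue,100,0.1711,0.0259
soft_tissue,150,0.1509,0.0279
soft_tissue,200,0.1374,0.0299
soft_tissue,300,0.1189,0.0320
lung,10,5.356,4.964
lung,15,1.693,1.396
lung,20,0.8205,0.5614
lung,30,0.3783,0.1591
lung,40,0.2698,0.0710
lung,50,0.2276,0.0430
lung,60,0.2065,0.0325
lung,80,0.1842,0.0265
lung,100,0.1711,0.0259
lung,150,0.1509,0.0279
lung,200,0.1374,0.0299
lung,300,0.1189,0.0320
pmma,10,3.357,3.026
pmma,15,1.101,0.8324
pmma,20,0.5714,0.3328
pmma,30,0.3032,0.0963
pmma,40,0.2350,0.0458
pmma,50,0.2074,0.0317
pmma,60,0.1924,0.0264
pmma,80,0.1751,0.0239
pmma,100,0.1641,0.0241
pmma,150,0.1456,0.0265
pmma,200,0.1328,0.0285
pmma,300,0.1152,0.0306
bone_cortical,10,28.51,26.80
bone_cortical,15,9.032,8.388
bone_cortical,20,4.001,3.601
bone_cortical,30,1.331,1.070
bone_cortical,40,0.6655,0.4507
bone_cortical,50,0.4242,0.2336
bone_cortical,60,0.3148,0.1400
bone_cortical,80,0.2229,0.0695
bone_cortical,100,0.1855,0.0459
bone_cortical,150,0.1480,0.0313
bone_cortical,200,0.1309,0.0293
bone_cortical,300,0.1113,0.0297
aluminum,10,26.23,25.43
aluminum,15,7.955,7.487
aluminum,20,3.441,3.094
aluminum,30,1.128,0.8778
aluminum,40,0.5685,0.3601
aluminum,50,0.3681,0.1840
aluminum,60,0.2778,0.1099
aluminum,80,0.2018,0.0551
aluminum,100,0.1704,0.0379
aluminum,150,0.1378,0.0283
aluminum,200,0.1223,0.0275
aluminum,300,0.1042,0.0283
tungsten,10,96.91,87.20
tungsten,15,83.50,73.50
tungsten,20,64.60,55.50
tungsten,30,22.68,18.80
tungsten,40,10.74,8.590
tungsten,50,6.010,4.630
tungsten,60,3.713,2.750
tungsten,69,2.552,1.850
tungsten,70,11.00,6.600
tungsten,80,7.810,4.690
tungsten,100,4.438,2.670
tungsten,150,1.581,0.9500
tungsten,200,0.7080,0.4250
tungsten,300,0.3020,0.1810
lead,10,130.6,111.0
lead,15,111.6,91.00
lead,20,86.36,68.90
lead,30,30.32,25.40
lead,40,14.36,12.10
lead,50,8.041,6.740
lead,60,5.021,4.150
lead,80,2.419,1.920
lead,87,1.910,1.490
lead,89,7.390,4.430
lead,100,5.549,3.330
lead,150,2.014,1.210
lead,200,0.9990,0.5990
lead,300,0.4031,0.2420
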