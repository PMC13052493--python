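# Decadic molar extinction of oxy-/deoxyhemoglobin (cm^-1 M^-1) and water
# absorption (mm^-1), 650-1000 nm. Compact digest of the widely used
# hemoglobin compendium (Gratzer/Kollias lineage) and near-infrared water
# absorption compilations; the 690 and 830 nm rows carry the compendium
# values to the digits given, intermediate rows are a smooth 10-nm digest
# intended for interpolation.
wavelength_nm,eps_hbo2_cm1_M1,eps_hb_cm1_M1,mua_water_mm1
650,368.0,3750.12,0.00032
660,319.6,3226.56,0.00036
670,294.0,2795.12,0.00042
680,277.6,2407.92,0.00045
690,276.0,2051.96,0.000474
700,290.0,1794.28,0.00060
710,314.0,1540.48,0.00072
720,348.0,1325.88,0.00104
730,390.0,1102.20,0.00180
740,446.0,1204.00,0.00266
750,518.0,1405.24,0.00283
760,586.0,1548.52,0.00270
770,650.0,1311.88,0.00240
780,710.0,1075.44,0.00221
790,774.0,898.00,0.00220
800,816.0,761.72,0.00224
810,864.0,717.08,0.00256
820,916.0,693.76,0.00280
830,974.0,693.04,0.00312
840,1022.0,692.36,0.00356
850,1058.0,691.32,0.00406
860,1092.0,696.00,0.00445
870,1128.0,705.00,0.00499
880,1154.0,726.44,0.00551
890,1178.0,743.00,0.00605
900,1198.0,761.84,0.00679
910,1220.0,780.00,0.00925
920,1238.0,797.28,0.01120
930,1254.0,812.00,0.01610
940,1268.0,825.00,0.02644
950,1280.0,835.00,0.03860
960,1290.0,843.00,0.04200
970,1296.0,850.00,0.04500
980,1300.0,856.00,0.04330
990,1302.0,861.00,0.04000
1000,1302.0,866.00,0.03640
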