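# Molar extinction coefficients, cm^-1 / (mol/L), NIR window 660-900 nm.
# Compiled (approximate) from standard literature tabulations: Hb / HbO2 from the
# widely used whole-blood hemoglobin compilations (per heme); ICG bound to plasma
# proteins (absorption peak near 800-805 nm). Values are external constants used
# in relative units after normalization; they are not fitted by this package.
# Hb and HbO2 cross near the 796 nm isosbestic point.
wavelength_nm,eps_Hb,eps_HbO2,eps_ICG
660,3226.6,319.6,40000
670,2795.1,294.0,48000
680,2407.9,277.6,58000
690,2052.0,276.0,70000
700,1794.3,290.0,83000
710,1540.5,314.0,96000
720,1325.9,348.0,110000
730,1102.2,390.0,126000
740,1115.9,446.0,144000
750,1405.2,518.0,160000
756,1549.0,562.7,170000
760,1548.5,586.0,176000
770,1311.9,650.0,188000
780,1075.4,710.0,196000
790,850.0,774.0,200000
796,805.0,800.0,201000
800,761.7,816.0,200000
810,717.1,864.0,192000
820,693.0,916.0,172000
830,693.8,974.0,142000
840,692.4,1022.0,110000
850,691.3,1058.0,80000
860,686.0,1086.0,56000
866,680.0,1100.0,44000
870,680.5,1114.0,38000
880,674.0,1128.0,26000
890,659.4,1140.0,18000
900,641.3,1150.0,12000
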