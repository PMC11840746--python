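wavelength_nm,eps_Hb,eps_HbO2
680,2190.0,298.0
690,1985.0,276.0
700,1794.0,290.0
710,1540.0,314.0
720,1327.0,348.0
730,1168.0,390.0
740,1124.0,446.0
750,1405.0,518.0
760,1549.0,586.0
770,1312.0,650.0
780,1075.0,710.0
790,891.0,774.0
800,762.0,816.0
810,717.0,864.0
820,694.0,916.0
830,693.0,974.0
840,692.0,1022.0
850,691.0,1058.0
860,694.0,1092.0
870,697.0,1128.0
880,726.0,1154.0
890,744.0,1178.0
900,762.0,1198.0
910,809.0,1220.0
920,858.0,1236.0
930,906.0,1228.0
940,971.0,1214.0
950,1023.0,1196.0
960,1070.0,1176.0
970,1116.0,1158.0
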