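wavelength_nm,HbO2,Hb,ICG
700,290.0,1794.28,45000.0
730,390.0,1102.20,85000.0
760,586.0,1548.52,130000.0
800,816.0,761.72,180000.0
850,1058.0,691.32,35000.0
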