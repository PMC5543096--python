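wavelength_nm,chromophore,epsilon,pathlength
470,HbO2,33209.2,1.0
470,HbR,16156.4,1.0
530,HbO2,39036.4,1.0
530,HbR,39036.4,1.0
588,HbO2,26629.2,1.0
588,HbR,31589.6,1.0
627,HbO2,664.0,1.0
627,HbR,5427.2,1.0
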