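place,cells_per_mm3
Resting_Teff_out,1689
Resting_Treg_out,63
NK_out,30
IL17_out,8
IL10_out,13
IFNg_out,42
IL17_in,1
IL10_in,1
IFNg_in,1
ODC:Lmax,500
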