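# molecule: 1M5NI
# table: anion branching ratios (DEA), anchored at the measured 3.1 and 4.7 eV
# note: NO2-/CN-/CNO- at 4.7 eV and NO2- at 3.1 eV are the printed values; all
# note: other entries are synthetic fills consistent with the stated ranges
# note: (minor-channel combined yield 23-30%, CN-/CNO- rising with energy);
# note: minor species share the residual probability equally.
energy_eV,species,mass_u,probability
3.1,NO2-,46,0.58
3.1,CN-,26,0.10
3.1,CNO-,42,0.05
3.1,C2N2Hx-,54,0.054
3.1,C3N2Hx-,66,0.054
3.1,C4N2Hx-,78,0.054
3.1,NO_loss-,97,0.054
3.1,OH_CH3_loss-,111,0.054
4.7,NO2-,46,0.35
4.7,CN-,26,0.21
4.7,CNO-,42,0.10
4.7,C2N2Hx-,54,0.068
4.7,C3N2Hx-,66,0.068
4.7,C4N2Hx-,78,0.068
4.7,NO_loss-,97,0.068
4.7,OH_CH3_loss-,111,0.068
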