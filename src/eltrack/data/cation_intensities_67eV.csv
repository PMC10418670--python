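# molecule: 1M5NI
# table: relative intensities of cations formed by 67 eV electron impact (parent = 1)
species,mass_u,relative_intensity
C4H5N3O2+,127,1
C4H2N3O2+,124,0.415
C4H4N2O2+,112,0.0564
C4HNO+,84,0.152
C2H5NO2+,75,0.0978
C2H3N3+,69,0.137
CH4NO+,62,0.0900
C2H4N2+,56,0.571
C3HN+,51,0.139
H2NO2+,48,0.124
CH3NO+,45,0.633
C2OH2+,42,0.230
C2N+,38,0.0720
H3NO+,33,0.201
CHO+,29,0.768
H2O+,18,0.0512
NH+,15,0.349
C+,12,0.0435
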