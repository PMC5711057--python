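# 6 MV flattening-filter-free (6X FFF) photon energy spectrum preset.
# Softer than the flattened 6X beam (no differential hardening by the
# flattening filter).  Editable approximation; vendor spectrum unpublished.
# columns: e_min_mev,e_max_mev,relative_fluence
0.05,0.25,0.060
0.25,0.50,0.160
0.50,0.75,0.170
0.75,1.00,0.140
1.00,1.25,0.110
1.25,1.50,0.090
1.50,1.75,0.070
1.75,2.00,0.055
2.00,2.25,0.042
2.25,2.50,0.032
2.50,2.75,0.024
2.75,3.00,0.018
3.00,3.25,0.013
3.25,3.50,0.010
3.50,3.75,0.0075
3.75,4.00,0.0055
4.00,4.25,0.0040
4.25,4.50,0.0028
4.50,4.75,0.0020
4.75,5.00,0.0013
5.00,5.25,0.0008
5.25,5.50,0.0005
5.50,6.00,0.0004
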