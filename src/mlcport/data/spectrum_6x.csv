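# 6 MV flattened (6X) photon energy spectrum preset.
# Approximate Varian-class 6 MV bremsstrahlung spectrum binned in 0.25 MeV
# bins; relative fluence per bin (normalized at load time).  The vendor
# spectrum is not published; this preset is an editable approximation.
# columns: e_min_mev,e_max_mev,relative_fluence
0.05,0.25,0.020
0.25,0.50,0.110
0.50,0.75,0.145
0.75,1.00,0.130
1.00,1.25,0.110
1.25,1.50,0.095
1.50,1.75,0.080
1.75,2.00,0.065
2.00,2.25,0.053
2.25,2.50,0.043
2.50,2.75,0.035
2.75,3.00,0.028
3.00,3.25,0.022
3.25,3.50,0.018
3.50,3.75,0.0145
3.75,4.00,0.0115
4.00,4.25,0.0090
4.25,4.50,0.0070
4.50,4.75,0.0055
4.75,5.00,0.0040
5.00,5.25,0.0030
5.25,5.50,0.0020
5.50,5.75,0.0012
5.75,6.00,0.0005
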