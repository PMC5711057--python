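# Synthesized hd120 lower-half thickness table (cm at the MLC plane).
# Vendor tables are proprietary; this table reproduces the published
# construction qualitatively (leaf widths, total thickness, interlocking
# tongue-and-groove halves, interleaf air gap). Columns:
# leaf_number  y_breakpoint_cm  thickness_cm
# A row opens a segment extending to the next row's breakpoint.
  1    -5.98600   3.4500
  1    -5.72925   0.0000
  2    -5.71425   3.4500
  2    -5.45750   0.0000
  3    -5.44250   3.4500
  3    -5.18575   0.0000
  4    -5.17075   3.4500
  4    -4.91400   0.0000
  5    -4.89900   3.4500
  5    -4.64225   0.0000
  6    -4.62725   3.4500
  6    -4.37050   0.0000
  7    -4.35550   3.4500
  7    -4.09875   0.0000
  8    -4.08375   3.4500
  8    -3.82700   0.0000
  9    -3.81200   3.4500
  9    -3.55525   0.0000
 10    -3.54025   3.4500
 10    -3.28350   0.0000
 11    -3.26850   3.4500
 11    -3.01175   0.0000
 12    -2.99675   3.4500
 12    -2.74000   0.0000
 13    -2.72500   3.4500
 13    -2.46825   0.0000
 14    -2.45325   3.4500
 14    -2.19650   0.0000
 15    -2.18150   3.4500
 15    -2.06062   0.0000
 16    -2.04563   3.4500
 16    -1.92475   0.0000
 17    -1.90975   3.4500
 17    -1.78887   0.0000
 18    -1.77387   3.4500
 18    -1.65300   0.0000
 19    -1.63800   3.4500
 19    -1.51712   0.0000
 20    -1.50212   3.4500
 20    -1.38125   0.0000
 21    -1.36625   3.4500
 21    -1.24537   0.0000
 22    -1.23037   3.4500
 22    -1.10950   0.0000
 23    -1.09450   3.4500
 23    -0.97362   0.0000
 24    -0.95863   3.4500
 24    -0.83775   0.0000
 25    -0.82275   3.4500
 25    -0.70187   0.0000
 26    -0.68688   3.4500
 26    -0.56600   0.0000
 27    -0.55100   3.4500
 27    -0.43013   0.0000
 28    -0.41513   3.4500
 28    -0.29425   0.0000
 29    -0.27925   3.4500
 29    -0.15837   0.0000
 30    -0.14337   3.4500
 30    -0.02250   0.0000
 31    -0.00750   3.4500
 31    +0.11338   0.0000
 32    +0.12837   3.4500
 32    +0.24925   0.0000
 33    +0.26425   3.4500
 33    +0.38512   0.0000
 34    +0.40013   3.4500
 34    +0.52100   0.0000
 35    +0.53600   3.4500
 35    +0.65687   0.0000
 36    +0.67187   3.4500
 36    +0.79275   0.0000
 37    +0.80775   3.4500
 37    +0.92863   0.0000
 38    +0.94362   3.4500
 38    +1.06450   0.0000
 39    +1.07950   3.4500
 39    +1.20037   0.0000
 40    +1.21538   3.4500
 40    +1.33625   0.0000
 41    +1.35125   3.4500
 41    +1.47212   0.0000
 42    +1.48713   3.4500
 42    +1.60800   0.0000
 43    +1.62300   3.4500
 43    +1.74388   0.0000
 44    +1.75888   3.4500
 44    +1.87975   0.0000
 45    +1.89475   3.4500
 45    +2.01562   0.0000
 46    +2.03062   3.4500
 46    +2.15150   0.0000
 47    +2.16650   3.4500
 47    +2.42325   0.0000
 48    +2.43825   3.4500
 48    +2.69500   0.0000
 49    +2.71000   3.4500
 49    +2.96675   0.0000
 50    +2.98175   3.4500
 50    +3.23850   0.0000
 51    +3.25350   3.4500
 51    +3.51025   0.0000
 52    +3.52525   3.4500
 52    +3.78200   0.0000
 53    +3.79700   3.4500
 53    +4.05375   0.0000
 54    +4.06875   3.4500
 54    +4.32550   0.0000
 55    +4.34050   3.4500
 55    +4.59725   0.0000
 56    +4.61225   3.4500
 56    +4.86900   0.0000
 57    +4.88400   3.4500
 57    +5.14075   0.0000
 58    +5.15575   3.4500
 58    +5.41250   0.0000
 59    +5.42750   3.4500
 59    +5.68425   0.0000
 60    +5.69925   3.4500
 60    +5.95600   0.0000
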