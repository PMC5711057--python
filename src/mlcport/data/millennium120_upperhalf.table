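# Synthesized millennium120 upper-half thickness table (cm at the MLC plane).
# Vendor tables are proprietary; this table reproduces the published
# construction qualitatively (leaf widths, total thickness, interlocking
# tongue-and-groove halves, interleaf air gap). Columns:
# leaf_number  y_breakpoint_cm  thickness_cm
# A row opens a segment extending to the next row's breakpoint.
  1   -10.83200   3.3500
  1   -10.29550   0.0000
  2   -10.28950   3.3500
  2    -9.75300   0.0000
  3    -9.74700   3.3500
  3    -9.21050   0.0000
  4    -9.20450   3.3500
  4    -8.66800   0.0000
  5    -8.66200   3.3500
  5    -8.12550   0.0000
  6    -8.11950   3.3500
  6    -7.58300   0.0000
  7    -7.57700   3.3500
  7    -7.04050   0.0000
  8    -7.03450   3.3500
  8    -6.49800   0.0000
  9    -6.49200   3.3500
  9    -5.95550   0.0000
 10    -5.94950   3.3500
 10    -5.41300   0.0000
 11    -5.40700   3.3500
 11    -5.14175   0.0000
 12    -5.13575   3.3500
 12    -4.87050   0.0000
 13    -4.86450   3.3500
 13    -4.59925   0.0000
 14    -4.59325   3.3500
 14    -4.32800   0.0000
 15    -4.32200   3.3500
 15    -4.05675   0.0000
 16    -4.05075   3.3500
 16    -3.78550   0.0000
 17    -3.77950   3.3500
 17    -3.51425   0.0000
 18    -3.50825   3.3500
 18    -3.24300   0.0000
 19    -3.23700   3.3500
 19    -2.97175   0.0000
 20    -2.96575   3.3500
 20    -2.70050   0.0000
 21    -2.69450   3.3500
 21    -2.42925   0.0000
 22    -2.42325   3.3500
 22    -2.15800   0.0000
 23    -2.15200   3.3500
 23    -1.88675   0.0000
 24    -1.88075   3.3500
 24    -1.61550   0.0000
 25    -1.60950   3.3500
 25    -1.34425   0.0000
 26    -1.33825   3.3500
 26    -1.07300   0.0000
 27    -1.06700   3.3500
 27    -0.80175   0.0000
 28    -0.79575   3.3500
 28    -0.53050   0.0000
 29    -0.52450   3.3500
 29    -0.25925   0.0000
 30    -0.25325   3.3500
 30    +0.01200   0.0000
 31    +0.01800   3.3500
 31    +0.28325   0.0000
 32    +0.28925   3.3500
 32    +0.55450   0.0000
 33    +0.56050   3.3500
 33    +0.82575   0.0000
 34    +0.83175   3.3500
 34    +1.09700   0.0000
 35    +1.10300   3.3500
 35    +1.36825   0.0000
 36    +1.37425   3.3500
 36    +1.63950   0.0000
 37    +1.64550   3.3500
 37    +1.91075   0.0000
 38    +1.91675   3.3500
 38    +2.18200   0.0000
 39    +2.18800   3.3500
 39    +2.45325   0.0000
 40    +2.45925   3.3500
 40    +2.72450   0.0000
 41    +2.73050   3.3500
 41    +2.99575   0.0000
 42    +3.00175   3.3500
 42    +3.26700   0.0000
 43    +3.27300   3.3500
 43    +3.53825   0.0000
 44    +3.54425   3.3500
 44    +3.80950   0.0000
 45    +3.81550   3.3500
 45    +4.08075   0.0000
 46    +4.08675   3.3500
 46    +4.35200   0.0000
 47    +4.35800   3.3500
 47    +4.62325   0.0000
 48    +4.62925   3.3500
 48    +4.89450   0.0000
 49    +4.90050   3.3500
 49    +5.16575   0.0000
 50    +5.17175   3.3500
 50    +5.43700   0.0000
 51    +5.44300   3.3500
 51    +5.97950   0.0000
 52    +5.98550   3.3500
 52    +6.52200   0.0000
 53    +6.52800   3.3500
 53    +7.06450   0.0000
 54    +7.07050   3.3500
 54    +7.60700   0.0000
 55    +7.61300   3.3500
 55    +8.14950   0.0000
 56    +8.15550   3.3500
 56    +8.69200   0.0000
 57    +8.69800   3.3500
 57    +9.23450   0.0000
 58    +9.24050   3.3500
 58    +9.77700   0.0000
 59    +9.78300   3.3500
 59   +10.31950   0.0000
 60   +10.32550   3.3500
 60   +10.86200   0.0000
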