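# Synthesized millennium120 lower-half thickness table (cm at the MLC plane).
# Vendor tables are proprietary; this table reproduces the published
# construction qualitatively (leaf widths, total thickness, interlocking
# tongue-and-groove halves, interleaf air gap). Columns:
# leaf_number  y_breakpoint_cm  thickness_cm
# A row opens a segment extending to the next row's breakpoint.
  1   -10.86200   3.3500
  1   -10.32550   0.0000
  2   -10.31950   3.3500
  2    -9.78300   0.0000
  3    -9.77700   3.3500
  3    -9.24050   0.0000
  4    -9.23450   3.3500
  4    -8.69800   0.0000
  5    -8.69200   3.3500
  5    -8.15550   0.0000
  6    -8.14950   3.3500
  6    -7.61300   0.0000
  7    -7.60700   3.3500
  7    -7.07050   0.0000
  8    -7.06450   3.3500
  8    -6.52800   0.0000
  9    -6.52200   3.3500
  9    -5.98550   0.0000
 10    -5.97950   3.3500
 10    -5.44300   0.0000
 11    -5.43700   3.3500
 11    -5.17175   0.0000
 12    -5.16575   3.3500
 12    -4.90050   0.0000
 13    -4.89450   3.3500
 13    -4.62925   0.0000
 14    -4.62325   3.3500
 14    -4.35800   0.0000
 15    -4.35200   3.3500
 15    -4.08675   0.0000
 16    -4.08075   3.3500
 16    -3.81550   0.0000
 17    -3.80950   3.3500
 17    -3.54425   0.0000
 18    -3.53825   3.3500
 18    -3.27300   0.0000
 19    -3.26700   3.3500
 19    -3.00175   0.0000
 20    -2.99575   3.3500
 20    -2.73050   0.0000
 21    -2.72450   3.3500
 21    -2.45925   0.0000
 22    -2.45325   3.3500
 22    -2.18800   0.0000
 23    -2.18200   3.3500
 23    -1.91675   0.0000
 24    -1.91075   3.3500
 24    -1.64550   0.0000
 25    -1.63950   3.3500
 25    -1.37425   0.0000
 26    -1.36825   3.3500
 26    -1.10300   0.0000
 27    -1.09700   3.3500
 27    -0.83175   0.0000
 28    -0.82575   3.3500
 28    -0.56050   0.0000
 29    -0.55450   3.3500
 29    -0.28925   0.0000
 30    -0.28325   3.3500
 30    -0.01800   0.0000
 31    -0.01200   3.3500
 31    +0.25325   0.0000
 32    +0.25925   3.3500
 32    +0.52450   0.0000
 33    +0.53050   3.3500
 33    +0.79575   0.0000
 34    +0.80175   3.3500
 34    +1.06700   0.0000
 35    +1.07300   3.3500
 35    +1.33825   0.0000
 36    +1.34425   3.3500
 36    +1.60950   0.0000
 37    +1.61550   3.3500
 37    +1.88075   0.0000
 38    +1.88675   3.3500
 38    +2.15200   0.0000
 39    +2.15800   3.3500
 39    +2.42325   0.0000
 40    +2.42925   3.3500
 40    +2.69450   0.0000
 41    +2.70050   3.3500
 41    +2.96575   0.0000
 42    +2.97175   3.3500
 42    +3.23700   0.0000
 43    +3.24300   3.3500
 43    +3.50825   0.0000
 44    +3.51425   3.3500
 44    +3.77950   0.0000
 45    +3.78550   3.3500
 45    +4.05075   0.0000
 46    +4.05675   3.3500
 46    +4.32200   0.0000
 47    +4.32800   3.3500
 47    +4.59325   0.0000
 48    +4.59925   3.3500
 48    +4.86450   0.0000
 49    +4.87050   3.3500
 49    +5.13575   0.0000
 50    +5.14175   3.3500
 50    +5.40700   0.0000
 51    +5.41300   3.3500
 51    +5.94950   0.0000
 52    +5.95550   3.3500
 52    +6.49200   0.0000
 53    +6.49800   3.3500
 53    +7.03450   0.0000
 54    +7.04050   3.3500
 54    +7.57700   0.0000
 55    +7.58300   3.3500
 55    +8.11950   0.0000
 56    +8.12550   3.3500
 56    +8.66200   0.0000
 57    +8.66800   3.3500
 57    +9.20450   0.0000
 58    +9.21050   3.3500
 58    +9.74700   0.0000
 59    +9.75300   3.3500
 59   +10.28950   0.0000
 60   +10.29550   3.3500
 60   +10.83200   0.0000
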