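# Synthesized HD120 MLC configuration (vendor values proprietary;
# geometry follows the published construction data; density and interleaf
# gap calibrated to the measured 6X transmission).
model_name = HD120
leaf_widths_iso = 14*0.5,32*0.25,14*0.5
physical_thickness = 6.9
tip_radius = 16.0
tip_angle = 0.0
density = 18.9
leaf_offset = 0.0
z_upper = 50.9
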