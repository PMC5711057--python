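# Synthesized Millennium120 MLC configuration (vendor values proprietary;
# geometry follows the published construction data; density and interleaf
# gap calibrated to the measured 6X transmission).
model_name = Millennium120
leaf_widths_iso = 10*1.0,40*0.5,10*1.0
physical_thickness = 6.7
tip_radius = 8.0
tip_angle = 11.3
density = 17.6
leaf_offset = 0.0
z_upper = 50.9
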