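# Synthetic stand-in calibration anchors for the hypocotyl map: representative
# Col-0 wild-type seedling hypocotyl lengths under short and long days.
photoperiod_h	length_mm
8	6.8
16	2.4
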