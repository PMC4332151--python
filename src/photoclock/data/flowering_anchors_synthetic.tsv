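# Synthetic stand-in calibration anchors for the flowering map: representative
# Col-0 wild-type days-to-flower under short and long days.  Replace with
# study-specific measurements to recalibrate.
photoperiod_h	days_to_flower
8	58.0
16	21.0
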