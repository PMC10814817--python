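"""Canonical disc labels, ordered top to bottom of the lumbar spine."""

#: the three target discs; fixed order (upper, lower, lowest)
DISC_LABELS = ("L1L2", "L4L5", "L5S1")

#: the two lower targets segmented by the crop-then-segment stages
LOWER_LABELS = ("L4L5", "L5S1")

#: the remaining upper target segmented with distance-map augmentation
UPPER_LABEL = "L1L2"
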