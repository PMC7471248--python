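"""Shared label vocabulary for per-pixel class maps and TSR categories.

Label masks are plain ``uint8`` arrays over the image canvas; the three
pixel classes match the tissue components distinguished on H&E slides.
"""

LABEL_BACKGROUND = 0  # background, necrosis, and other non-tumor tissue
LABEL_EPITHELIUM = 1  # tumor epithelial cells (hematoxylin-dominant)
LABEL_STROMA = 2      # desmoplastic stroma (eosin-dominant)

VALID_LABELS = (LABEL_BACKGROUND, LABEL_EPITHELIUM, LABEL_STROMA)

HIGH_STROMAL = "high_stromal"  # TSR <= cutoff: stroma-rich tumor
LOW_STROMAL = "low_stromal"    # TSR > cutoff: epithelium-rich tumor

CATEGORIES = (HIGH_STROMAL, LOW_STROMAL)
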