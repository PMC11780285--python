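"""Canonical analysis time grid and 3-month block layout.

Weigh-ins are analysed at five points: baseline, ~12 weeks, and 6, 9 and
12 months.  The four inter-point intervals are the "blocks" over which
trajectory symbols (L/M/G) and per-block platform use are computed.  The
first block is nominally 12 weeks; the program and its reporting treat
"12 weeks" and "3 months" as interchangeable.
"""

TIME_POINTS = ("baseline", "w12", "m6", "m9", "m12")
POST_BASELINE = ("w12", "m6", "m9", "m12")
INTERVALS = ("b1", "b2", "b3", "b4")

#: (start, end) time points of each 3-month block
BLOCKS = (
    ("baseline", "w12"),
    ("w12", "m6"),
    ("m6", "m9"),
    ("m9", "m12"),
)

#: weeks per block, used to express per-block platform use as activity/week
BLOCK_WEEKS = (12.0, 13.0, 13.0, 13.0)

#: maintenance band (kg): a block change within +/- this is "M"
MAINTENANCE_BAND_KG = 1.4

#: weight validity cutoffs (kg), strict: weights < 13 or > 250 are invalid
WEIGHT_VALID_MIN_KG = 13.0
WEIGHT_VALID_MAX_KG = 250.0
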