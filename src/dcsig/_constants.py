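"""Shared label vocabulary and small numeric helpers."""

import math

INFLAMMATORY = "inflammatory"
NON_INFLAMMATORY = "non_inflammatory"
CLASS_LABELS = (INFLAMMATORY, NON_INFLAMMATORY)

UP = "up"
DOWN = "down"
DIRECTIONS = (UP, DOWN)

#: label an unclassified qPCR condition carries before a class call is made
UNKNOWN = "unknown"


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up.

    Used for percent formatting and split sizes; Python's built-in
    ``round`` is banker's rounding, which would map e.g. 76.5 -> 76.
    """
    return int(math.floor(x + 0.5))
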