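"""Shared fixed-window tiling constants.

The genome is tiled into fixed, non-overlapping 200 bp windows: the
window of a position ``p`` is ``[floor(p/200)*200, floor(p/200)*200 + 200)``
in 0-based half-open coordinates. 200 bp approximates the median exon
length of the target genome, so windowed methylation differences map
naturally onto exon-scale features.
"""

WINDOW_SIZE = 200
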