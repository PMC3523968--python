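"""Boundary-condition modes of the walking cell.

The cell is advanced under exactly one of three boundary-condition sets:

* ``STEADY`` -- both edges free; the protrusive stress acts on the leading
  edge and the trailing edge carries no external load.  This is the classic
  steadily-creeping viscoelastic cell.
* ``FRONT_ADVANCE`` -- the trailing edge is anchored to the substrate and
  the protrusive stress drives the leading edge forward.
* ``REAR_RETRACT`` -- the leading edge is anchored and the freed trailing
  edge is dragged forward by the stress stored in the cell body.
"""

from __future__ import annotations

import enum


class BoundaryMode(enum.Enum):
    STEADY = "steady"
    FRONT_ADVANCE = "front_advance"
    REAR_RETRACT = "rear_retract"

    def __str__(self) -> str:  # compact labels for trajectory tables
        return self.value
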