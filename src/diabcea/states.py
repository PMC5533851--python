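"""Glucose states of the Markov model.

Six mutually exclusive states: normal glucose tolerance (NGT), the three
pre-diabetic states — impaired fasting glucose (IFG), impaired glucose
tolerance (IGT) and their combination (IFG&IGT) — manifest type 2 diabetes
(T2D), and the absorbing state DEAD.
"""

from __future__ import annotations

from enum import IntEnum


class GlucoseState(IntEnum):
    """Model states, in the fixed order used by occupancy vectors and matrices."""

    NGT = 0
    IFG = 1
    IGT = 2
    IFG_IGT = 3
    T2D = 4
    DEAD = 5


#: The five living states, in occupancy order.
LIVING_STATES = tuple(s for s in GlucoseState if s is not GlucoseState.DEAD)

#: The three pre-diabetic states (where every cohort starts).
PREDIABETIC_STATES = (GlucoseState.IFG, GlucoseState.IGT, GlucoseState.IFG_IGT)

N_STATES = len(GlucoseState)
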