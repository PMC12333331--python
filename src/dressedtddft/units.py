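"""Unit conversion constants.

All internal math is in hartree atomic units; eV and meV appear only at
reporting boundaries.
"""

HARTREE_TO_EV: float = 27.211386245988
HARTREE_TO_MEV: float = HARTREE_TO_EV * 1000.0


def hartree_to_ev(value):
    return value * HARTREE_TO_EV


def ev_to_hartree(value):
    return value / HARTREE_TO_EV
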