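"""Bundled synthetic worked-example analog sets.

These are *synthetic* demonstration sets, generated once with the
package's own generators (:mod:`oligorep.simulate`, seed 2019) and frozen
here so that the docs, the test suite and the acceptance script all run
the same small, fully deterministic examples:

* a two-analog set -- a random 10-mer and a copy carrying three
  substitutions, at 1 unit (uM) each; and
* a three-analog set -- an 8-mer origin with three analogs carrying two
  independent substitutions each, at 1 unit each.

They follow the canonical study designs (pair with three mutual
mismatches; 8-mer origin with two-mutation analogs) but the concrete
sequences are this package's own random draws.
"""

from __future__ import annotations

from .representative import AnalogMember, AnalogSet

#: Two 10-mer analogs differing at three positions (synthetic, seed 2019).
TWO_ANALOG_SEQUENCES = {
    "Analog A": "CACCGCCTGA",
    "Analog B": "AACCGCCGTA",
}

#: 8-mer origin and three analogs with two substitutions each
#: (synthetic, seed 2019; mutated positions in the provenance map).
THREE_ANALOG_ORIGIN = "TGCCGTGT"
THREE_ANALOG_SEQUENCES = {
    "Analog 1": "TGCCCTTT",
    "Analog 2": "TACGGTGT",
    "Analog 3": "AACCGTGT",
}
THREE_ANALOG_PROVENANCE = {
    "Analog 1": (4, 6),
    "Analog 2": (1, 3),
    "Analog 3": (0, 1),
}


def two_analog_example(concentration: float = 1.0) -> AnalogSet:
    """The synthetic two-analog (10-mer, three mismatches) worked example."""
    members = tuple(AnalogMember(name, seq, concentration)
                    for name, seq in TWO_ANALOG_SEQUENCES.items())
    return AnalogSet(members=members)


def three_analog_example(concentration: float = 1.0) -> AnalogSet:
    """The synthetic three-analog (8-mer origin, two mutations) example."""
    members = tuple(AnalogMember(name, seq, concentration)
                    for name, seq in THREE_ANALOG_SEQUENCES.items())
    return AnalogSet(members=members, origin=THREE_ANALOG_ORIGIN,
                     provenance=dict(THREE_ANALOG_PROVENANCE))
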