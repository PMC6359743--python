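"""Validated short DNA sequences and Watson-Crick complementation.

All strands in this package are plain uppercase strings over {A, C, G, T},
read 5'->3'.  Two strands of equal length hybridize antiparallel and
end-to-end: position ``i`` of one strand pairs with position ``N-1-i`` of
the other.  Lengths are capped at 16 so that the exhaustive 4**N candidate
enumerations elsewhere in the package stay desk-scale.
"""

from __future__ import annotations

import numpy as np

#: Canonical base order; also the digit order of the base-4 candidate codes.
BASES = "ACGT"

#: Watson-Crick pairing partner of each base.
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_COMP_TABLE = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

MIN_LENGTH = 2
MAX_LENGTH = 16


class SequenceError(ValueError):
    """Raised for malformed nucleotide sequences."""


def clean_sequence(seq: str, *, min_length: int = MIN_LENGTH,
                   max_length: int = MAX_LENGTH) -> str:
    """Validate ``seq`` and return its canonical uppercase form.

    Raises
    ------
    SequenceError
        If the sequence contains characters outside {A, C, G, T} (case
        insensitive) or its length falls outside ``[min_length, max_length]``.
    """
    if not isinstance(seq, str):
        raise SequenceError(f"expected a string, got {type(seq).__name__}")
    s = seq.strip().upper()
    if not (min_length <= len(s) <= max_length):
        raise SequenceError(
            f"sequence length {len(s)} outside [{min_length}, {max_length}]: {s!r}")
    bad = set(s) - set(BASES)
    if bad:
        raise SequenceError(f"invalid bases {sorted(bad)} in {s!r}")
    return s


def wc_complement(seq: str) -> str:
    """Antiparallel Watson-Crick partner (reverse complement), 5'->3'."""
    return clean_sequence(seq)[::-1].translate(_COMP_TABLE)


def base_indices(seq: str) -> np.ndarray:
    """Map a sequence onto its digit representation (A=0, C=1, G=2, T=3)."""
    return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between two equal-length strands."""
    if len(a) != len(b):
        raise SequenceError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
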