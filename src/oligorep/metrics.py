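"""Hybridization-profile similarity between sequences.

Two complementary views of "how alike do these strands hybridize":

* closeness -- the number of shared members of the two strands' top-k
  lowest-dG complement lists (an integer in [0, k]); and
* the Pearson correlation of the two full 4**N dG profiles.

Closeness drives the merge ordering of the iterative representative-
sequence construction; the Pearson correlation is the headline similarity
statistic of the replicate studies.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .candidates import top_k
from .sequences import clean_sequence
from .thermo import NNParameterSet, ThermoConfig, delta_g_profile


def shared_count(codes_a: np.ndarray, codes_b: np.ndarray) -> int:
    """|A ∩ B| for two arrays of candidate codes."""
    return int(np.intersect1d(codes_a, codes_b, assume_unique=True).size)


def closeness(a: str, b: str, k: int = 1000,
              params: NNParameterSet | None = None,
              cfg: ThermoConfig | None = None) -> int:
    """Shared members of the two strands' top-k lowest-dG complement lists.

    Symmetric; equals ``k`` for identical strands.  ``k`` larger than the
    candidate space is rejected.
    """
    sa, sb = clean_sequence(a), clean_sequence(b)
    if len(sa) != len(sb):
        raise ValueError("closeness requires equal-length sequences")
    pa = delta_g_profile(sa, params, cfg)
    pb = delta_g_profile(sb, params, cfg)
    ra = top_k(pa, k, length=len(sa))
    rb = top_k(pb, k, length=len(sb))
    return shared_count(ra.codes, rb.codes)


def closeness_matrix(seqs: Sequence[str], names: Sequence[str] | None = None,
                     k: int = 1000,
                     params: NNParameterSet | None = None,
                     cfg: ThermoConfig | None = None) -> pd.DataFrame:
    """Symmetric closeness table for a set of equal-length sequences."""
    seqs = [clean_sequence(s) for s in seqs]
    if names is None:
        names = [f"seq{i + 1}" for i in range(len(seqs))]
    code_sets = [
        top_k(delta_g_profile(s, params, cfg), k, length=len(s)).codes
        for s in seqs
    ]
    m = len(seqs)
    counts = np.zeros((m, m), dtype=int)
    for i in range(m):
        counts[i, i] = k
        for j in range(i + 1, m):
            counts[i, j] = counts[j, i] = shared_count(code_sets[i], code_sets[j])
    return pd.DataFrame(counts, index=list(names), columns=list(names))


def pearson_from_profiles(pa: np.ndarray, pb: np.ndarray) -> float:
    """Pearson r between two dG profiles; errors on zero variance."""
    if pa.std() == 0.0 or pb.std() == 0.0:
        raise ValueError("Pearson correlation undefined for a constant profile")
    return float(np.corrcoef(pa, pb)[0, 1])


def pearson_profile(a: str, b: str,
                    params: NNParameterSet | None = None,
                    cfg: ThermoConfig | None = None) -> float:
    """Pearson correlation of the full dG profiles of two strands."""
    sa, sb = clean_sequence(a), clean_sequence(b)
    if len(sa) != len(sb):
        raise ValueError("profile correlation requires equal-length sequences")
    return pearson_from_profiles(delta_g_profile(sa, params, cfg),
                                 delta_g_profile(sb, params, cfg))
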