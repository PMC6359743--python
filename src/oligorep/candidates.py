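"""Canonical encoding and ranking of the 4**N candidate-complement space.

Every candidate strand of length N is assigned a code in ``[0, 4**N)``:
base-4 digits with A=0, C=1, G=2, T=3, most-significant digit first,
sequence read 5'->3'.  Rankings are by ascending dG with ties broken by
ascending code, so all orderings in the package are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequences import BASES, base_indices, clean_sequence
from .thermo import NNParameterSet, ThermoConfig, delta_g_profile


def encode(seq: str) -> int:
    """Base-4 code of a sequence (A=0, C=1, G=2, T=3, MSB first)."""
    s = clean_sequence(seq)
    code = 0
    for d in base_indices(s):
        code = code * 4 + int(d)
    return code


def decode(code: int, length: int) -> str:
    """Inverse of :func:`encode` for a given strand length."""
    if not 0 <= code < 4 ** length:
        raise ValueError(f"code {code} out of range for length {length}")
    bases = []
    for _ in range(length):
        bases.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(bases))


@dataclass(frozen=True)
class CandidateRanking:
    """The ``k`` lowest-dG candidate codes of a (possibly summed) profile.

    ``scores`` is non-decreasing; ties are resolved by ascending code.
    """

    codes: np.ndarray
    scores: np.ndarray
    k: int
    length: int

    def __post_init__(self) -> None:
        if len(self.codes) != self.k or len(self.scores) != self.k:
            raise ValueError("ranking length inconsistent with k")

    def sequences(self) -> list[str]:
        return [decode(int(c), self.length) for c in self.codes]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "rank": np.arange(self.k),
            "code": self.codes,
            "sequence": self.sequences(),
            "delta_g_sum": self.scores,
        })


def top_k(profile: np.ndarray, k: int, *, length: int | None = None) -> CandidateRanking:
    """The ``k`` smallest entries of a dG profile, ties broken by code.

    Exact tie handling matters because profile values are sums of a small
    set of stack energies and collide frequently; candidates with scores
    equal to the k-th smallest are disambiguated by ascending code.
    """
    m = int(profile.shape[0])
    if not 1 <= k <= m:
        raise ValueError(f"k={k} out of range for profile of size {m}")
    if length is None:
        length = round(np.log(m) / np.log(4))
    if k == m:
        cand = np.arange(m)
    else:
        part = np.argpartition(profile, k - 1)[:k]
        threshold = profile[part].max()
        cand = np.flatnonzero(profile <= threshold)
    order = np.lexsort((cand, profile[cand]))
    codes = cand[order][:k]
    return CandidateRanking(codes=codes, scores=profile[codes], k=k, length=length)


def combined_ranking(analogs: Sequence[str], k: int = 1000,
                     params: NNParameterSet | None = None,
                     cfg: ThermoConfig | None = None,
                     *, return_profiles: bool = False):
    """Rank candidates by the unweighted sum of per-analog duplex dG.

    This is the shortlist from which the common complement sequence (CS) is
    later selected by competitive equilibrium; analog concentrations do not
    enter the ranking.  Permutation-invariant in analog order.
    """
    seqs = [clean_sequence(s) for s in analogs]
    if not seqs:
        raise ValueError("need at least one analog")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"analogs must share one length, got {sorted(lengths)}")
    n = lengths.pop()
    profiles = np.stack([delta_g_profile(s, params, cfg) for s in seqs])
    ranking = top_k(profiles.sum(axis=0), k, length=n)
    if return_profiles:
        return ranking, profiles
    return ranking
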