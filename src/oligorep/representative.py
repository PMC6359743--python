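"""Selection of the common complement (CS) and representative sequence (RS).

The CS of an analog group is the candidate strand that maximizes the summed
equilibrium hybridization yield against all analogs at their actual
concentrations, searched over a shortlist of the lowest summed-dG
candidates.  The RS is the reverse complement of the CS, carried with an
equivalent concentration: the RS total is set so that a plain two-strand
CS+RS equilibrium binds exactly the amount of CS that the analog mixture
bound.  Groups of three or more analogs are reduced pairwise, always
merging the pair with the highest closeness and feeding the intermediate RS
back in as a new analog -- the sequence-space analogue of updating a
K-means centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np

from .candidates import combined_ranking, decode, top_k
from .equilibrium import (EquilibriumState, ReactionSystem, binding_constant,
                          competition_yields, solve_competition, total_yield)
from .metrics import shared_count
from .sequences import clean_sequence, wc_complement
from .thermo import NNParameterSet, ThermoConfig, delta_g_profile, duplex_delta_g


@dataclass(frozen=True)
class AnalogMember:
    name: str
    sequence: str
    concentration: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_sequence(self.sequence))
        if self.concentration <= 0:
            raise ValueError(f"{self.name}: concentration must be positive")


@dataclass(frozen=True)
class AnalogSet:
    """Named equal-length sequences with concentrations and provenance."""

    members: tuple
    origin: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = tuple(
            m if isinstance(m, AnalogMember) else AnalogMember(*m)
            for m in self.members)
        if not members:
            raise ValueError("analog set must not be empty")
        lengths = {len(m.sequence) for m in members}
        if len(lengths) != 1:
            raise ValueError("all analogs must share one length")
        names = [m.name for m in members]
        if len(set(names)) != len(names):
            raise ValueError("analog names must be unique")
        object.__setattr__(self, "members", members)
        if self.origin is not None:
            object.__setattr__(self, "origin", clean_sequence(self.origin))

    def __len__(self) -> int:
        return len(self.members)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.members]

    @property
    def sequences(self) -> list[str]:
        return [m.sequence for m in self.members]

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([m.concentration for m in self.members])

    @property
    def length(self) -> int:
        return len(self.members[0].sequence)


@dataclass(frozen=True)
class MergeStep:
    """One pairwise reduction of the iterative RS construction."""

    merged: tuple          # (name_a, name_b)
    closeness: int
    cs: str
    rs: str
    rs_concentration: float
    pair_total_yield: float


@dataclass(frozen=True)
class RepresentativeResult:
    """Final CS/RS of an analog group plus the pairwise merge history.

    ``per_analog_yield`` and ``total_yield`` evaluate the final CS against
    the *original* analogs at their concentrations (candidate total equal to
    their summed concentration), regardless of the merge path.
    """

    cs: str
    rs: str
    rs_concentration: float
    per_analog_yield: np.ndarray
    total_yield: float
    merge_tree: tuple
    analog_names: tuple


def select_cs(analogs: AnalogSet | Sequence, pool_size: int = 1000,
              params: NNParameterSet | None = None,
              cfg: ThermoConfig | None = None,
              *, candidate_total: float | None = None):
    """Pick the CS: pooled argmax of total equilibrium yield.

    The shortlist is the ``pool_size`` candidates with the lowest summed dG
    across analogs (concentration-free); the winner is the shortlist member
    with the highest summed equilibrium yield at the analogs' actual
    concentrations.  Ties go to the lower summed dG, then the lower code.

    Returns ``(cs_sequence, EquilibriumState)`` for the winning candidate.
    """
    analogs = as_analog_set(analogs)
    cfg = cfg or ThermoConfig()
    n = analogs.length
    k = min(pool_size, 4 ** n)
    ranking, profiles = combined_ranking(analogs.sequences, k, params, cfg,
                                         return_profiles=True)
    dg = profiles[:, ranking.codes]                  # (n_analogs, k)
    ks = binding_constant(dg, cfg).T                 # (k, n_analogs)
    totals = analogs.concentrations
    ctot = candidate_total if candidate_total is not None else float(totals.sum())
    yields = competition_yields(ks, totals, ctot)    # (k, n_analogs)
    tot = yields.sum(axis=1)
    best = int(np.lexsort((ranking.codes, ranking.scores, -tot))[0])
    cs = decode(int(ranking.codes[best]), n)
    system = ReactionSystem(analog_totals=totals,
                            binding_constants=ks[best],
                            candidate_total=ctot)
    return cs, solve_competition(system)


def derive_rs(cs: str) -> str:
    """The representative sequence: reverse complement of the CS."""
    return wc_complement(cs)


def rs_concentration(cs: str, cs_total: float, bound_amount: float,
                     params: NNParameterSet | None = None,
                     cfg: ThermoConfig | None = None) -> float:
    """Equivalent RS concentration reproducing the analogs' bound CS amount.

    For the two-strand equilibrium CS + RS with binding constant K of the
    perfect CS/RS duplex, the RS total c satisfies
    ``K (c - x)(C - x) = x`` at duplex amount ``x = bound_amount``, so

        c = x + x / (K (C - x)).

    ``bound_amount`` must lie in (0, cs_total); values >= the CS total would
    require infinite RS.
    """
    cfg = cfg or ThermoConfig()
    if bound_amount <= 0:
        return 0.0
    if bound_amount >= cs_total:
        raise ValueError("bound amount must be below the CS total")
    rs = derive_rs(cs)
    k = float(binding_constant(duplex_delta_g(rs, cs, params, cfg), cfg))
    return bound_amount + bound_amount / (k * (cs_total - bound_amount))


def as_analog_set(analogs) -> AnalogSet:
    """Coerce a list of sequences / (name, seq, conc) tuples to an AnalogSet."""
    if isinstance(analogs, AnalogSet):
        return analogs
    members = []
    for i, item in enumerate(analogs):
        if isinstance(item, AnalogMember):
            members.append(item)
        elif isinstance(item, str):
            members.append(AnalogMember(f"seq{i + 1}", item))
        else:
            members.append(AnalogMember(*item))
    return AnalogSet(members=tuple(members))


def merge_pair(analogs: AnalogSet, name_a: str, name_b: str,
               pool_size: int = 1000,
               params: NNParameterSet | None = None,
               cfg: ThermoConfig | None = None,
               *, closeness_value: int = -1):
    """Replace two members with the RS of their pair.

    The pair's CS is selected at the two members' concentrations with the
    candidate total equal to their sum; the merged member carries the RS
    sequence and its equivalent concentration, under the name "a/b".
    Returns ``(new AnalogSet, MergeStep)``.
    """
    if name_a == name_b:
        raise ValueError("cannot merge a member with itself")
    byname = {m.name: m for m in analogs.members}
    a, b = byname[name_a], byname[name_b]
    pair = AnalogSet(members=(a, b))
    cs, state = select_cs(pair, pool_size, params, cfg)
    rs = derive_rs(cs)
    bound = float(np.sum(state.duplex))
    conc = rs_concentration(cs, state.system.candidate_total, bound, params, cfg)
    merged = AnalogMember(name=f"{name_a}/{name_b}", sequence=rs,
                          concentration=conc)
    rest = tuple(m for m in analogs.members if m.name not in (name_a, name_b))
    step = MergeStep(merged=(name_a, name_b), closeness=closeness_value,
                     cs=cs, rs=rs, rs_concentration=conc,
                     pair_total_yield=total_yield(state))
    new_set = AnalogSet(members=rest + (merged,), origin=analogs.origin,
                        provenance=analogs.provenance)
    return new_set, step


def _closest_pair(analogs: AnalogSet, closeness_k: int, pool_size: int,
                  params, cfg):
    """Pair with maximal closeness; ties by the pair equilibrium yield,
    then lexicographic names."""
    n = analogs.length
    k = min(closeness_k, 4 ** n)
    codes = {
        m.name: top_k(delta_g_profile(m.sequence, params, cfg), k,
                      length=n).codes
        for m in analogs.members
    }
    scored = [
        (shared_count(codes[a.name], codes[b.name]), a.name, b.name)
        for a, b in combinations(analogs.members, 2)
    ]
    best = max(c for c, _, _ in scored)
    tied = [(na, nb) for c, na, nb in scored if c == best]
    if len(tied) > 1:
        def pair_yield(names):
            byname = {m.name: m for m in analogs.members}
            pair = AnalogSet(members=(byname[names[0]], byname[names[1]]))
            _, state = select_cs(pair, pool_size, params, cfg)
            return total_yield(state)
        yields = [pair_yield(t) for t in tied]
        top = max(yields)
        tied = sorted(t for t, y in zip(tied, yields) if y == top)
    return tied[0], best


def iterative_rs(analogs: AnalogSet | Sequence, pool_size: int = 1000,
                 closeness_k: int = 1000,
                 params: NNParameterSet | None = None,
                 cfg: ThermoConfig | None = None) -> RepresentativeResult:
    """Reduce an analog group to one RS by closeness-ordered pairwise merges.

    Each round recomputes closeness among the current members (original
    analogs and intermediate representative sequences alike), merges the
    closest pair into its RS at the equivalent concentration, and repeats
    until one member remains.  The final member's CS/RS is the result; its
    reported yields re-evaluate that CS against the original analogs.
    """
    analogs = as_analog_set(analogs)
    if len(analogs) < 2:
        raise ValueError("need at least two analogs")
    cfg = cfg or ThermoConfig()
    current = analogs
    tree: list[MergeStep] = []
    while len(current) > 1:
        (na, nb), close = _closest_pair(current, closeness_k, pool_size,
                                        params, cfg)
        current, step = merge_pair(current, na, nb, pool_size, params, cfg,
                                   closeness_value=close)
        tree.append(step)
    final = tree[-1]
    # Re-evaluate the final CS against the original analog group.
    dg = np.array([duplex_delta_g(s, final.cs, params, cfg)
                   for s in analogs.sequences])
    system = ReactionSystem(analog_totals=analogs.concentrations,
                            binding_constants=binding_constant(dg, cfg))
    state = solve_competition(system)
    return RepresentativeResult(cs=final.cs, rs=final.rs,
                                rs_concentration=final.rs_concentration,
                                per_analog_yield=state.yields,
                                total_yield=total_yield(state),
                                merge_tree=tuple(tree),
                                analog_names=tuple(analogs.names))
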