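"""Synthetic sequence sets: origins, mutant ladders and replicate studies.

These generators reproduce the study designs used throughout the package's
validation: a random origin, cumulative single-base mutant ladders (Mut-1
carries one substitution, Mut-2 carries Mut-1's plus one more, ...),
independent random analog sets with a fixed per-analog mutation count, and
replicate drivers that repeat the whole RS construction over many random
sets and tabulate profile-correlation statistics.

Mutations are uniform random substitutions (never to the original base);
no attempt is made to emulate biological mutation processes.  A single
global seed spawns one recorded child seed per replicate set, so any row
of a replicate table can be regenerated exactly.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import pearson_from_profiles
from .representative import AnalogMember, AnalogSet, iterative_rs
from .sequences import BASES, clean_sequence
from .thermo import NNParameterSet, ThermoConfig, delta_g_profile

_SEED_CAP = 2 ** 31 - 1


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_origin(length: int, seed=None) -> str:
    """Uniform random sequence of the given length (2-16)."""
    if not 2 <= length <= 16:
        raise ValueError("length must be in [2, 16]")
    rng = _rng(seed)
    return "".join(rng.choice(list(BASES), size=length))


def _mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    bases = list(seq)
    for p in positions:
        choices = [b for b in BASES if b != bases[p]]
        bases[p] = choices[rng.integers(len(choices))]
    return "".join(bases)


def cumulative_mutants(origin: str, count: int, seed=None) -> list[str]:
    """Mutant ladder: Mut-k differs from the origin at exactly k positions.

    Each mutant inherits all previous substitutions and adds one at a fresh
    position, so consecutive mutants differ at exactly one position.
    """
    origin = clean_sequence(origin)
    if count > len(origin):
        raise ValueError("cannot mutate more positions than the length")
    rng = _rng(seed)
    positions = rng.permutation(len(origin))[:count]
    mutants = []
    current = origin
    for p in positions:
        current = _mutate(current, [int(p)], rng)
        mutants.append(current)
    return mutants


def random_analog_set(origin: str, n_analogs: int, n_mutations: int,
                      seed=None, *, concentration: float = 1.0,
                      prefix: str = "Analog") -> AnalogSet:
    """Analogs carrying ``n_mutations`` independent substitutions each.

    Mutated positions are drawn independently per analog (without
    replacement within an analog); all analogs get equal concentrations
    by default.
    """
    origin = clean_sequence(origin)
    if n_mutations > len(origin):
        raise ValueError("cannot mutate more positions than the length")
    rng = _rng(seed)
    members, provenance = [], {}
    for i in range(n_analogs):
        positions = [int(p) for p in rng.permutation(len(origin))[:n_mutations]]
        name = f"{prefix} {i + 1}"
        members.append(AnalogMember(name=name,
                                    sequence=_mutate(origin, positions, rng),
                                    concentration=concentration))
        provenance[name] = tuple(sorted(positions))
    return AnalogSet(members=tuple(members), origin=origin,
                     provenance=provenance)


def mismatched_pair(length: int, n_mismatches: int, seed=None,
                    *, concentration: float = 1.0) -> AnalogSet:
    """A random strand and a copy carrying ``n_mismatches`` substitutions.

    This is the two-analog study design: the pair differs at exactly
    ``n_mismatches`` positions *from each other* (no separate origin).
    """
    rng = _rng(seed)
    a = random_origin(length, rng)
    positions = [int(p) for p in rng.permutation(length)[:n_mismatches]]
    b = _mutate(a, positions, rng)
    members = (AnalogMember("Analog A", a, concentration),
               AnalogMember("Analog B", b, concentration))
    return AnalogSet(members=members,
                     provenance={"Analog B": tuple(sorted(positions))})


def set_statistics(analogs: AnalogSet, pool_size: int = 1000,
                   closeness_k: int = 1000,
                   params: NNParameterSet | None = None,
                   cfg: ThermoConfig | None = None) -> dict:
    """Run the RS construction on one analog set and collect Pearson stats.

    Returns mean profile correlations origin<->analogs, RS<->analogs and
    analog<->analog (pairwise), plus the RS itself and its concentration.
    """
    result = iterative_rs(analogs, pool_size, closeness_k, params, cfg)
    profiles = {s: delta_g_profile(s, params, cfg)
                for s in set(analogs.sequences) | {result.rs, analogs.origin}
                if s is not None}
    seqs = analogs.sequences
    pair_r = [pearson_from_profiles(profiles[a], profiles[b])
              for a, b in combinations(seqs, 2)]
    rs_r = [pearson_from_profiles(profiles[result.rs], profiles[a])
            for a in seqs]
    out = {
        "rs": result.rs,
        "cs": result.cs,
        "rs_concentration": result.rs_concentration,
        "total_yield": result.total_yield,
        "r_rs_analogs": float(np.mean(rs_r)),
        "r_analog_pairs": float(np.mean(pair_r)) if pair_r else np.nan,
    }
    if analogs.origin is not None:
        origin_r = [pearson_from_profiles(profiles[analogs.origin], profiles[a])
                    for a in seqs]
        out["r_origin_analogs"] = float(np.mean(origin_r))
    return out


def replicate_study(n_sets: int, n_analogs: int, n_mutations: int,
                    length: int, seed=None, *, design: str = "from_origin",
                    pool_size: int = 1000, closeness_k: int = 1000,
                    concentration: float = 1.0,
                    params: NNParameterSet | None = None,
                    cfg: ThermoConfig | None = None) -> pd.DataFrame:
    """Repeat the RS construction over ``n_sets`` random analog sets.

    ``design`` selects how a set is drawn: ``"from_origin"`` mutates every
    analog independently from a shared random origin (the multi-analog
    study), while ``"pair"`` draws a random strand and a copy with
    ``n_mutations`` substitutions, so the two analogs differ from *each
    other* by that many bases (the two-analog study; requires
    ``n_analogs == 2``).

    Each row records the child seed (for exact replay), the origin (where
    the design has one), the RS and the mean profile correlations.  Use
    ``.mean()`` / ``.std()`` on the correlation columns for the study
    summary.
    """
    if design not in ("from_origin", "pair"):
        raise ValueError(f"unknown design {design!r}")
    if design == "pair" and n_analogs != 2:
        raise ValueError("the pair design is defined for exactly 2 analogs")
    root = _rng(seed)
    rows = []
    for i in range(n_sets):
        child = int(root.integers(_SEED_CAP))
        rng = np.random.default_rng(child)
        if design == "pair":
            analogs = mismatched_pair(length, n_mutations, rng,
                                      concentration=concentration)
            origin = None
        else:
            origin = random_origin(length, rng)
            analogs = random_analog_set(origin, n_analogs, n_mutations, rng,
                                        concentration=concentration)
        stats = set_statistics(analogs, pool_size, closeness_k, params, cfg)
        rows.append({"set": i, "seed": child, "origin": origin, **stats})
    return pd.DataFrame(rows)


def mutation_sweep(mutation_counts: Sequence[int] = (1, 2, 3, 4),
                   n_sets: int = 30, n_analogs: int = 5, length: int = 8,
                   seed=None, **kwargs) -> pd.DataFrame:
    """Replicate studies across mutation loads, one summary row per load.

    Tabulates how the origin's and the RS's mean correlation with the
    analogs decay as the analogs drift, and their ratio (RS/origin), which
    grows with mutation load.
    """
    root = _rng(seed)
    rows = []
    for m in mutation_counts:
        table = replicate_study(n_sets, n_analogs, m, length, root, **kwargs)
        rows.append({
            "n_mutations": m,
            "r_origin_analogs": table["r_origin_analogs"].mean(),
            "r_rs_analogs": table["r_rs_analogs"].mean(),
            "r_analog_pairs": table["r_analog_pairs"].mean(),
            "rs_origin_ratio": table["r_rs_analogs"].mean()
                               / table["r_origin_analogs"].mean(),
        })
    return pd.DataFrame(rows)
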