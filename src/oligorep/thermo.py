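"""Mismatch-gated nearest-neighbor duplex thermodynamics.

The free energy of a duplex between two equal-length strands aligned
antiparallel, end-to-end and ungapped is modelled as the sum of
dinucleotide stacking contributions dH - T*dS, counted only over adjacent
positions where *both* base pairs are Watson-Crick.  A stack containing a
mismatch contributes nothing, and no initiation, terminal or salt
corrections are applied.  The model is deliberately simple: its purpose is
to rank the whole 4**N candidate space of complements cheaply, not to
predict absolute melting behaviour.

Because every stacking term in the bundled unified table is stabilizing
(dG < 0 at physiological temperature), the model has two useful global
properties: every duplex free energy is <= 0, and for a fixed target the
unique minimizer over all candidates is the perfect reverse complement.

Parameters are loaded from a TSV table (``step``, ``dH_kcal_mol``,
``dS_cal_molK``); the bundled default is the SantaLucia 1998 unified set.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from .sequences import BASES, COMPLEMENT, base_indices, clean_sequence

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT = 1.987e-3

#: Default reporting temperature of the unified parameter set (37 C).
DEFAULT_TEMPERATURE = 310.15

#: Largest strand length enumerated exhaustively without an explicit override.
MAX_EXHAUSTIVE_LENGTH = 10

_ALL_STEPS = tuple(x + y for x in BASES for y in BASES)


@dataclass(frozen=True)
class ThermoConfig:
    """Temperature and gas constant used for dG and binding constants."""

    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.gas_constant <= 0:
            raise ValueError("gas constant must be positive")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor stacking parameters for all 16 Watson-Crick stacks.

    ``steps`` maps each dimer step (read 5'->3' on the target strand, paired
    with its antiparallel complement) to ``(dH kcal/mol, dS cal/(mol*K))``.
    """

    steps: Mapping[str, Tuple[float, float]]
    source_label: str = "unspecified"

    def __post_init__(self) -> None:
        missing = set(_ALL_STEPS) - set(self.steps)
        if missing:
            raise ValueError(f"missing NN steps: {sorted(missing)}")
        for step, (dh, ds) in self.steps.items():
            if dh >= 0 or ds >= 0:
                raise ValueError(
                    f"step {step}: stacking requires dH < 0 and dS < 0, "
                    f"got ({dh}, {ds})")

    def delta_g(self, step: str, temperature: float = DEFAULT_TEMPERATURE) -> float:
        """Free energy of one stack, dH - T*dS, in kcal/mol (dS in cal)."""
        dh, ds = self.steps[step]
        return dh - temperature * ds * 1e-3

    def stack_free_energies(self, temperature: float = DEFAULT_TEMPERATURE) -> dict:
        return {s: self.delta_g(s, temperature) for s in _ALL_STEPS}


def load_nn_table(path) -> NNParameterSet:
    """Read an NN parameter table from TSV (columns: step, dH_kcal_mol, dS_cal_molK)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"step", "dH_kcal_mol", "dS_cal_molK"}
    if not required <= set(df.columns):
        raise ValueError(f"NN table needs columns {sorted(required)}")
    steps = {
        str(row.step).upper(): (float(row.dH_kcal_mol), float(row.dS_cal_molK))
        for row in df.itertuples()
    }
    return NNParameterSet(steps=steps, source_label=str(path))


@functools.lru_cache(maxsize=1)
def default_parameters() -> NNParameterSet:
    """The bundled unified NN stacking table (SantaLucia 1998, 1 M NaCl)."""
    ref = resources.files("oligorep").joinpath("data/nn_unified.tsv")
    with resources.as_file(ref) as path:
        params = load_nn_table(path)
    return NNParameterSet(steps=params.steps,
                          source_label="SantaLucia 1998 unified NN set")


def duplex_delta_g(target: str, candidate: str,
                   params: NNParameterSet | None = None,
                   cfg: ThermoConfig | None = None) -> float:
    """Duplex free energy (kcal/mol) of ``target`` against ``candidate``.

    Both strands are 5'->3'; the candidate is aligned antiparallel so that
    target position ``i`` pairs with candidate position ``N-1-i``.  Only
    stacks whose two base pairs are both Watson-Crick contribute.
    """
    params = params or default_parameters()
    cfg = cfg or ThermoConfig()
    t = clean_sequence(target)
    c = clean_sequence(candidate)
    n = len(t)
    if len(c) != n:
        raise ValueError(f"length mismatch: {n} vs {len(c)}")
    wc = [c[n - 1 - i] == COMPLEMENT[t[i]] for i in range(n)]
    dg = 0.0
    for i in range(n - 1):
        if wc[i] and wc[i + 1]:
            dg += params.delta_g(t[i:i + 2], cfg.temperature)
    return dg


def delta_g_profile(target: str,
                    params: NNParameterSet | None = None,
                    cfg: ThermoConfig | None = None,
                    *, allow_large: bool = False) -> np.ndarray:
    """Duplex dG of ``target`` against every candidate of the same length.

    Returns a vector of length ``4**N`` indexed by candidate code (base-4,
    A=0/C=1/G=2/T=3, most-significant base first, candidate read 5'->3'; see
    :func:`oligorep.candidates.encode`).  Deterministic: repeated calls are
    bit-identical.

    The stack between target positions ``i`` and ``i+1`` contributes to
    exactly the candidates whose bases at positions ``N-1-i`` and ``N-2-i``
    are the Watson-Crick partners of the target bases, so the profile is
    accumulated by slice-assignment on a ``(4,)*N`` array and flattened in
    C order.
    """
    params = params or default_parameters()
    cfg = cfg or ThermoConfig()
    t = clean_sequence(target)
    n = len(t)
    if n > MAX_EXHAUSTIVE_LENGTH and not allow_large:
        raise ValueError(
            f"exhaustive enumeration of 4**{n} candidates refused; "
            f"pass allow_large=True to override (lengths above "
            f"{MAX_EXHAUSTIVE_LENGTH} are memory-hungry)")
    ti = base_indices(t)
    prof = np.zeros((4,) * n)
    for i in range(n - 1):
        g = params.delta_g(t[i:i + 2], cfg.temperature)
        key: list = [slice(None)] * n
        key[n - 1 - i] = 3 - ti[i]        # WC partner of target base i
        key[n - 2 - i] = 3 - ti[i + 1]    # WC partner of target base i+1
        prof[tuple(key)] += g
    return prof.reshape(-1)
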