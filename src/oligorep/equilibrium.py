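"""Competitive mass-action equilibrium of one shared complement strand.

A single candidate strand (total concentration ``C``) binds ``n`` analog
strands (totals ``A_i``) with binding constants ``K_i``; duplexes
``x_i`` satisfy

    x_i = K_i * (A_i - x_i) * c_f,      c_f = C - sum_i x_i,

where ``c_f`` is the free candidate.  Substituting the mass-action relation
into the candidate balance gives a scalar equation in ``c_f``:

    g(c_f) = c_f + sum_i A_i K_i c_f / (1 + K_i c_f) - C = 0,

with ``g`` strictly increasing on (0, C), so the physical root is unique
and bracketed.  For two analogs this is the intersection, inside the
physical box 0 <= x_i <= min(A_i, C), of the two mass-action hyperbolae in
the (x_1, x_2) plane.

Concentrations are dimensionless "units" throughout (nominally 1 unit =
1 uM) and binding constants are exp(-dG/RT) applied to those numbers
directly; the default candidate total is the summed analog total, so the
perfect-hybridization coordinate (1, ..., 1) in yield space is reachable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .sequences import clean_sequence, wc_complement
from .thermo import NNParameterSet, ThermoConfig, duplex_delta_g


def binding_constant(delta_g, cfg: ThermoConfig | None = None):
    """K = exp(-dG / RT); strictly decreasing in dG, K(0) = 1.  Vectorized."""
    cfg = cfg or ThermoConfig()
    return np.exp(-np.asarray(delta_g, dtype=float) / cfg.rt)


@dataclass(frozen=True)
class ReactionSystem:
    """Totals and binding constants for one shared candidate vs n analogs."""

    analog_totals: np.ndarray
    binding_constants: np.ndarray
    candidate_total: float | None = None

    def __post_init__(self) -> None:
        totals = np.asarray(self.analog_totals, dtype=float)
        ks = np.asarray(self.binding_constants, dtype=float)
        if totals.ndim != 1 or ks.shape != totals.shape:
            raise ValueError("analog_totals and binding_constants must be "
                             "1-D arrays of equal length")
        if np.any(totals < 0):
            raise ValueError("analog totals must be non-negative")
        if np.any(ks <= 0):
            raise ValueError("binding constants must be positive")
        object.__setattr__(self, "analog_totals", totals)
        object.__setattr__(self, "binding_constants", ks)
        ctot = self.candidate_total
        if ctot is None:
            ctot = float(totals.sum())
        if ctot <= 0:
            raise ValueError("candidate total must be positive")
        object.__setattr__(self, "candidate_total", float(ctot))


@dataclass(frozen=True)
class EquilibriumState:
    """Solved duplex concentrations and hybridization yields."""

    system: ReactionSystem
    duplex: np.ndarray          # x_i, same units as the totals
    free_analog: np.ndarray
    free_candidate: float
    yields: np.ndarray          # x_i / A_i, in [0, 1] (0 for dropped analogs)


def _g(cf: float, totals: np.ndarray, ks: np.ndarray, ctot: float) -> float:
    return cf + float(np.sum(totals * ks * cf / (1.0 + ks * cf))) - ctot


def solve_competition(system: ReactionSystem, *, gtol: float = 1e-14,
                      maxiter: int = 200) -> EquilibriumState:
    """Solve the competition equilibrium for one candidate strand.

    Bracketed root-finding (Brent) on ``g`` over (0, C], polished with
    Newton steps until ``|g| <= gtol`` (or machine precision allows).
    Analogs with zero total are dropped with a warning and reported with
    zero duplex and zero yield.
    """
    totals_all = system.analog_totals
    active = totals_all > 0
    if not np.all(active):
        warnings.warn("dropping analog(s) with zero concentration",
                      stacklevel=2)
    totals = totals_all[active]
    ks = system.binding_constants[active]
    ctot = system.candidate_total
    if totals.size == 0:
        cf = ctot
    else:
        cf = brentq(_g, 0.0, ctot, args=(totals, ks, ctot),
                    xtol=1e-300, rtol=4 * np.finfo(float).eps,
                    maxiter=maxiter)
        # Newton polish: g is smooth and strictly increasing.
        for _ in range(3):
            g = _g(cf, totals, ks, ctot)
            if abs(g) <= gtol:
                break
            dg = 1.0 + float(np.sum(totals * ks / (1.0 + ks * cf) ** 2))
            step = g / dg
            if not np.isfinite(step) or abs(step) >= cf:
                break
            cf -= step
        if abs(_g(cf, totals, ks, ctot)) > max(gtol, 1e-9 * ctot):
            raise RuntimeError(
                f"equilibrium solver failed to converge: residual "
                f"{_g(cf, totals, ks, ctot):.3e} at c_f={cf:.6e}")
    ks_all = system.binding_constants
    frac = ks_all * cf / (1.0 + ks_all * cf)
    duplex = np.where(active, totals_all * frac, 0.0)
    yields = np.where(active, frac, 0.0)
    return EquilibriumState(system=system, duplex=duplex,
                            free_analog=totals_all - duplex,
                            free_candidate=float(cf), yields=yields)


def total_yield(state: EquilibriumState) -> float:
    """Sum of per-analog hybridization yields; in [0, n]."""
    return float(np.sum(state.yields))


def shortfall(state: EquilibriumState) -> np.ndarray:
    """Per-analog unbound amount A_i - x_i (distance from perfect binding)."""
    return state.system.analog_totals - state.duplex


def solve_free_candidate_batch(ks: np.ndarray, totals: np.ndarray,
                               ctot, *, iterations: int = 80) -> np.ndarray:
    """Free-candidate roots for many candidate strands against one analog set.

    ``ks`` has shape (m, n): binding constants of m candidates against the
    same n analogs (totals shape (n,)).  Vectorized bisection on the
    strictly increasing balance function; 80 halvings of (0, C] reach the
    floating-point resolution of the bracket.
    """
    ks = np.asarray(ks, dtype=float)
    totals = np.asarray(totals, dtype=float)
    m = ks.shape[0]
    ctot = np.broadcast_to(np.asarray(ctot, dtype=float), (m,)).copy()
    lo = np.zeros(m)
    hi = ctot.copy()
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        kc = ks * mid[:, None]
        g = mid + np.sum(totals * kc / (1.0 + kc), axis=1) - ctot
        pos = g >= 0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
    return 0.5 * (lo + hi)


def competition_yields(ks: np.ndarray, totals: np.ndarray, ctot) -> np.ndarray:
    """Per-analog yields, shape (m, n), for a batch of candidate strands."""
    cf = solve_free_candidate_batch(ks, totals, ctot)
    kc = np.asarray(ks, dtype=float) * cf[:, None]
    return kc / (1.0 + kc)


def concentration_sweep(analogs: Sequence[str], candidates: dict,
                        grid: Sequence[Sequence[float]],
                        params: NNParameterSet | None = None,
                        cfg: ThermoConfig | None = None,
                        *, candidate_total: float | None = None) -> pd.DataFrame:
    """Yields of named candidate strands while analog concentrations vary.

    ``grid`` is a list of per-analog concentration tuples sharing one fixed
    sum (e.g. (0, 2), (0.2, 1.8), ..., (2, 0)); the candidate total defaults
    to that fixed sum.  Returns a tidy table with one row per grid point and
    candidate: concentrations, per-analog yields and the total yield.
    """
    seqs = [clean_sequence(s) for s in analogs]
    cfg = cfg or ThermoConfig()
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.ndim != 2 or grid_arr.shape[1] != len(seqs):
        raise ValueError("grid rows must match the number of analogs")
    sums = grid_arr.sum(axis=1)
    if not np.allclose(sums, sums[0], rtol=1e-9, atol=1e-12):
        raise ValueError("grid must keep the summed analog concentration fixed")
    ctot = candidate_total if candidate_total is not None else float(sums[0])
    rows = []
    for cand_id, cand_seq in candidates.items():
        dg = np.array([duplex_delta_g(a, cand_seq, params, cfg) for a in seqs])
        ks = binding_constant(dg, cfg)
        for point in grid_arr:
            system = ReactionSystem(analog_totals=point,
                                    binding_constants=ks,
                                    candidate_total=ctot)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                state = solve_competition(system)
            row = {f"c{i + 1}": point[i] for i in range(len(seqs))}
            row["candidate_id"] = cand_id
            for i, y in enumerate(state.yields):
                row[f"yield_{i + 1}"] = y
            row["total_yield"] = total_yield(state)
            rows.append(row)
    return pd.DataFrame(rows)
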