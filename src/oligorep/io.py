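"""FASTA / TSV input, result reports and sociogram export.

Sequences come in as FASTA (unique record names) with an optional sidecar
TSV of per-strand concentrations (``name<TAB>concentration_uM``); results
go out as TSV tables plus a JSON run summary that echoes the full
configuration, so every output can be regenerated from its own header.
The sociogram is a bipartite graph linking each input strand to its top-k
lowest-dG candidate complements, written as GraphML (Cytoscape-importable)
and SIF; no layout is computed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .candidates import top_k
from .representative import AnalogMember, AnalogSet, RepresentativeResult
from .sequences import SequenceError, clean_sequence
from .thermo import (DEFAULT_TEMPERATURE, NNParameterSet, ThermoConfig,
                     delta_g_profile)


@dataclass
class RunConfig:
    """Run parameters echoed into every output header."""

    temperature: float = DEFAULT_TEMPERATURE
    pool_size: int = 1000
    closeness_k: int = 1000
    default_concentration: float = 1.0
    seed: int | None = None
    max_exhaustive_length: int = 10
    out_dir: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def thermo(self) -> ThermoConfig:
        return ThermoConfig(temperature=self.temperature)


def read_sequences(fasta_path, concentrations_path=None,
                   *, default_concentration: float = 1.0) -> AnalogSet:
    """Load an analog set from FASTA plus an optional concentration TSV.

    Record names must be unique; lowercase bases are uppercased with a
    warning; the TSV (columns ``name``, ``concentration_uM``, no header
    required) must cover every record when given.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {fasta_path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SequenceError(f"duplicate record names: {dupes}")
    concs = {}
    if concentrations_path is not None:
        table = pd.read_csv(concentrations_path, sep="\t", header=None,
                            comment="#", names=["name", "concentration_uM"])
        concs = dict(zip(table["name"].astype(str),
                         table["concentration_uM"].astype(float)))
        missing = [n for n in names if n not in concs]
        if missing:
            raise SequenceError(f"no concentration for record(s): {missing}")
    members = []
    for rec in records:
        raw = str(rec.seq)
        if raw != raw.upper():
            warnings.warn(f"{rec.id}: lowercase bases uppercased")
        members.append(AnalogMember(
            name=rec.id, sequence=clean_sequence(raw),
            concentration=concs.get(rec.id, default_concentration)))
    return AnalogSet(members=tuple(members))


def write_sequences(analogs: AnalogSet, fasta_path,
                    concentrations_path=None) -> None:
    """Write an analog set back out as FASTA (+ optional concentration TSV)."""
    with open(fasta_path, "w") as fh:
        for m in analogs.members:
            fh.write(f">{m.name}\n{m.sequence}\n")
    if concentrations_path is not None:
        with open(concentrations_path, "w") as fh:
            for m in analogs.members:
                fh.write(f"{m.name}\t{m.concentration:.10g}\n")


def _config_header(config: RunConfig | None) -> str:
    if config is None:
        return ""
    items = "  ".join(f"{k}={v}" for k, v in config.to_dict().items())
    return f"# config: {items}\n"


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """TSV dump with the run configuration echoed as a comment header."""
    with open(path, "w") as fh:
        fh.write(_config_header(config))
        df.to_csv(fh, sep="\t", index=False)


def write_results(result: RepresentativeResult, path,
                  config: RunConfig | None = None) -> None:
    """JSON run summary: CS, RS, concentration, yields and merge tree."""
    payload = {
        "config": config.to_dict() if config is not None else None,
        "cs": result.cs,
        "rs": result.rs,
        "rs_concentration": result.rs_concentration,
        "analog_names": list(result.analog_names),
        "per_analog_yield": [float(y) for y in result.per_analog_yield],
        "total_yield": result.total_yield,
        "merge_tree": [
            {"merged": list(s.merged), "closeness": s.closeness,
             "cs": s.cs, "rs": s.rs,
             "rs_concentration": s.rs_concentration,
             "pair_total_yield": s.pair_total_yield}
            for s in result.merge_tree
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def build_sociogram(members: Sequence[AnalogMember] | AnalogSet, k: int = 100,
                    params: NNParameterSet | None = None,
                    cfg: ThermoConfig | None = None) -> nx.Graph:
    """Bipartite graph of strands vs their top-k candidate complements.

    Strand nodes carry ``kind="sequence"``; candidate nodes (named by their
    sequence) carry ``kind="candidate"`` and ``shared=True`` when linked to
    two or more strands.  Edge attribute ``delta_g`` is the duplex dG.
    """
    if isinstance(members, AnalogSet):
        members = members.members
    g = nx.Graph()
    for m in members:
        g.add_node(m.name, kind="sequence", sequence=m.sequence)
        prof = delta_g_profile(m.sequence, params, cfg)
        ranking = top_k(prof, k, length=len(m.sequence))
        for seq, dg in zip(ranking.sequences(), ranking.scores):
            node = f"c:{seq}"
            if not g.has_node(node):
                g.add_node(node, kind="candidate", sequence=seq, shared=False)
            g.add_edge(m.name, node, delta_g=float(dg))
    for node, data in g.nodes(data=True):
        if data["kind"] == "candidate" and g.degree(node) >= 2:
            data["shared"] = True
    return g


def export_sociogram(members, base_path, k: int = 100,
                     params: NNParameterSet | None = None,
                     cfg: ThermoConfig | None = None) -> nx.Graph:
    """Write the sociogram as ``<base>.graphml`` and ``<base>.sif``."""
    g = build_sociogram(members, k, params, cfg)
    base = Path(base_path)
    nx.write_graphml(g, base.with_suffix(".graphml"))
    with open(base.with_suffix(".sif"), "w") as fh:
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\thybridizes\t{v}\n")
    return g
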