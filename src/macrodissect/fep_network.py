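"""Relative binding free energy network bookkeeping and diagnostics.

An alchemical relative free energy calculation produces, for each pair of
ligands (an *edge*), a ΔΔG for the transformation run in the protein complex
and in bulk solvent; the binding free energy difference of the edge is
``ΔΔG_bind = ΔΔG_complex - ΔΔG_solvent``.  Edges may be run at several
restraint force constants (the restraint holds ligand and protein backbone
near the bound reference) and forward/backward, giving two convergence
diagnostics:

* *hysteresis*: forward ΔΔG + backward ΔΔG of one edge (0 when converged);
* *cycle closure*: signed ΔΔG sum around any closed thermodynamic cycle
  (0 for a consistent network).

Node (per-ligand) free energies relative to a chosen reference ligand are
estimated by least squares over all binding edges, and converted to ΔpKd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .thermo import DEFAULT_TEMPERATURE, ddg_to_dpkd

__all__ = [
    "FepEdge",
    "FepNetwork",
    "combine_legs",
    "build_network",
    "edge_hysteresis",
    "cycle_closure",
    "relative_dpkd",
    "restraint_sensitivity",
    "read_edge_table",
    "write_edge_table",
]


@dataclass
class FepEdge:
    """One alchemical transformation leg between two ligands.

    ``ddG`` in kcal/mol; ``force_constant`` in kcal mol^-1 Å^-2 (0 = no
    restraint); ``ddG_reverse`` is the backward transformation when run.
    """

    ligand_from: str
    ligand_to: str
    leg: str  # "complex" or "solvent"
    ddG: float
    ddG_reverse: float | None = None
    force_constant: float = 0.0
    sim_time_ns: float | None = None

    def __post_init__(self) -> None:
        if self.ligand_from == self.ligand_to:
            raise ValueError(f"self-edge on ligand {self.ligand_from!r}")
        if self.leg not in ("complex", "solvent"):
            raise ValueError(f"leg must be 'complex' or 'solvent', got {self.leg!r}")


@dataclass
class FepNetwork:
    """Ligands as nodes, binding ΔΔG values as directed edges, with one
    ligand pinned as the reference for relative estimates."""

    nodes: list[str]
    binding_edges: list[tuple[str, str, float]]  # (from, to, ddG_bind kcal/mol)
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.nodes:
            raise ValueError(f"reference {self.reference!r} is not a network node")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, _ in self.binding_edges:
            g.add_edge(u, v)
        return g


def combine_legs(complex_ddg: float | None, solvent_ddg: float | None) -> float:
    """Binding ΔΔG of one edge from its two legs:
    ΔΔG_bind = ΔΔG_complex - ΔΔG_solvent."""
    if complex_ddg is None or solvent_ddg is None:
        raise ValueError("both complex and solvent legs are required")
    return complex_ddg - solvent_ddg


def build_network(
    edges: Iterable[FepEdge],
    reference: str,
    force_constant: float | None = None,
) -> FepNetwork:
    """Assemble a binding network from per-leg edges.

    Legs are paired by (ligand_from, ligand_to, force_constant); an edge
    missing either leg raises and names the pair.  When ``force_constant`` is
    given only edges at that restraint level are used.
    """
    legs: dict[tuple[str, str, float], dict[str, float]] = {}
    for e in edges:
        if force_constant is not None and e.force_constant != force_constant:
            continue
        key = (e.ligand_from, e.ligand_to, e.force_constant)
        legs.setdefault(key, {})[e.leg] = e.ddG
    binding = []
    nodes: set[str] = set()
    for (u, v, _fc), by_leg in sorted(legs.items()):
        if "complex" not in by_leg or "solvent" not in by_leg:
            missing = {"complex", "solvent"} - set(by_leg)
            raise ValueError(f"edge {u}->{v}: missing {sorted(missing)} leg(s)")
        binding.append((u, v, combine_legs(by_leg["complex"], by_leg["solvent"])))
        nodes.update((u, v))
    nodes.add(reference)
    return FepNetwork(nodes=sorted(nodes), binding_edges=binding, reference=reference)


def edge_hysteresis(edge: FepEdge) -> float | None:
    """Forward/backward convergence gap of one leg: ddG + ddG_reverse
    (zero for perfectly converged transformations).  ``None`` when no
    backward run exists."""
    if edge.ddG_reverse is None:
        return None
    return edge.ddG + edge.ddG_reverse


def cycle_closure(network: FepNetwork) -> dict:
    """Signed ΔΔG sum around each independent cycle of the network.

    Cycles come from a cycle basis of the undirected graph; traversing an
    edge against its stored direction contributes ``-ΔΔG``.  Returns per-cycle
    closure errors (kcal/mol) and their RMS; an acyclic network yields an
    empty result.  Parallel edges between one pair are averaged first.
    """
    ddg: dict[tuple[str, str], list[float]] = {}
    for u, v, g in network.binding_edges:
        key = (min(u, v), max(u, v))
        sign = 1.0 if (u, v) == key else -1.0
        ddg.setdefault(key, []).append(sign * g)
    mean_ddg = {k: float(np.mean(vs)) for k, vs in ddg.items()}
    g = nx.Graph(list(mean_ddg))
    cycles = nx.cycle_basis(g)
    closures = []
    for cycle in cycles:
        total = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            key = (min(a, b), max(a, b))
            total += mean_ddg[key] if (a, b) == key else -mean_ddg[key]
        closures.append({"cycle": list(cycle), "closure_kcal_mol": total})
    rms = float(np.sqrt(np.mean([c["closure_kcal_mol"] ** 2 for c in closures]))) if closures else 0.0
    return {"cycles": closures, "rms_closure_kcal_mol": rms}


def relative_dpkd(
    network: FepNetwork, temperature: float = DEFAULT_TEMPERATURE
) -> dict[str, float]:
    """Per-ligand ΔpKd relative to the network reference.

    Node free energies solve the overdetermined system ``G(to) - G(from) =
    ΔΔG_bind`` by ordinary least squares with ``G(reference) = 0``; for a
    tree this reduces to exact path sums.  Nodes not connected to the
    reference are excluded with a warning.
    """
    g = network.graph()
    component = nx.node_connected_component(g, network.reference)
    excluded = sorted(set(network.nodes) - component)
    if excluded:
        warnings.warn(
            f"nodes not connected to reference {network.reference!r} excluded: {excluded}",
            stacklevel=2,
        )
    nodes = sorted(component)
    free = [n for n in nodes if n != network.reference]
    index = {n: i for i, n in enumerate(free)}
    edges = [(u, v, d) for u, v, d in network.binding_edges if u in component and v in component]
    a = np.zeros((len(edges), len(free)))
    b = np.zeros(len(edges))
    for row, (u, v, d) in enumerate(edges):
        if v != network.reference:
            a[row, index[v]] += 1.0
        if u != network.reference:
            a[row, index[u]] -= 1.0
        b[row] = d
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    node_g = {network.reference: 0.0, **{n: float(sol[index[n]]) for n in free}}
    return {n: ddg_to_dpkd(node_g[n], temperature) for n in nodes}


def restraint_sensitivity(
    tables: dict[float, dict[str, float]],
    flag_threshold: float = 0.5,
) -> pd.DataFrame:
    """Spread of ΔpKd estimates across restraint force constants.

    ``tables`` maps force constant -> {ligand -> ΔpKd}.  For every ligand
    present at >= 2 levels, reports the max-min spread, the standard
    deviation (ddof=1) over levels, and a flag when the spread exceeds
    ``flag_threshold`` (pKd units).  Restraint levels are metadata labels;
    no restraint debiasing is attempted.
    """
    if len(tables) < 2:
        raise ValueError("need at least two restraint levels to compare")
    ligands = sorted(set().union(*[set(t) for t in tables.values()]))
    rows = []
    for lig in ligands:
        vals = np.array([t[lig] for t in tables.values() if lig in t])
        if vals.size < 2:
            continue
        spread = float(vals.max() - vals.min())
        rows.append(
            {
                "ligand_id": lig,
                "n_levels": int(vals.size),
                "spread": spread,
                "std": float(np.std(vals, ddof=1)),
                "flagged": spread > flag_threshold,
            }
        )
    return pd.DataFrame(rows, columns=["ligand_id", "n_levels", "spread", "std", "flagged"])


# ---------------------------------------------------------------------------
# Tabular I/O

_EDGE_COLUMNS = [
    "ligand_from",
    "ligand_to",
    "leg",
    "ddG_kcal_mol",
    "ddG_reverse_kcal_mol",
    "force_constant",
]


def read_edge_table(path) -> list[FepEdge]:
    """Read per-leg edges from a TSV/CSV table with columns
    ligand_from, ligand_to, leg, ddG_kcal_mol[, ddG_reverse_kcal_mol,
    force_constant, sim_time_ns]."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"ligand_from", "ligand_to", "leg", "ddG_kcal_mol"} - set(df.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    edges = []
    for _, row in df.iterrows():
        rev = row.get("ddG_reverse_kcal_mol")
        edges.append(
            FepEdge(
                ligand_from=str(row["ligand_from"]),
                ligand_to=str(row["ligand_to"]),
                leg=str(row["leg"]),
                ddG=float(row["ddG_kcal_mol"]),
                ddG_reverse=None if rev is None or pd.isna(rev) else float(rev),
                force_constant=0.0
                if "force_constant" not in df.columns or pd.isna(row["force_constant"])
                else float(row["force_constant"]),
                sim_time_ns=None
                if "sim_time_ns" not in df.columns or pd.isna(row["sim_time_ns"])
                else float(row["sim_time_ns"]),
            )
        )
    return edges


def write_edge_table(edges: Sequence[FepEdge], path) -> None:
    """Write per-leg edges as a TSV with a header row."""
    rows = [
        {
            "ligand_from": e.ligand_from,
            "ligand_to": e.ligand_to,
            "leg": e.leg,
            "ddG_kcal_mol": e.ddG,
            "ddG_reverse_kcal_mol": e.ddG_reverse,
            "force_constant": e.force_constant,
        }
        for e in edges
    ]
    pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
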