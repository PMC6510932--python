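"""Weighted per-group per-phase contact networks and per-animal metrics.

Each (group, phase) cell yields one undirected weighted network whose nodes
are the group's animals and whose edges carry two weights per dyad: the
number of contact bouts (``freq``) and the total contact seconds (``dur``).
From the resident-only network four per-animal response metrics are derived:

* ``degree`` — weighted degree, the animal's total number of contacts in the
  phase (row sum of the frequency matrix, counting bouts, not partners);
* ``freq_per_day`` — contacts per day, degree / days in phase;
* ``total_dur_per_day`` — contact seconds per day;
* ``mean_dur`` — mean seconds per contact bout (total seconds / bout count),
  0 for an animal with no contacts.

``total_dur_per_day = freq_per_day × mean_dur`` holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .contact_log import StudyDesign, ValidationError

METRIC_COLUMNS = ["animal", "group_id", "phase",
                  "freq_per_day", "mean_dur", "total_dur_per_day", "degree"]
METRIC_NAMES = ("freq_per_day", "mean_dur", "total_dur_per_day", "degree")

GRAPH_FORMATS = ("graphml", "edgelist_csv", "adjacency_csv")


@dataclass
class GroupPhaseNetwork:
    """One group's contact network in one phase.

    ``freq_matrix`` (integer bout counts) and ``dur_matrix`` (total contact
    seconds) are symmetric with zero diagonal, indexed by ``nodes``; ``roles``
    maps each node to ``resident`` or ``unfamiliar``.
    """

    group_id: str
    phase: str
    nodes: tuple[str, ...]
    roles: dict[str, str]
    freq_matrix: np.ndarray
    dur_matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.nodes)
        for m in (self.freq_matrix, self.dur_matrix):
            if m.shape != (n, n):
                raise ValueError("matrix shape does not match node count")
            if not np.allclose(m, m.T):
                raise ValueError("adjacency matrices must be symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError("diagonal must be zero")
        if np.any((self.freq_matrix == 0) != (self.dur_matrix == 0)):
            raise ValueError("freq and dur matrices must share a sparsity pattern")

    @property
    def n_bouts(self) -> int:
        return int(self.freq_matrix.sum() // 2)

    def to_graph(self) -> nx.Graph:
        """NetworkX view with ``role`` node attributes and ``freq``/``dur`` edge weights."""
        g = nx.Graph(group_id=self.group_id, phase=self.phase)
        for node in self.nodes:
            g.add_node(node, role=self.roles[node])
        idx = np.triu_indices(len(self.nodes), k=1)
        for i, j in zip(*idx):
            if self.freq_matrix[i, j] > 0:
                g.add_edge(self.nodes[i], self.nodes[j],
                           freq=int(self.freq_matrix[i, j]),
                           dur=float(self.dur_matrix[i, j]))
        return g

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "GroupPhaseNetwork":
        nodes = tuple(sorted(g.nodes))
        roles = {n: g.nodes[n].get("role", "resident") for n in nodes}
        n = len(nodes)
        pos = {a: i for i, a in enumerate(nodes)}
        freq = np.zeros((n, n), dtype=np.int64)
        dur = np.zeros((n, n), dtype=float)
        for u, v, d in g.edges(data=True):
            i, j = pos[u], pos[v]
            freq[i, j] = freq[j, i] = int(d["freq"])
            dur[i, j] = dur[j, i] = float(d["dur"])
        return cls(str(g.graph.get("group_id", "")), str(g.graph.get("phase", "")),
                   nodes, roles, freq, dur)


def build_networks(bouts: pd.DataFrame, roster: pd.DataFrame, design: StudyDesign,
                   restrict: str = "residents_only") -> dict[tuple[str, str], GroupPhaseNetwork]:
    """Aggregate phase-assigned bouts into one network per (group, phase).

    ``restrict="residents_only"`` drops dyads involving the unfamiliar animal
    (the analysed metrics use resident–resident contacts only);
    ``restrict="all"`` keeps every roster animal, as in the network figures.
    Every (group, phase) cell is returned, empty networks included.
    """
    if restrict not in ("residents_only", "all"):
        raise ValueError(f"unknown restrict mode {restrict!r}")
    roster_animals = set(roster["animal_id"])
    in_bouts = set(bouts["animal_a"]) | set(bouts["animal_b"])
    missing = in_bouts - roster_animals
    if missing:
        raise ValidationError(f"animals in bouts but not in roster: {sorted(missing)[:5]}")

    networks: dict[tuple[str, str], GroupPhaseNetwork] = {}
    for group_id, group_roster in roster.groupby("group_id", sort=True):
        if restrict == "residents_only":
            group_roster = group_roster[group_roster["role"] == "resident"]
        nodes = tuple(sorted(group_roster["animal_id"]))
        roles = dict(zip(group_roster["animal_id"], group_roster["role"]))
        pos = {a: i for i, a in enumerate(nodes)}
        gb = bouts[bouts["group_id"] == group_id]
        for phase in design.phase_labels:
            sel = gb[(gb["phase"] == phase)
                     & gb["animal_a"].isin(pos) & gb["animal_b"].isin(pos)]
            n = len(nodes)
            freq = np.zeros((n, n), dtype=np.int64)
            dur = np.zeros((n, n), dtype=float)
            if len(sel):
                i = sel["animal_a"].map(pos).to_numpy()
                j = sel["animal_b"].map(pos).to_numpy()
                seconds = (sel["end_s"] - sel["start_s"]).to_numpy()
                np.add.at(freq, (i, j), 1)
                np.add.at(dur, (i, j), seconds)
                freq += freq.T
                dur += dur.T
            networks[(str(group_id), phase)] = GroupPhaseNetwork(
                str(group_id), phase, nodes, roles, freq, dur)
    return networks


def animal_metrics(network: GroupPhaseNetwork, days_per_phase: float) -> pd.DataFrame:
    """Per-animal response metrics from one (group, phase) network.

    Computed for resident animals; expects a network built with
    ``restrict="residents_only"``.
    """
    if days_per_phase <= 0:
        raise ValueError("days_per_phase must be > 0")
    rows = []
    deg = network.freq_matrix.sum(axis=1)
    tot = network.dur_matrix.sum(axis=1)
    for i, animal in enumerate(network.nodes):
        if network.roles[animal] != "resident":
            continue
        degree = float(deg[i])
        mean_dur = float(tot[i] / deg[i]) if deg[i] > 0 else 0.0
        rows.append({
            "animal": animal,
            "group_id": network.group_id,
            "phase": network.phase,
            "freq_per_day": degree / days_per_phase,
            "mean_dur": mean_dur,
            "total_dur_per_day": float(tot[i]) / days_per_phase,
            "degree": degree,
        })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def metrics_table(networks: dict[tuple[str, str], GroupPhaseNetwork],
                  design: StudyDesign) -> pd.DataFrame:
    """Stack :func:`animal_metrics` over all (group, phase) networks."""
    frames = [animal_metrics(net, design.phase_of(phase).n_days)
              for (_, phase), net in sorted(networks.items())]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=METRIC_COLUMNS)
    return out.sort_values(["group_id", "animal", "phase"], kind="mergesort").reset_index(drop=True)


def export_graph(network: GroupPhaseNetwork, path, fmt: str = "graphml") -> None:
    """Write a network to disk.

    Formats: ``graphml`` (self-contained, exact round trip via
    :func:`import_graph`); ``edgelist_csv`` (columns
    ``animal_a,animal_b,freq,total_dur_s``); ``adjacency_csv`` (two labelled
    matrix CSVs, ``<path>`` for frequency with a sibling ``.dur.csv`` for
    duration).
    """
    path = str(path)
    if fmt == "graphml":
        nx.write_graphml(network.to_graph(), path)
    elif fmt == "edgelist_csv":
        idx = np.triu_indices(len(network.nodes), k=1)
        rows = [(network.nodes[i], network.nodes[j],
                 int(network.freq_matrix[i, j]), float(network.dur_matrix[i, j]))
                for i, j in zip(*idx) if network.freq_matrix[i, j] > 0]
        pd.DataFrame(rows, columns=["animal_a", "animal_b", "freq", "total_dur_s"]) \
            .to_csv(path, index=False)
    elif fmt == "adjacency_csv":
        labels = list(network.nodes)
        pd.DataFrame(network.freq_matrix, index=labels, columns=labels).to_csv(path)
        pd.DataFrame(network.dur_matrix, index=labels, columns=labels) \
            .to_csv(path + ".dur.csv")
    else:
        raise ValueError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")


def import_graph(path, fmt: str = "graphml",
                 nodes: tuple[str, ...] | None = None,
                 roles: dict[str, str] | None = None) -> GroupPhaseNetwork:
    """Read a network written by :func:`export_graph`.

    The CSV formats do not carry isolated nodes or roles, so ``nodes`` (and
    optionally ``roles``) must be supplied for them; GraphML is self-contained.
    """
    path = str(path)
    if fmt == "graphml":
        return GroupPhaseNetwork.from_graph(nx.read_graphml(path))
    if nodes is None:
        raise ValueError(f"{fmt} import requires the node list")
    roles = roles or {n: "resident" for n in nodes}
    pos = {a: i for i, a in enumerate(nodes)}
    n = len(nodes)
    freq = np.zeros((n, n), dtype=np.int64)
    dur = np.zeros((n, n), dtype=float)
    if fmt == "edgelist_csv":
        edges = pd.read_csv(path, dtype={"animal_a": str, "animal_b": str})
        for _, r in edges.iterrows():
            i, j = pos[r["animal_a"]], pos[r["animal_b"]]
            freq[i, j] = freq[j, i] = int(r["freq"])
            dur[i, j] = dur[j, i] = float(r["total_dur_s"])
    elif fmt == "adjacency_csv":
        f = pd.read_csv(path, index_col=0)
        d = pd.read_csv(path + ".dur.csv", index_col=0)
        freq = f.loc[list(nodes), list(nodes)].to_numpy(dtype=np.int64)
        dur = d.loc[list(nodes), list(nodes)].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")
    return GroupPhaseNetwork("", "", tuple(nodes), roles, freq, dur)
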