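"""The undirected landmark graph used by the MRF-based refiners.

The graph encodes anatomical plausibility for a 37-landmark hand: per-finger
bone chains, a wrist/carpal chain, attachments from the carpal row to the
metacarpophalangeal (MCP) joints, and "rung" edges between corresponding
joints of adjacent fingers. A fixed set of *global* landmarks (wrist pair,
MCP row, fingertips) is additionally a message source for every landmark, so
an occluded region can still be placed from the global hand structure.

The default topology is a convention, not anatomical ground truth; any
dataset can override it with a plain-text edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

#: 1-based indices: wrist pair, MCP joints, fingertips.
DEFAULT_GLOBAL_SET = frozenset({2, 6, 14, 15, 16, 17, 18, 21, 25, 29, 33, 37})

#: Finger chains from MCP joint to fingertip, 1-based (thumb has 4 joints).
FINGER_CHAINS: tuple[tuple[int, ...], ...] = (
    (14, 19, 20, 21),           # thumb
    (15, 22, 23, 24, 25),       # index
    (16, 26, 27, 28, 29),       # middle
    (17, 30, 31, 32, 33),       # ring
    (18, 34, 35, 36, 37),       # little
)


@dataclass(frozen=True)
class Topology:
    """Undirected landmark graph with a fixed global-landmark set.

    ``local_neighborhood(i)`` is the set of direct graph neighbours; the
    extended neighbourhood ``neighbors(i)`` additionally contains every
    global landmark except ``i`` itself (no self-messages).
    """

    n_landmarks: int
    edges: frozenset[frozenset[int]]
    global_set: frozenset[int]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not all(1 <= i <= self.n_landmarks for i in e):
                raise ValueError(f"edge {sorted(e)} out of range 1..{self.n_landmarks}")
        if not self.global_set <= set(range(1, self.n_landmarks + 1)):
            raise ValueError("global set contains out-of-range indices")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(1, self.n_landmarks + 1))
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def local_neighborhood(self, i: int) -> set[int]:
        return {next(iter(e - {i})) for e in self.edges if i in e}

    def neighbors(self, i: int) -> set[int]:
        """Extended neighbourhood LN_i ∪ GN, excluding i."""
        return (self.local_neighborhood(i) | set(self.global_set)) - {i}

    def message_pairs(self) -> list[tuple[int, int]]:
        """All ordered (receiver i, sender j in N_i) pairs, deterministic order."""
        return [(i, j) for i in range(1, self.n_landmarks + 1)
                for j in sorted(self.neighbors(i))]

    def validate(self) -> list[str]:
        """Diagnostics: disconnected components, isolated vertices."""
        issues = []
        g = self.graph()
        comps = list(nx.connected_components(g))
        if len(comps) > 1:
            issues.append(f"graph has {len(comps)} connected components")
        for v in nx.isolates(g):
            issues.append(f"landmark {v} has no edges")
        return issues


def default_hand_topology() -> Topology:
    """The shipped 37-landmark hand graph.

    Vertices 1..13 are wrist/carpal landmarks chained in index order (with
    the wrist pair 2-6 connected through the chain), 14..18 the MCP row,
    and the finger chains run MCP -> fingertip. Cross-finger rungs connect
    corresponding joints of adjacent fingers.
    """
    edges: set[tuple[int, int]] = set()

    def add(a: int, b: int) -> None:
        edges.add((min(a, b), max(a, b)))

    # carpal chain 1..13 plus the direct wrist edge 2-6
    for k in range(1, 13):
        add(k, k + 1)
    add(2, 6)
    # attach the carpal row to each MCP joint and chain the MCP row
    for k, mcp in zip((9, 10, 11, 12, 13), (14, 15, 16, 17, 18)):
        add(k, mcp)
    for mcp in (14, 15, 16, 17):
        add(mcp, mcp + 1)
    # finger chains
    for chain in FINGER_CHAINS:
        for a, b in zip(chain, chain[1:]):
            add(a, b)
    # rungs between corresponding joints of adjacent fingers; the thumb is
    # one joint short, so align chains from the MCP side
    for ca, cb in zip(FINGER_CHAINS, FINGER_CHAINS[1:]):
        for a, b in zip(ca[1:], cb[1:]):
            add(a, b)
    return Topology(
        n_landmarks=37,
        edges=frozenset(frozenset(e) for e in edges),
        global_set=DEFAULT_GLOBAL_SET,
    )


def save_topology(t: Topology, path: str | Path) -> None:
    """Plain-text format: "i j" per line (1-based), plus "global: ..." and
    "n: ..." header lines."""
    lines = [f"n: {t.n_landmarks}", "global: " + " ".join(map(str, sorted(t.global_set)))]
    lines += [f"{a} {b}" for a, b in sorted(tuple(sorted(e)) for e in t.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def topology_to_json(t: Topology) -> str:
    import json

    return json.dumps({
        "n_landmarks": t.n_landmarks,
        "edges": sorted(sorted(e) for e in t.edges),
        "global": sorted(t.global_set),
    })


def topology_from_json(s: str) -> Topology:
    import json

    d = json.loads(s)
    return Topology(
        n_landmarks=int(d["n_landmarks"]),
        edges=frozenset(frozenset(e) for e in d["edges"]),
        global_set=frozenset(d["global"]),
    )


def load_topology(path: str | Path) -> Topology:
    """Parse and validate an edge-list file (see :func:`save_topology`)."""
    n = 37
    global_set: set[int] = set()
    edges: set[frozenset[int]] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        try:
            if line.startswith("n:"):
                n = int(line[2:])
            elif line.startswith("global:"):
                global_set = {int(tok) for tok in line[7:].split()}
            else:
                a, b = (int(tok) for tok in line.split())
                if a == b:
                    raise ValueError("self-loop")
                edges.add(frozenset((a, b)))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed line {raw!r}: {exc}") from exc
    return Topology(n_landmarks=n, edges=frozenset(edges), global_set=frozenset(global_set))
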