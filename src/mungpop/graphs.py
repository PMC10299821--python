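"""Admixture graphs with Balding–Nichols drift parameters.

A rooted acyclic graph describes a population history: each drift edge
``parent -> child`` carries a parameter ``c`` in [0, 1), the variance
proportion of one Balding–Nichols drift step (child allele frequency is
Beta-distributed with mean p_parent and variance c * p * (1 - p)).  An
admixture node instead mixes two source nodes with weight ``alpha``:
p_child = alpha * p_A + (1 - alpha) * p_B.

The same object serves as simulation ground truth and as the analytic
oracle for f-statistic expectations (shared-drift path overlaps).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["AdmixtureGraph", "chain_graph", "star_graph"]


@dataclass
class AdmixtureGraph:
    """Rooted admixture graph over population labels.

    Parameters
    ----------
    root : str
        Label of the root node.
    edges : dict
        ``child -> (parent, c)`` for drift edges, with c in [0, 1).
    admixtures : dict
        ``child -> (source_a, source_b, alpha)`` with alpha in [0, 1];
        the child frequency is ``alpha * p_a + (1 - alpha) * p_b``.
    leaves : list of str
        Nodes that map to sampled populations.
    root_freq : (float, float)
        Bounds of the uniform distribution the ancestral allele
        frequency is drawn from.
    """

    root: str
    edges: dict[str, tuple[str, float]] = field(default_factory=dict)
    admixtures: dict[str, tuple[str, str, float]] = field(default_factory=dict)
    leaves: list[str] = field(default_factory=list)
    root_freq: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def nodes(self) -> list[str]:
        out = {self.root}
        for child, (parent, _) in self.edges.items():
            out.add(child)
            out.add(parent)
        for child, (a, b, _) in self.admixtures.items():
            out.update((child, a, b))
        return sorted(out)

    def parents(self, node: str) -> tuple[str, ...]:
        if node in self.edges:
            return (self.edges[node][0],)
        if node in self.admixtures:
            return self.admixtures[node][:2]
        return ()

    def validate(self) -> None:
        dup = set(self.edges) & set(self.admixtures)
        if dup:
            raise ValueError(f"nodes with both drift and admixture parents: {dup}")
        if self.root in self.edges or self.root in self.admixtures:
            raise ValueError("root must not have a parent")
        for child, (parent, c) in self.edges.items():
            if not 0.0 <= c < 1.0:
                raise ValueError(f"drift c for {parent}->{child} out of [0,1): {c}")
        for child, (a, b, alpha) in self.admixtures.items():
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"admixture weight for {child} out of [0,1]: {alpha}")
        lo, hi = self.root_freq
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid root frequency bounds {self.root_freq}")
        order = self.topological_order()  # raises on cycles
        missing = set(self.leaves) - set(order)
        if missing:
            raise ValueError(f"leaves not in graph: {missing}")

    def topological_order(self) -> list[str]:
        """Parents-before-children ordering; raises ValueError on a cycle."""
        nodes = self.nodes()
        indeg = {n: len(self.parents(n)) for n in nodes}
        children: dict[str, list[str]] = {n: [] for n in nodes}
        for child in nodes:
            for p in self.parents(child):
                children[p].append(child)
        ready = sorted(n for n in nodes if indeg[n] == 0)
        if ready != [self.root]:
            raise ValueError(f"graph must have the root as unique source, got {ready}")
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for ch in sorted(children[n]):
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    ready.append(ch)
            ready.sort()
        if len(order) != len(nodes):
            raise ValueError("graph contains a cycle")
        return order

    # ------------------------------------------------------------------
    # Analytic expectations (tree part only; used as test oracles).
    def path_to_root(self, node: str) -> list[str]:
        """Drift-edge path from ``node`` up to the root.

        Defined only when no admixture node lies on the ancestry path.
        """
        path = [node]
        while path[-1] != self.root:
            cur = path[-1]
            if cur in self.admixtures:
                raise ValueError(
                    f"ancestry of {node!r} passes through admixture node {cur!r}"
                )
            path.append(self.edges[cur][0])
        return path

    def expected_het_factor(self, node: str) -> float:
        """prod(1 - c) along the root path: E[p(1-p)] at node / E[p(1-p)] at root."""
        fac = 1.0
        for n in self.path_to_root(node)[:-1]:
            fac *= 1.0 - self.edges[n][1]
        return fac

    def root_het(self) -> float:
        """E[p(1-p)] under the uniform root frequency distribution."""
        lo, hi = self.root_freq
        if hi == lo:
            return lo * (1 - lo)
        # E[p] - E[p^2] for p ~ U(lo, hi)
        ep = 0.5 * (lo + hi)
        ep2 = (hi**3 - lo**3) / (3.0 * (hi - lo))
        return ep - ep2

    def expected_f2(self, a: str, b: str) -> float:
        """E[f2(a, b)] = sum of drift variances along the path joining a and b.

        Valid for admixture-free graphs: each drift edge parent->child with
        parameter c contributes c * E[p(1-p) at parent].
        """
        pa, pb = self.path_to_root(a), self.path_to_root(b)
        shared = set(pa) & set(pb)
        h0 = self.root_het()
        total = 0.0
        for path in (pa, pb):
            for n in path:
                if n in shared:
                    break
                parent, c = self.edges[n]
                total += c * h0 * self.expected_het_factor(parent)
        return total

    def expected_f3(self, target: str, a: str, b: str) -> float:
        """E[f3(target; a, b)] from f2 path sums (admixture-free graphs)."""
        return 0.5 * (
            self.expected_f2(target, a)
            + self.expected_f2(target, b)
            - self.expected_f2(a, b)
        )

    def expected_f4(self, a: str, b: str, c: str, d: str) -> float:
        """E[f4(a, b; c, d)] from f2 path sums (admixture-free graphs)."""
        return 0.5 * (
            self.expected_f2(a, d)
            + self.expected_f2(b, c)
            - self.expected_f2(a, c)
            - self.expected_f2(b, d)
        )

    # ------------------------------------------------------------------
    def to_json(self, path: str) -> None:
        spec = {
            "root": self.root,
            "edges": {ch: [p, c] for ch, (p, c) in self.edges.items()},
            "admixtures": {ch: [a, b, w] for ch, (a, b, w) in self.admixtures.items()},
            "leaves": self.leaves,
            "root_freq": list(self.root_freq),
        }
        with open(path, "w") as fh:
            json.dump(spec, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "AdmixtureGraph":
        with open(path) as fh:
            spec = json.load(fh)
        return cls(
            root=spec["root"],
            edges={ch: (p, float(c)) for ch, (p, c) in spec.get("edges", {}).items()},
            admixtures={
                ch: (a, b, float(w))
                for ch, (a, b, w) in spec.get("admixtures", {}).items()
            },
            leaves=list(spec.get("leaves", [])),
            root_freq=tuple(spec.get("root_freq", (0.1, 0.9))),
        )


def chain_graph(
    labels: list[str],
    drifts: list[float],
    root: str = "root",
    root_freq: tuple[float, float] = (0.1, 0.9),
) -> AdmixtureGraph:
    """Serial-founder chain: root -> labels[0] -> labels[1] -> ...

    ``drifts[i]`` is the Balding–Nichols c on the edge into ``labels[i]``.
    Emulates a stepping-stone colonization with diversity lost at each step.
    """
    if len(labels) != len(drifts):
        raise ValueError("labels and drifts must have equal length")
    edges = {}
    prev = root
    for lab, c in zip(labels, drifts):
        edges[lab] = (prev, c)
        prev = lab
    return AdmixtureGraph(root=root, edges=edges, leaves=list(labels), root_freq=root_freq)


def star_graph(
    labels: list[str],
    drifts: list[float],
    root: str = "root",
    root_freq: tuple[float, float] = (0.1, 0.9),
) -> AdmixtureGraph:
    """Simultaneous radiation: every label splits directly from the root."""
    if len(labels) != len(drifts):
        raise ValueError("labels and drifts must have equal length")
    edges = {lab: (root, c) for lab, c in zip(labels, drifts)}
    return AdmixtureGraph(root=root, edges=edges, leaves=list(labels), root_freq=root_freq)
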