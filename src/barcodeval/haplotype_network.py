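"""Haplotype collapsing and minimum-spanning networks.

Aligned sequences are collapsed to haplotypes under one of two
gap-handling modes: ``missing`` ignores columns where either sequence has
a gap or N; ``fifth_state`` treats the gap character as a fifth state
(so an indel difference is a mutation step) while N is always missing.
Haplotypes sharing members of more than one species are flagged: such
shared haplotypes are the signature of incomplete lineage sorting or
hybridisation among sibling species. The network is the minimum spanning
tree over the complete graph of pairwise mutation-step counts, with
deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .distances import MISSING, seq_to_ints

GAP_STATE = 4  # internal code for '-' under fifth_state semantics


@dataclass
class Haplotype:
    haplotype_id: str
    sequence: str  # representative: the first member's sequence
    members: list[str]
    species_set: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def shared(self) -> bool:
        """True if members come from more than one species."""
        return len(self.species_set) > 1


@dataclass
class HaplotypeNetwork:
    haplotypes: list[Haplotype]
    edges: list[tuple[str, str, int]]  # (hap_id, hap_id, mutation steps)
    gap_mode: str

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for h in self.haplotypes:
            g.add_node(h.haplotype_id, size=h.size,
                       species=sorted(h.species_set), shared=h.shared)
        for u, v, w in self.edges:
            g.add_edge(u, v, steps=w)
        return g

    def to_dot(self) -> str:
        lines = ["graph haplotypes {"]
        for h in self.haplotypes:
            label = f"{h.haplotype_id}\\nn={h.size}"
            shape = "doublecircle" if h.shared else "circle"
            lines.append(f'  "{h.haplotype_id}" [label="{label}", shape={shape}];')
        for u, v, w in self.edges:
            lines.append(f'  "{u}" -- "{v}" [label="{w}"];')
        lines.append("}")
        return "\n".join(lines)


def _encode(seq: str, gap_mode: str) -> np.ndarray:
    enc = seq_to_ints(seq).copy()
    if gap_mode == "fifth_state":
        gaps = np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord("-")
        enc[gaps] = GAP_STATE
    elif gap_mode != "missing":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    return enc


def step_count(seq_a: str, seq_b: str, gap_mode: str = "missing") -> int:
    """Number of mutation steps between two aligned sequences.

    Columns where either sequence is missing (N always; '-' too under
    ``missing`` mode) are skipped; under ``fifth_state`` a gap versus a
    base, or a gap versus N-free mismatch, counts as one step.
    """
    a, b = _encode(seq_a, gap_mode), _encode(seq_b, gap_mode)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal aligned length")
    ok = (a != MISSING) & (b != MISSING)
    return int(((a != b) & ok).sum())


def collapse_haplotypes(alignment, labels, gap_mode: str = "missing") -> list[Haplotype]:
    """Collapse an alignment into haplotypes.

    Two sequences share a haplotype iff their pairwise step count is zero
    under the chosen gap mode. Because missing data makes zero-distance
    non-transitive, grouping is by connected components of the
    zero-difference relation (union-find). Haplotypes are numbered H1,
    H2, ... in order of first appearance; the representative sequence is
    the first member's.

    ``labels`` maps specimen_id -> species (dict) or is a list aligned
    with the alignment rows.
    """
    ids = alignment.specimen_ids
    if isinstance(labels, dict):
        lab = [labels[i] for i in ids]
    else:
        lab = list(labels)
    enc = np.vstack([_encode(seq, gap_mode) for _, seq in alignment.rows])
    n = len(ids)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    valid = enc != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            if not ((enc[i] != enc[j]) & ok).any():
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    haps = []
    for k, root in enumerate(sorted(groups, key=lambda r: min(groups[r]))):
        members = sorted(groups[root])
        haps.append(
            Haplotype(
                haplotype_id=f"H{k + 1}",
                sequence=alignment.rows[members[0]][1],
                members=[ids[i] for i in members],
                species_set={lab[i] for i in members},
            )
        )
    return haps


def build_network(haplotypes: list[Haplotype], gap_mode: str = "missing") -> HaplotypeNetwork:
    """Minimum spanning tree over the complete mutation-step graph.

    Kruskal with edges sorted by (steps, lexicographic haplotype-id
    pair), so the result is deterministic under ties. Step counts are
    computed between representative sequences. With a single haplotype
    the network has no edges.
    """
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    by_id = {h.haplotype_id: h for h in haplotypes}
    hap_ids = list(by_id)
    edges = []
    for i, u in enumerate(hap_ids):
        for v in hap_ids[i + 1:]:
            w = step_count(by_id[u].sequence, by_id[v].sequence, gap_mode)
            a, b = sorted((u, v))
            edges.append((w, a, b))
    edges.sort()

    parent = {h: h for h in hap_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = []
    for w, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            mst.append((u, v, w))
            if len(mst) == len(hap_ids) - 1:
                break
    return HaplotypeNetwork(haplotypes=haplotypes, edges=mst, gap_mode=gap_mode)


def export_tsv(network: HaplotypeNetwork, nodes_path, edges_path) -> None:
    """Write the network as two TSVs (nodes with species breakdown; edges)."""
    import pandas as pd

    node_rows = [
        {"id": h.haplotype_id, "size": h.size,
         "species": ";".join(sorted(h.species_set)), "shared": int(h.shared)}
        for h in network.haplotypes
    ]
    pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(
        [{"from": u, "to": v, "steps": w} for u, v, w in network.edges]
    ).to_csv(edges_path, sep="\t", index=False)
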