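"""Haplotype collapsing and tree-derived haplotype networks.

The network is derived from the fixed haplogroup tree (the Fitchi
philosophy: a network drawn from a tree, with multi-mutation edges
subdivided by inferred intermediate haplotypes) rather than median-joining.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .io import MitoAlignment, VALID_BASES
from .haplotree import HaplogroupTree, classify

logger = logging.getLogger("liontree")


@dataclass
class Haplotype:
    hap_id: str
    sequence: str  # consensus over members (missing filled from observed)
    members: list[str]
    populations: Counter = field(default_factory=Counter)

    @property
    def count(self) -> int:
        return len(self.members)


def _compatible(a: str, b: str) -> bool:
    return all(
        x == y or x not in VALID_BASES or y not in VALID_BASES for x, y in zip(a, b)
    )


def _merge_seq(a: str, b: str) -> str:
    return "".join(x if x in VALID_BASES else y for x, y in zip(a, b))


def collapse_haplotypes(
    aln: MitoAlignment, populations: dict[str, str] | None = None
) -> list[Haplotype]:
    """Merge sequences identical over mutually callable positions.

    Sequences are processed in alignment order and merged into the first
    compatible haplotype (N/'-' match anything); a merge that relied on
    missing data is logged.  Each haplotype carries per-population counts.
    Returned sorted by descending count, then by first-member order.
    """
    populations = populations or {}
    haps: list[Haplotype] = []
    for seq_id, seq in zip(aln.ids, aln.seqs):
        placed = False
        for hap in haps:
            if _compatible(hap.sequence, seq):
                if any(
                    x not in VALID_BASES or y not in VALID_BASES
                    for x, y in zip(hap.sequence, seq)
                    if x != y
                ):
                    logger.info("merge of %s into %s used missing positions",
                                seq_id, hap.hap_id)
                hap.sequence = _merge_seq(hap.sequence, seq)
                hap.members.append(seq_id)
                hap.populations[populations.get(seq_id, "unknown")] += 1
                placed = True
                break
        if not placed:
            hap = Haplotype(f"H{len(haps) + 1}", seq, [seq_id])
            hap.populations[populations.get(seq_id, "unknown")] += 1
            haps.append(hap)
    order = {h.hap_id: k for k, h in enumerate(haps)}
    return sorted(haps, key=lambda h: (-h.count, order[h.hap_id]))


def hamming(a: str, b: str) -> int:
    """Differences over mutually callable positions."""
    return sum(
        1 for x, y in zip(a, b) if x in VALID_BASES and y in VALID_BASES and x != y
    )


def build_network(
    haplotypes: list[Haplotype],
    tree: HaplogroupTree,
    aln_ref: MitoAlignment,
) -> nx.Graph:
    """Fitchi-style haplotype network on the haplogroup tree backbone.

    Every sampled haplotype is classified and placed on its haplogroup's
    node; haplogroup nodes without samples become inferred nodes (count 0).
    Edge weights are mutation counts; edges carrying k>1 mutations are
    subdivided by k-1 inferred median nodes so that every drawn edge is a
    single mutational step times its weight of 1.
    """
    G = nx.Graph()
    placement: dict[str, list[Haplotype]] = {n: [] for n in tree.nodes}
    for hap in haplotypes:
        res = classify(hap.hap_id, hap.sequence, tree, aln_ref)
        placement[res.haplogroup].append(hap)

    node_profile: dict[str, str] = {}
    ref = aln_ref.ref_seq
    for name in tree.nodes:
        expected = tree.expected_states(name)
        seq = list(ref)
        for col in range(aln_ref.length):
            if aln_ref.insertion_ordinal[col] != 0:
                continue
            pos = aln_ref.positions[col]
            if pos in expected:
                seq[col] = expected[pos][1]
        node_profile[name] = "".join(seq)

    # haplogroup nodes joined by zero-mutation branches share one haplotype:
    # union them so empty branches never become fake single-step edges
    group_of: dict[str, str] = {}
    for name in tree.preorder():
        parent = tree.nodes[name][0]
        if parent is not None and hamming(node_profile[parent], node_profile[name]) == 0:
            group_of[name] = group_of.get(parent, parent)
        else:
            group_of[name] = name

    members: dict[str, list[str]] = {}
    for name in tree.preorder():
        members.setdefault(group_of[name], []).append(name)

    def add_hap_node(node_id, hap: Haplotype | None, haplogroup: str):
        if hap is None:
            G.add_node(node_id, kind="inferred", count=0, haplogroup=haplogroup,
                       populations="")
        else:
            pops = ";".join(f"{p}:{c}" for p, c in sorted(hap.populations.items()))
            G.add_node(node_id, kind="sampled", count=hap.count,
                       haplogroup=haplogroup, populations=pops,
                       members=",".join(hap.members))

    # one anchor per union group: its first sampled haplotype, else inferred
    anchor: dict[str, str] = {}
    anchor_seq: dict[str, str] = {}
    extras: dict[str, list[Haplotype]] = {}
    for rep, names in members.items():
        placed = [h for n in names for h in placement[n]]
        if placed:
            anchor[rep] = placed[0].hap_id
            anchor_seq[rep] = placed[0].sequence
            add_hap_node(placed[0].hap_id, placed[0], rep)
            extras[rep] = placed[1:]
            for extra in placed[1:]:
                add_hap_node(extra.hap_id, extra, rep)
        else:
            anchor[rep] = f"[{rep}]"
            anchor_seq[rep] = node_profile[rep]
            add_hap_node(f"[{rep}]", None, rep)
            extras[rep] = []

    def connect(u: str, v: str, k: int):
        """Join u and v with k-1 inferred intermediates (k>=1)."""
        k = max(k, 1)
        prev = u
        for step in range(1, k):
            mid = f"{u}~{v}~{step}"
            G.add_node(mid, kind="inferred", count=0, haplogroup="", populations="")
            G.add_edge(prev, mid, mutations=1)
            prev = mid
        G.add_edge(prev, v, mutations=1)

    for name in tree.preorder():
        parent = tree.nodes[name][0]
        if parent is None or group_of[name] == group_of[parent]:
            continue
        rep_p, rep_c = group_of[parent], group_of[name]
        connect(anchor[rep_p], anchor[rep_c],
                hamming(node_profile[parent], node_profile[name]))
    for rep, hs in extras.items():
        for extra in hs:
            connect(anchor[rep], extra.hap_id, hamming(anchor_seq[rep], extra.sequence))
    return G


def path_mutations(G: nx.Graph, u: str, v: str) -> int:
    """Total mutation count along the network path between two nodes."""
    path = nx.shortest_path(G, u, v, weight="mutations")
    return sum(G.edges[a, b]["mutations"] for a, b in zip(path, path[1:]))


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, str(path))


def write_dot(G: nx.Graph, path) -> None:
    """Minimal DOT export (no pydot dependency)."""
    with open(path, "w") as fh:
        fh.write("graph haplotype_network {\n")
        for n, data in G.nodes(data=True):
            label = f"{n} (n={data.get('count', 0)})"
            shape = "circle" if data.get("kind") == "sampled" else "point"
            fh.write(f'  "{n}" [label="{label}", shape={shape}];\n')
        for u, v, data in G.edges(data=True):
            fh.write(f'  "{u}" -- "{v}" [label="{data.get("mutations", 1)}"];\n')
        fh.write("}\n")
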