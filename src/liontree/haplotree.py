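"""Haplogroup trees with branch-defining mutations.

A haplogroup is a clade of mitochondrial haplotypes defined by the derived
substitutions accumulated on its root-ward path.  The tree topology is
nomenclature, not inference: the hierarchy (A1 inside A, etc.) is an input,
and maximum-parsimony (Fitch) reconstruction on per-haplogroup consensus
sequences places the defining mutations on its branches.  Standard names
follow the A–F (modern lion), S (cave lion), X (American cave lion) scheme.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

from .io import MitoAlignment, Mutation, VALID_BASES

logger = logging.getLogger("liontree")

STANDARD_NAME_RE = re.compile(r"^[A-FSX][0-9a-z]*$")

#: Penalty per private (observed-but-unexpected) mutation in classification.
PRIVATE_PENALTY = 0.5
#: Minimum fraction of tree-defining sites that must be callable in a query.
COVERAGE_FLOOR = 0.5


class InsufficientCoverageError(ValueError):
    pass


@dataclass
class HaplogroupTree:
    """Rooted tree: node name -> (parent name or None, defining mutations).

    Mutations on a branch are substitutions acquired on the edge from the
    parent haplogroup to the child.  A reversion toward the root state on a
    path is stored as a mutation with swapped ref/alt and ``back=True``;
    paths never silently repeat a mutation.
    """

    nodes: dict[str, tuple[str | None, list[Mutation]]]
    root: str
    nomenclature_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: list[tuple[str, str | None, list[Mutation]]]) -> "HaplogroupTree":
        nodes: dict[str, tuple[str | None, list[Mutation]]] = {}
        roots = []
        for name, parent, muts in rows:
            if name in nodes:
                raise ValueError(f"duplicate haplogroup name: {name}")
            nodes[name] = (parent, list(muts))
            if parent is None:
                roots.append(name)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        tree = cls(nodes=nodes, root=roots[0])
        tree.validate()
        return tree

    @classmethod
    def from_parent_map(cls, parent_map: dict[str, str | None]) -> "HaplogroupTree":
        return cls.from_rows([(n, p, []) for n, p in parent_map.items()])

    def validate(self) -> None:
        for name, (parent, _) in self.nodes.items():
            if parent is not None and parent not in self.nodes:
                raise ValueError(f"orphan parent {parent!r} for haplogroup {name}")
        # reachability from the root doubles as the cycle check
        seen = set(self.preorder())
        if seen != set(self.nodes):
            unreachable = sorted(set(self.nodes) - seen)
            raise ValueError(f"cycle or disconnected haplogroups: {unreachable}")
        for name in self.nodes:
            states: dict[int, str] = {}
            for mut in self.path_mutations(name):
                if not mut.back and states.get(mut.pos) == mut.alt:
                    raise ValueError(
                        f"mutation {mut.label()} repeated on path to {name} without back-flag"
                    )
                states[mut.pos] = mut.alt

    def children(self, name: str) -> list[str]:
        return [n for n, (p, _) in self.nodes.items() if p == name]

    def preorder(self) -> list[str]:
        order, stack, guard = [], [self.root], 0
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(sorted(self.children(node), reverse=True))
            guard += 1
            if guard > len(self.nodes):
                break
        return order

    def path(self, name: str) -> list[str]:
        """Node names from the root down to (and including) ``name``."""
        out, cur, guard = [], name, 0
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur][0]
            guard += 1
            if guard > len(self.nodes):
                raise ValueError("cycle in haplogroup tree")
        return out[::-1]

    def depth(self, name: str) -> int:
        return len(self.path(name)) - 1

    def path_mutations(self, name: str) -> list[Mutation]:
        muts: list[Mutation] = []
        for node in self.path(name):
            muts.extend(self.nodes[node][1])
        return muts

    def expected_states(self, name: str) -> dict[int, tuple[str, str]]:
        """Position -> (ancestral base, expected derived base) for a node.

        Applies path mutations in root->node order so a flagged back-mutation
        restores the earlier state; positions whose expected state returns to
        the root base are dropped (the query is expected to match reference).
        """
        states: dict[int, tuple[str, str]] = {}
        for mut in self.path_mutations(name):
            root_ref = states[mut.pos][0] if mut.pos in states else mut.ref
            states[mut.pos] = (root_ref, mut.alt)
        return {p: rv for p, rv in states.items() if rv[0] != rv[1]}

    def defining_positions(self) -> set[int]:
        return {m.pos for _, (_, muts) in self.nodes.items() for m in muts}

    def homoplasies(self) -> list[Mutation]:
        """Mutations (by position+states) assigned to more than one branch."""
        counts = Counter()
        for _, (_, muts) in self.nodes.items():
            for m in muts:
                counts[(m.pos, m.ref, m.alt)] += 1
        return [Mutation(p, r, a) for (p, r, a), c in counts.items() if c > 1]


@dataclass
class ClassificationResult:
    query_id: str
    haplogroup: str
    score: float
    matched: list[Mutation]
    missing: list[Mutation]
    private: list[Mutation]
    ties: list[str] = field(default_factory=list)


def group_consensus(aln: MitoAlignment, ids: list[str]) -> str:
    """Majority base per column within a group; ties and all-missing give N."""
    if not ids:
        raise ValueError("empty haplogroup sequence group")
    seqs = [aln.seq(i) for i in ids]
    out = []
    for col in range(aln.length):
        counts = Counter(s[col] for s in seqs if s[col] in VALID_BASES)
        if not counts:
            out.append("N")
            continue
        (top, n1), *rest = counts.most_common()
        out.append("N" if rest and rest[0][1] == n1 else top)
    return "".join(out)


def _fitch_up(tree: HaplogroupTree, leaf_states: dict[str, frozenset]) -> dict[str, frozenset]:
    full = frozenset(VALID_BASES)
    sets: dict[str, frozenset] = {}
    for name in reversed(tree.preorder()):
        child_sets = [sets[c] for c in tree.children(name)]
        if name in leaf_states:
            child_sets.append(leaf_states[name])
        if not child_sets:
            sets[name] = full
            continue
        inter = frozenset.intersection(*child_sets)
        sets[name] = inter if inter else frozenset.union(*child_sets)
    return sets


def _fitch_assign(tree: HaplogroupTree, sets: dict[str, frozenset], root_pref: str | None) -> dict[str, str]:
    assigned: dict[str, str] = {}
    for name in tree.preorder():
        options = sets[name]
        parent = tree.nodes[name][0]
        if parent is None:
            pick = root_pref if root_pref in options else min(options)
        else:
            pick = assigned[parent] if assigned[parent] in options else min(options)
        assigned[name] = pick
    return assigned


def extract_defining_mutations(
    aln: MitoAlignment,
    labels: dict[str, str],
    topology: HaplogroupTree | dict[str, str | None],
) -> tuple[HaplogroupTree, list[Mutation]]:
    """Place branch-defining mutations on a fixed haplogroup topology.

    Each haplogroup's sequences are collapsed to a majority consensus
    (50/50 ties -> N, excluding the site from that group's evidence), and
    per-column Fitch parsimony over the topology assigns a substitution to
    the branch where parent and child reconstructed states differ.  The same
    derived change appearing on two branches is kept on both and returned in
    the homoplasy report.

    Returns ``(tree_with_mutations, homoplasy_report)``.
    """
    if isinstance(topology, dict):
        topology = HaplogroupTree.from_parent_map(topology)
    groups: dict[str, list[str]] = {}
    for seq_id, hg in labels.items():
        if hg not in topology.nodes:
            raise ValueError(f"label {hg!r} absent from topology")
        groups.setdefault(hg, []).append(seq_id)
    consensus = {hg: group_consensus(aln, sorted(ids)) for hg, ids in groups.items()}
    ref = aln.ref_seq if aln.ref_id is not None else consensus.get(
        topology.root, next(iter(consensus.values()))
    )

    branch_muts: dict[str, list[Mutation]] = {n: [] for n in topology.nodes}
    for col in range(aln.length):
        if aln.insertion_ordinal[col] != 0:
            continue  # indels carry no mutation notation
        observed = {
            hg: seq[col] for hg, seq in consensus.items() if seq[col] in VALID_BASES
        }
        if len(set(observed.values()) | {ref[col]}) <= 1:
            continue
        leaf_states = {hg: frozenset(b) for hg, b in observed.items()}
        sets = _fitch_up(topology, leaf_states)
        root_pref = ref[col] if ref[col] in VALID_BASES else None
        assigned = _fitch_assign(topology, sets, root_pref)
        pos = aln.position_of(col)
        root_state = assigned[topology.root]
        for name in topology.preorder():
            parent = topology.nodes[name][0]
            if parent is None or assigned[parent] == assigned[name]:
                continue
            is_back = assigned[name] == root_state and assigned[parent] != root_state
            branch_muts[name].append(
                Mutation(pos, assigned[parent], assigned[name], back=is_back)
            )

    nodes = {
        name: (topology.nodes[name][0], branch_muts[name]) for name in topology.nodes
    }
    tree = HaplogroupTree(nodes=nodes, root=topology.root,
                          nomenclature_map=dict(topology.nomenclature_map))
    report = tree.homoplasies()
    if report:
        logger.info("homoplasy report: %s", ", ".join(m.label() for m in report))
    return tree, report


def _query_states(query: str, aln_ref: MitoAlignment) -> dict[int, str]:
    """Map 1-based reference position -> query base over callable columns."""
    if len(query) != aln_ref.length:
        raise ValueError("query must be aligned to reference coordinates")
    ref = aln_ref.ref_seq
    states = {}
    for col, base in enumerate(query):
        if aln_ref.insertion_ordinal[col] != 0:
            continue
        if base in VALID_BASES and ref[col] in VALID_BASES:
            states[aln_ref.positions[col]] = base
    return states


def classify(
    query_id: str,
    query: str,
    tree: HaplogroupTree,
    aln_ref: MitoAlignment,
    alpha: float = PRIVATE_PENALTY,
    coverage_floor: float = COVERAGE_FLOOR,
) -> ClassificationResult:
    """Assign an aligned query sequence to its best haplogroup.

    For each node the score is ``(matched - alpha*private) / expected``
    over callable positions (clipped to [0,1]; a node with no expected
    mutations — the root — uses denominator 1 so a reference-identical
    query scores 1 there).  Ties break toward the deeper node, then
    lexicographically.  N and '-' in the query are missing data: they are
    neither matches nor mismatches.
    """
    qstates = _query_states(query, aln_ref)
    defining = tree.defining_positions()
    if defining:
        callable_frac = sum(1 for p in defining if p in qstates) / len(defining)
        if callable_frac < coverage_floor:
            raise InsufficientCoverageError(
                f"insufficient coverage: {callable_frac:.0%} of tree-defining "
                f"sites callable in {query_id} (floor {coverage_floor:.0%})"
            )
    ref = aln_ref.ref_seq
    ref_at = {
        aln_ref.positions[c]: ref[c]
        for c in range(aln_ref.length)
        if aln_ref.insertion_ordinal[c] == 0 and ref[c] in VALID_BASES
    }
    query_muts = {
        pos: base for pos, base in qstates.items() if base != ref_at.get(pos, base)
    }

    scored: list[tuple[float, int, str]] = []
    details: dict[str, tuple[list[Mutation], list[Mutation], list[Mutation]]] = {}
    for name in tree.nodes:
        expected = tree.expected_states(name)
        matched, missing = [], []
        for pos, (anc, derived) in expected.items():
            if pos not in qstates:
                continue  # not callable — excluded from both sets
            if qstates[pos] == derived:
                matched.append(Mutation(pos, anc, derived))
            else:
                missing.append(Mutation(pos, anc, derived))
        private = [
            Mutation(pos, ref_at[pos], base)
            for pos, base in sorted(query_muts.items())
            if pos not in expected or qstates[pos] != expected[pos][1]
        ]
        n_expected_callable = len(matched) + len(missing)
        if n_expected_callable == 0:
            # no expected mutations callable (the root, typically): a clean
            # query matches perfectly, each private costs alpha
            score = 1.0 - alpha * len(private)
        else:
            score = (len(matched) - alpha * len(private)) / n_expected_callable
        score = min(1.0, max(0.0, score))
        scored.append((score, tree.depth(name), name))
        details[name] = (matched, missing, private)

    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best_score, _, best = scored[0]
    ties = [n for s, d, n in scored[1:] if s == best_score and d == scored[0][1]]
    matched, missing, private = details[best]
    return ClassificationResult(
        query_id=query_id,
        haplogroup=best,
        score=best_score,
        matched=sorted(matched, key=lambda m: m.pos),
        missing=sorted(missing, key=lambda m: m.pos),
        private=sorted(private, key=lambda m: m.pos),
        ties=ties,
    )


def convert_nomenclature(label: str, mapping: dict[str, str]) -> str:
    """Map a legacy haplogroup label to the standard A–F/S/X nomenclature."""
    if label in mapping:
        label = mapping[label]
    if not STANDARD_NAME_RE.match(label):
        raise ValueError(f"unknown haplogroup label: {label!r}")
    return label


def impute_partial(
    partial: str,
    haplogroup: str,
    tree: HaplogroupTree,
    aln_ref: MitoAlignment,
) -> tuple[str, list[str]]:
    """Reconstruct a full-length sequence from a partial one.

    Missing positions (N or '-') take the reference base, except positions
    carrying a root->haplogroup defining mutation, which take the derived
    base.  Observed positions are never changed; an observed base that
    contradicts a defining mutation is retained with a warning.

    Returns ``(sequence, flags)`` with per-column flags observed|imputed.
    """
    if haplogroup not in tree.nodes:
        raise ValueError(f"unknown haplogroup: {haplogroup}")
    if len(partial) != aln_ref.length:
        raise ValueError("partial sequence must be aligned to reference coordinates")
    expected = tree.expected_states(haplogroup)
    ref = aln_ref.ref_seq
    out, flags = [], []
    for col, base in enumerate(partial):
        pos = aln_ref.positions[col]
        inserted = aln_ref.insertion_ordinal[col] != 0
        if base in VALID_BASES:
            if not inserted and pos in expected and base != expected[pos][1]:
                logger.warning(
                    "observed %s at %d conflicts with defining %s%d%s; keeping observed",
                    base, pos, expected[pos][0], pos, expected[pos][1],
                )
            out.append(base)
            flags.append("observed")
        else:
            fill = expected[pos][1] if not inserted and pos in expected else ref[col]
            out.append(fill if fill in VALID_BASES else "N")
            flags.append("imputed")
    return "".join(out), flags
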