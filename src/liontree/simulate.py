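"""Synthetic data with known truth for every pipeline stage.

Mitogenome fragments evolve on an ultrametric (strict-clock) haplogroup
tree under an HKY85 substitution process with discrete-gamma rate
heterogeneity plus a proportion of invariant sites.  Simulation is
counts-then-placement: each branch draws a Poisson number of substitutions
with mean rate x length x duration, then places them at sites proportional
to the per-site rate multipliers and picks target bases with HKY
transition/transversion bias.  Every event is recorded, so replaying the
per-branch substitution lists from the root reproduces each tip exactly
and homoplasy is observable.  Defaults mirror the cytb setting: 1040 sites
at 0.01797 substitutions/site/lineage/Myr.

SSR genotypes come from a Balding–Nichols model: per locus, population
allele frequencies are Dirichlet-distributed around a shared ancestral
frequency with concentration (1-F)/F, so the expected Weir–Cockerham theta
is close to F.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.stats import gamma as gamma_dist

from .io import (
    MitoAlignment,
    Mutation,
    write_annotation,
    write_fasta,
    write_genotypes,
    write_haplogroup_table,
    GeneAnnotation,
)
from .haplotree import HaplogroupTree
from .popgen import GenotypeMatrix

#: cytb defaults: locus length and calibrated rate (subs/site/lineage/Myr)
CYTB_LENGTH = 1040
CYTB_RATE = 0.01797
MITO_RATE = 0.01327

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimScenario:
    """Study conditions for a mitogenome simulation.

    newick branch lengths / node ages are in years; ``rate`` is per site
    per lineage per Myr.  kappa is the HKY transition/transversion rate
    ratio; gamma rate heterogeneity uses ``gamma_categories``
    equal-probability categories of shape ``gamma_shape``, and a fraction
    ``prop_invariant`` of sites never mutates.
    """

    newick: str
    rate: float = CYTB_RATE
    kappa: float = 2.0
    gamma_shape: float = 0.5
    gamma_categories: int = 8
    prop_invariant: float = 0.5
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    locus_length: int = CYTB_LENGTH
    samples_per_leaf: int = 1
    private_mutations: int = 0  # extra per-sample substitutions on tip branches
    sample_internal_nodes: bool = False  # also emit samples for internal haplogroups
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0 or self.locus_length <= 0:
            raise ValueError("rate must be >=0 and locus length positive")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")


@dataclass
class SimTruth:
    alignment: MitoAlignment
    reference: str
    true_haplogroup: dict[str, str]  # sequence id -> haplogroup
    branch_substitutions: dict[str, list[tuple[int, str, str]]]  # node -> (pos, from, to)
    sample_substitutions: dict[str, list[tuple[int, str, str]]]
    node_ages: dict[str, float]  # years
    tree: HaplogroupTree
    node_sequences: dict[str, str] = field(default_factory=dict)


def discrete_gamma_means(shape: float, k: int) -> np.ndarray:
    """Means of k equal-probability categories of a mean-1 gamma."""
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), shape, scale=1 / shape)
    upper = gamma_dist.cdf(edges[1:], shape + 1, scale=1 / shape)
    lower = gamma_dist.cdf(edges[:-1], shape + 1, scale=1 / shape)
    return k * (upper - lower)


def _parse_tree(newick: str):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    ages: dict[str, float] = {}
    parents: dict[str, str | None] = {}
    durations: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        name = node.taxon.label if node.taxon else node.label
        if name is None:
            raise ValueError("every tree node must be named")
        node._lt_name = name
        parent = node.parent_node
        parents[name] = parent._lt_name if parent is not None else None
        durations[name] = node.edge.length or 0.0
    # node ages from root depths; ultrametricity checked over leaves
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node._lt_name] = (depths[parent._lt_name] if parent else 0.0) + (
            node.edge.length or 0.0
        )
    leaf_depths = [depths[lf._lt_name] for lf in tree.leaf_node_iter()]
    height = max(leaf_depths)
    if max(leaf_depths) - min(leaf_depths) > 1e-6 * max(height, 1.0):
        raise ValueError("tree is not ultrametric (strict clock required)")
    ages = {n: height - d for n, d in depths.items()}
    return parents, durations, ages


def _hky_target(rng, current: str, kappa: float, freqs: dict[str, float]) -> str:
    others = [b for b in BASES if b != current]
    weights = np.array([
        kappa * freqs[b] if b == _TRANSITION[current] else freqs[b] for b in others
    ])
    return rng.choice(others, p=weights / weights.sum())


def simulate_mitogenomes(scenario: SimScenario) -> SimTruth:
    """Evolve sequences on the scenario tree; fully deterministic per seed."""
    rng = np.random.default_rng(scenario.seed)
    parents, durations, ages = _parse_tree(scenario.newick)
    L = scenario.locus_length
    freqs = dict(zip(BASES, scenario.base_freqs))

    # per-site rate multipliers, normalised to mean 1 so the expected
    # substitution count on a branch is exactly rate x L x t
    cat_means = discrete_gamma_means(scenario.gamma_shape, scenario.gamma_categories)
    mult = np.where(
        rng.random(L) < scenario.prop_invariant,
        0.0,
        cat_means[rng.integers(0, scenario.gamma_categories, size=L)],
    )
    if mult.sum() == 0:
        mult = np.ones(L)
    site_rates = mult / mult.mean()
    site_p = site_rates / site_rates.sum()

    root_name = next(n for n, p in parents.items() if p is None)
    root_seq = rng.choice(list(BASES), size=L, p=list(scenario.base_freqs))
    node_seq: dict[str, np.ndarray] = {root_name: root_seq}
    branch_subs: dict[str, list[tuple[int, str, str]]] = {n: [] for n in parents}

    order = [root_name]
    children = {}
    for n, p in parents.items():
        children.setdefault(p, []).append(n)
    stack = [root_name]
    order = []
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(sorted(children.get(n, []), reverse=True))

    def mutate(seq: np.ndarray, n_events: int, record: list) -> np.ndarray:
        seq = seq.copy()
        if n_events:
            sites = rng.choice(L, size=n_events, p=site_p)
            for site in sites:
                old = seq[site]
                new = _hky_target(rng, old, scenario.kappa, freqs)
                seq[site] = new
                record.append((int(site) + 1, old, new))  # 1-based positions
        return seq

    for name in order:
        parent = parents[name]
        if parent is None:
            continue
        t_myr = durations[name] / 1e6
        mean = scenario.rate * L * t_myr
        n_events = rng.poisson(mean)
        node_seq[name] = mutate(node_seq[parent], n_events, branch_subs[name])

    leaves = [n for n in parents if n not in children]
    sampled_nodes = sorted(parents) if scenario.sample_internal_nodes else sorted(leaves)
    ids, seqs = ["reference"], ["".join(root_seq)]
    true_hg: dict[str, str] = {}
    sample_subs: dict[str, list[tuple[int, str, str]]] = {}
    for leaf in sampled_nodes:
        for k in range(scenario.samples_per_leaf):
            sid = f"{leaf}_{k + 1}"
            record: list[tuple[int, str, str]] = []
            seq = mutate(node_seq[leaf], scenario.private_mutations, record)
            ids.append(sid)
            seqs.append("".join(seq))
            true_hg[sid] = leaf
            sample_subs[sid] = record

    aln = MitoAlignment(ids=ids, seqs=seqs, ref_id="reference")
    tree = HaplogroupTree(
        nodes={
            n: (
                parents[n],
                [Mutation(pos, a, b) for pos, a, b in _net_changes(branch_subs[n])],
            )
            for n in parents
        },
        root=root_name,
    )
    return SimTruth(
        alignment=aln,
        reference="".join(root_seq),
        true_haplogroup=true_hg,
        branch_substitutions=branch_subs,
        sample_substitutions=sample_subs,
        node_ages=ages,
        tree=tree,
        node_sequences={n: "".join(s) for n, s in node_seq.items()},
    )


def _net_changes(events: list[tuple[int, str, str]]) -> list[tuple[int, str, str]]:
    """Collapse multiple hits at a site on one branch to the net change."""
    state: dict[int, tuple[str, str]] = {}
    order: list[int] = []
    for pos, old, new in events:
        if pos not in state:
            state[pos] = (old, new)
            order.append(pos)
        else:
            state[pos] = (state[pos][0], new)
    return [(p, *state[p]) for p in order if state[p][0] != state[p][1]]


def star_newick(n_tips: int, age_years: float, prefix: str = "T") -> str:
    """Ultrametric star tree: n tips all splitting from the root at once."""
    tips = ",".join(f"{prefix}{i + 1}:{age_years:g}" for i in range(n_tips))
    return f"({tips})root;"


def replay_tip(truth: SimTruth, sample_id: str) -> str:
    """Rebuild a tip from the root by replaying recorded substitutions."""
    hg = truth.true_haplogroup[sample_id]
    seq = list(truth.reference)
    path = truth.tree.path(hg)
    for node in path:
        for pos, _old, new in truth.branch_substitutions.get(node, []):
            seq[pos - 1] = new
    for pos, _old, new in truth.sample_substitutions[sample_id]:
        seq[pos - 1] = new
    return "".join(seq)


def simulate_ssr(
    n_populations: int,
    F: float,
    n_per_pop: int,
    n_loci: int = 7,
    n_alleles: int = 6,
    seed: int = 0,
) -> GenotypeMatrix:
    """Balding–Nichols SSR genotypes with differentiation level F.

    Ancestral allele frequencies per locus are Dirichlet(1,...,1); each
    population's frequencies are Dirichlet(p * (1-F)/F) around them (F=0
    returns the ancestral frequencies exactly).  Alleles are reported as
    microsatellite fragment sizes 100, 102, ...
    """
    if not 0 <= F < 1:
        raise ValueError("F must be in [0, 1)")
    if n_per_pop < 2:
        raise ValueError("need >=2 diploids per population for FST estimation")
    rng = np.random.default_rng(seed)
    sizes = 100 + 2 * np.arange(n_alleles)
    individuals, populations = [], []
    alleles = np.zeros((n_populations * n_per_pop, n_loci, 2), dtype=int)
    for j in range(n_loci):
        p_anc = rng.dirichlet(np.ones(n_alleles))
        for k in range(n_populations):
            if F == 0:
                p_pop = p_anc
            else:
                p_pop = rng.dirichlet(np.maximum(p_anc, 1e-9) * (1 - F) / F)
            draws = rng.choice(n_alleles, size=(n_per_pop, 2), p=p_pop)
            rows = slice(k * n_per_pop, (k + 1) * n_per_pop)
            alleles[rows, j, :] = sizes[draws]
    for k in range(n_populations):
        for i in range(n_per_pop):
            individuals.append(f"P{k + 1}_I{i + 1}")
            populations.append(f"P{k + 1}")
    return GenotypeMatrix(individuals, populations, [f"SSR{j + 1}" for j in range(n_loci)], alleles)


#: toy haplogroup hierarchy used by the fixture suite
FIXTURE_NEWICK = (
    "(((A1:20000)A:40000,(B1:25000,B2:25000)B:35000)AB:40000,"
    "((D1:30000)D:30000,(F2:25000,F3:25000)F:35000)DF:40000)LiAM;"
)


def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, str]:
    """Write a small, fully-determined fixture set used across module tests.

    Produces an aligned FASTA (30 sequences on an A/B/D/F-style toy
    hierarchy), the truth haplogroup table, the extracted tree TSV, a toy
    gene annotation and an SSR genotype CSV.  Byte-identical for a given
    seed.
    """
    os.makedirs(out_dir, exist_ok=True)
    scenario = SimScenario(
        newick=FIXTURE_NEWICK,
        rate=CYTB_RATE * 40,  # compressed timescale: toy tree is ky-deep
        samples_per_leaf=5,
        private_mutations=1,
        seed=seed,
    )
    truth = simulate_mitogenomes(scenario)
    paths = {
        "fasta": os.path.join(out_dir, "synthetic_cytb.fasta"),
        "tree": os.path.join(out_dir, "synthetic_haplogroups.tsv"),
        "truth": os.path.join(out_dir, "synthetic_truth.tsv"),
        "annotation": os.path.join(out_dir, "synthetic_genes.tsv"),
        "genotypes": os.path.join(out_dir, "synthetic_ssr.csv"),
    }
    write_fasta(truth.alignment, paths["fasta"])
    write_haplogroup_table(truth.tree, paths["tree"])
    with open(paths["truth"], "w") as fh:
        fh.write("sequence\thaplogroup\n")
        for sid in sorted(truth.true_haplogroup):
            fh.write(f"{sid}\t{truth.true_haplogroup[sid]}\n")
    write_annotation(
        [GeneAnnotation("cytb", 1, 1040, "+")], paths["annotation"]
    )
    write_genotypes(
        simulate_ssr(4, 0.2, 20, seed=seed), paths["genotypes"]
    )
    return paths
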