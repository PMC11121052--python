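"""Shared fixtures: small hand-built alignments and seeded simulations."""

import pytest

import liontree as lt
from liontree.simulate import FIXTURE_NEWICK

#: fixture hierarchy with branch durations scaled into the Myr range, so
#: branches accumulate enough substitutions at the calibrated cytb rate
MYR_NEWICK = (
    "(((A1:800000)A:1600000,(B1:1000000,B2:1000000)B:1400000)AB:1600000,"
    "((D1:1200000)D:1200000,(F2:1000000,F3:1000000)F:1400000)DF:1600000)LiAM;"
)


@pytest.fixture(scope="session")
def labelled_truth():
    """Simulation with every haplogroup (internal included) sampled, at a
    rate low enough that parsimony placement is identifiable."""
    scenario = lt.SimScenario(
        newick=FIXTURE_NEWICK,
        rate=0.01797 * 8,
        samples_per_leaf=3,
        sample_internal_nodes=True,
        seed=1,
    )
    return lt.simulate_mitogenomes(scenario)


@pytest.fixture(scope="session")
def deep_truth():
    """~200 queries with one private mutation each on a Myr-deep hierarchy
    at the calibrated cytb rate."""
    scenario = lt.SimScenario(
        newick=MYR_NEWICK,
        rate=0.01797,
        samples_per_leaf=34,
        private_mutations=1,
        seed=11,
    )
    return lt.simulate_mitogenomes(scenario)


@pytest.fixture()
def toy_aln():
    """Five 20-site sequences over a tiny two-level hierarchy."""
    ref = "ACGTACGTACGTACGTACGT"
    b2 = ref[:4] + "G" + ref[5:9] + "A" + ref[10:14] + "T" + ref[15:]  # A5G C10A G15T
    return lt.MitoAlignment(
        ids=["reference", "q_ref", "q_b2"],
        seqs=[ref, ref, b2],
        ref_id="reference",
    )


@pytest.fixture()
def toy_tree():
    """Root plus B/B2 with explicit defining mutations on 20 sites."""
    return lt.HaplogroupTree.from_rows(
        [
            ("A", None, []),
            ("B", "A", [lt.parse_mutation("A5G")]),
            ("B2", "B", [lt.parse_mutation("C10A"), lt.parse_mutation("G15T")]),
        ]
    )
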