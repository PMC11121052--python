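"""Classify mitochondrial sequences into haplogroups.

Simulates cytb-like sequences on a small dated haplogroup hierarchy, then
extracts branch-defining mutations by parsimony and classifies each
sequence back.  The score is 1.0 when a query carries exactly the expected
defining mutations for its haplogroup (penalty 0.5 per private mutation).
"""

import liontree as lt
from liontree.simulate import FIXTURE_NEWICK

truth = lt.simulate_mitogenomes(
    lt.SimScenario(newick=FIXTURE_NEWICK, rate=0.01797 * 8,
                   samples_per_leaf=2, private_mutations=1, seed=1)
)

topology = {name: parent for name, (parent, _) in truth.tree.nodes.items()}
tree, homoplasies = lt.extract_defining_mutations(
    truth.alignment, truth.true_haplogroup, topology
)
print(f"homoplasy report: {[m.label() for m in homoplasies] or 'none'}")

correct = 0
for sid, true_hg in sorted(truth.true_haplogroup.items()):
    res = lt.classify(sid, truth.alignment.seq(sid), tree, truth.alignment)
    correct += res.haplogroup == true_hg
    print(f"{sid:8s} -> {res.haplogroup:4s} score={res.score:.2f} "
          f"(truth {true_hg}, {len(res.private)} private)")

n = len(truth.true_haplogroup)
print(f"\n{correct}/{n} queries assigned to their true haplogroup.")
print("A private mutation is one the query carries beyond its haplogroup's "
      "defining set; it lowers the score but rarely changes the assignment.")
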