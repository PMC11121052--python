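"""Haplogroup tree extraction, classification, nomenclature, imputation."""

import pytest

import liontree as lt
from liontree.haplotree import InsufficientCoverageError, group_consensus


def apply_mutations(ref, muts):
    seq = list(ref)
    for m in muts:
        seq[m.pos - 1] = m.alt
    return "".join(seq)


class TestExtractDefiningMutations:
    def test_star_topology_private_sites(self):
        ref = "AAAAAAAAAA"
        seqs = {
            "g1a": apply_mutations(ref, [lt.Mutation(2, "A", "C")]),
            "g2a": apply_mutations(ref, [lt.Mutation(5, "A", "G")]),
            "g3a": apply_mutations(ref, [lt.Mutation(8, "A", "T")]),
        }
        aln = lt.MitoAlignment(
            ids=["reference"] + list(seqs),
            seqs=[ref] + list(seqs.values()),
            ref_id="reference",
        )
        labels = {"g1a": "G1", "g2a": "G2", "g3a": "G3"}
        topo = {"R": None, "G1": "R", "G2": "R", "G3": "R"}
        tree, report = lt.extract_defining_mutations(aln, labels, topo)
        assert [m.label() for m in tree.nodes["G1"][1]] == ["A2C"]
        assert [m.label() for m in tree.nodes["G2"][1]] == ["A5G"]
        assert [m.label() for m in tree.nodes["G3"][1]] == ["A8T"]
        assert report == []

    def test_recovers_simulated_branch_substitutions(self, labelled_truth):
        t = labelled_truth
        topo = {n: p for n, (p, _) in t.tree.nodes.items()}
        tree, _ = lt.extract_defining_mutations(t.alignment, t.true_haplogroup, topo)
        for node in tree.preorder():
            got = sorted((m.pos, str(m.ref), str(m.alt)) for m in tree.nodes[node][1])
            truth = sorted(
                (m.pos, str(m.ref), str(m.alt)) for m in t.tree.nodes[node][1]
            )
            assert got == truth, node

    def test_parallel_mutation_lands_on_both_branches(self):
        # four taxa, site 3 derived independently in T1 and T3 (hand Fitch:
        # ((T1,T2),(T3,T4)) with C at 3 in T1 and T3 only is homoplasic)
        ref = "AAAAA"
        seqs = {
            "t1": "AACAA",
            "t2": "AAAAA",
            "t3": "AACAA",
            "t4": "AAAAA",
        }
        aln = lt.MitoAlignment(
            ids=["reference"] + list(seqs),
            seqs=[ref] + list(seqs.values()),
            ref_id="reference",
        )
        labels = {s: s.upper() for s in seqs}
        topo = {"R": None, "L": "R", "M": "R",
                "T1": "L", "T2": "L", "T3": "M", "T4": "M"}
        tree, report = lt.extract_defining_mutations(aln, labels, topo)
        assert [m.label() for m in tree.nodes["T1"][1]] == ["A3C"]
        assert [m.label() for m in tree.nodes["T3"][1]] == ["A3C"]
        assert [m.label() for m in report] == ["A3C"]

    def test_invariant_to_within_group_order(self, labelled_truth):
        t = labelled_truth
        topo = {n: p for n, (p, _) in t.tree.nodes.items()}
        tree1, _ = lt.extract_defining_mutations(t.alignment, t.true_haplogroup, topo)
        reordered = t.alignment.subset(list(reversed(t.alignment.ids)))
        tree2, _ = lt.extract_defining_mutations(reordered, t.true_haplogroup, topo)
        assert {n: tree1.nodes[n][1] for n in tree1.nodes} == {
            n: tree2.nodes[n][1] for n in tree2.nodes
        }

    def test_empty_group_and_unknown_label_rejected(self, toy_aln):
        with pytest.raises(ValueError, match="absent from topology"):
            lt.extract_defining_mutations(toy_aln, {"q_ref": "Z"}, {"A": None})
        with pytest.raises(ValueError, match="empty"):
            group_consensus(toy_aln, [])

    def test_consensus_tie_gives_n(self):
        aln = lt.MitoAlignment(ids=["a", "b"], seqs=["AAAA", "AACA"])
        assert group_consensus(aln, ["a", "b"]) == "AANA"


class TestClassify:
    def test_query_with_all_b2_mutations_scores_one(self, toy_aln, toy_tree):
        res = lt.classify("q_b2", toy_aln.seq("q_b2"), toy_tree, toy_aln)
        assert res.haplogroup == "B2"
        assert res.score == 1.0
        assert res.private == [] and res.missing == []

    def test_reference_query_is_root(self, toy_aln, toy_tree):
        res = lt.classify("q_ref", toy_aln.seq("q_ref"), toy_tree, toy_aln)
        assert res.haplogroup == "A"
        assert res.score == 1.0

    def test_simulated_queries_all_recover_truth(self, deep_truth):
        t = deep_truth
        correct = 0
        for sid, hg in t.true_haplogroup.items():
            res = lt.classify(sid, t.alignment.seq(sid), t.tree, t.alignment)
            correct += res.haplogroup == hg
        assert correct == len(t.true_haplogroup)

    def test_low_coverage_refused(self, toy_aln, toy_tree):
        q = "N" * toy_aln.length
        with pytest.raises(InsufficientCoverageError, match="insufficient coverage"):
            lt.classify("q", q, toy_tree, toy_aln)

    def test_missing_site_excluded_from_both_sets(self, toy_aln, toy_tree):
        q = list(toy_aln.seq("q_b2"))
        q[9] = "N"  # mask defining site C10A
        res = lt.classify("q", "".join(q), toy_tree, toy_aln)
        sites = {m.pos for m in res.matched} | {m.pos for m in res.missing}
        assert 10 not in sites
        assert res.haplogroup == "B2"


class TestNomenclature:
    def test_legacy_label_maps_to_standard(self):
        assert lt.convert_nomenclature("lineage III", {"lineage III": "B"}) == "B"

    def test_standard_label_idempotent(self):
        assert lt.convert_nomenclature("B2", {}) == "B2"

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            lt.convert_nomenclature("Q9", {})


class TestImputePartial:
    def test_gap_over_defining_site_gets_derived_base(self, toy_aln, toy_tree):
        partial = "N" * 12 + toy_aln.seq("q_b2")[12:]
        seq, flags = lt.impute_partial(partial, "B2", toy_tree, toy_aln)
        assert seq[4] == "G" and seq[9] == "A"  # A5G and C10A derived states
        assert flags[4] == "imputed" and flags[12] == "observed"

    def test_neutral_gap_filled_with_reference(self, toy_aln, toy_tree):
        partial = toy_aln.seq("q_b2")[:16] + "NNNN"  # no defining site in tail
        seq, _ = lt.impute_partial(partial, "B2", toy_tree, toy_aln)
        assert seq[16:] == toy_aln.ref_seq[16:]
        before = lt.classify("q", partial, toy_tree, toy_aln).haplogroup
        after = lt.classify("q", seq, toy_tree, toy_aln).haplogroup
        assert before == after == "B2"

    def test_observed_positions_never_changed(self, deep_truth):
        t = deep_truth
        sid = next(iter(t.true_haplogroup))
        full = t.alignment.seq(sid)
        partial = full[:718] + "N" * (len(full) - 718)
        seq, flags = lt.impute_partial(
            partial, t.true_haplogroup[sid], t.tree, t.alignment
        )
        assert seq[:718] == full[:718]
        assert all(f == "observed" for f in flags[:718])

    def test_truncated_queries_classify_like_full_length(self, deep_truth):
        """718 of 1040 sites amplified -> impute -> identical assignments."""
        t = deep_truth
        changed = []
        for sid, hg in t.true_haplogroup.items():
            full = t.alignment.seq(sid)
            partial = full[:718] + "N" * (t.alignment.length - 718)
            first = lt.classify(sid, partial, t.tree, t.alignment)
            imputed, _ = lt.impute_partial(partial, first.haplogroup, t.tree, t.alignment)
            final = lt.classify(sid, imputed, t.tree, t.alignment)
            if final.haplogroup != hg:
                changed.append(sid)
        assert changed == []
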