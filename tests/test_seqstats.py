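"""Diversity, sliding windows, ns/s classification, NUMT scan, species rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import liontree as lt
from liontree.seqstats import classify_codon_change, translate_codon

# vertebrate mitochondrial code, written out independently of the library's
# translation table (stops as '*')
VERT_MITO_CODE = {}
_AAS = (
    "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"
)
_B = "TCAG"
for _i, _aa in enumerate(_AAS):
    VERT_MITO_CODE[_B[_i // 16] + _B[(_i // 4) % 4] + _B[_i % 4]] = _aa


def test_oracle_table_is_the_vertebrate_code():
    # spot-check the four departures from the standard code
    assert VERT_MITO_CODE["AGA"] == "*" and VERT_MITO_CODE["AGG"] == "*"
    assert VERT_MITO_CODE["ATA"] == "M"
    assert VERT_MITO_CODE["TGA"] == "W"


class TestJCDistance:
    def test_zero_proportion_gives_zero(self):
        assert lt.jc_distance(0.0) == 0.0

    def test_closed_form_value(self):
        expected = -0.75 * math.log(1 - 4 * 0.05 / 3)
        assert lt.jc_distance(0.05) == pytest.approx(expected, abs=1e-12)
        assert lt.jc_distance(0.05) == pytest.approx(0.051744, abs=1e-6)

    @pytest.mark.parametrize("p", [0.75, 0.9, -0.01])
    def test_saturation_and_domain_errors(self, p):
        with pytest.raises(ValueError):
            lt.jc_distance(p)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=0.74))
    def test_correction_never_below_raw_distance(self, p):
        assert lt.jc_distance(p) >= p
        if p > 1e-6:  # strict inequality, away from rounding at tiny p
            assert lt.jc_distance(p) > p


class TestNucleotideDiversity:
    def test_identical_group_is_zero(self):
        aln = lt.MitoAlignment(ids=["a", "b", "c"], seqs=["ACGT" * 5] * 3)
        (res,) = lt.nucleotide_diversity(aln, {"g": ["a", "b", "c"]})
        assert res.pi == 0.0 and res.n_pairs == 3

    def test_two_sequences_two_differences_closed_form(self):
        s1 = "A" * 100
        s2 = "C" + "A" * 98 + "C"
        aln = lt.MitoAlignment(ids=["a", "b"], seqs=[s1, s2])
        (res,) = lt.nucleotide_diversity(aln, {"g": ["a", "b"]})
        assert res.pi == pytest.approx(100 * lt.jc_distance(0.02), abs=1e-9)
        assert res.pi == pytest.approx(2.0271, abs=1e-4)

    def test_between_group_matches_simulated_divergence(self):
        """Two groups separated for time t: E[pi_between] ~ 2*r*t."""
        # near-homogeneous site rates: the JC correction assumes them, so
        # this is the regime where the closed-form expectation applies
        rate, t_myr = 0.05, 1.0
        newick = f"(P:{t_myr * 1e6:.0f},Q:{t_myr * 1e6:.0f})R;"
        pis = []
        for seed in range(20):
            truth = lt.simulate_mitogenomes(
                lt.SimScenario(newick=newick, rate=rate, locus_length=2000,
                               samples_per_leaf=2, gamma_shape=200.0,
                               prop_invariant=0.0, seed=seed)
            )
            groups = {"P": ["P_1", "P_2"], "Q": ["Q_1", "Q_2"]}
            between = [
                r for r in lt.nucleotide_diversity(truth.alignment, groups)
                if r.scope == "between-groups"
            ]
            pis.append(between[0].pi)
        expected = 100 * 2 * rate * t_myr  # percent
        se = np.std(pis, ddof=1) / math.sqrt(len(pis))
        assert abs(np.mean(pis) - expected) < 3 * se + 0.5

    def test_all_missing_pair_errors(self):
        aln = lt.MitoAlignment(ids=["a", "b"], seqs=["NNNN", "ACGT"])
        with pytest.raises(ValueError, match="no callable pairs"):
            lt.nucleotide_diversity(aln, {"g": ["a", "b"]})


class TestSlidingWindows:
    def test_window_starts_and_trailing_drop(self):
        aln = lt.MitoAlignment(ids=["a", "b"], seqs=["A" * 100, "C" * 100])
        spans = [r.window for r in lt.sliding_windows(aln)]
        assert spans == [(1, 50), (26, 75), (51, 100)]

    def test_sixty_sites_keep_single_window(self):
        aln = lt.MitoAlignment(ids=["a", "b"], seqs=["A" * 60, "A" * 60])
        spans = [r.window for r in lt.sliding_windows(aln)]
        assert spans == [(1, 50)]

    def test_constant_alignment_zero_trace(self):
        aln = lt.MitoAlignment(ids=["a", "b", "c"], seqs=["ACGT" * 25] * 3)
        assert all(r.pi == 0.0 for r in lt.sliding_windows(aln))

    def test_tiled_windows_recompose_whole_region_proportion(self):
        rng = np.random.default_rng(5)
        base = rng.choice(list("ACGT"), 100)
        seqs = []
        for _ in range(4):  # ~10% divergent copies, far from JC saturation
            s = base.copy()
            idx = rng.choice(100, 10, replace=False)
            s[idx] = [transition(b) for b in s[idx]]
            seqs.append("".join(s))
        aln = lt.MitoAlignment(ids=[f"s{i}" for i in range(4)], seqs=seqs)
        tiles = lt.sliding_windows(aln, window=25, step=25)
        whole = lt.sliding_windows(aln, window=100, step=100)[0]
        weighted = sum(r.mean_p * 25 for r in tiles) / 100
        assert weighted == pytest.approx(whole.mean_p, abs=1e-9)


class TestNsS:
    @pytest.mark.parametrize(
        "anc,der,expected",
        [
            ("ATA", "ATG", "synonymous"),  # both Met in the mito code
            ("AGA", "AGG", "synonymous"),  # both mito stops
            ("ATA", "ACA", "nonsynonymous"),
            ("TGA", "TGG", "synonymous"),  # Trp in the mito code
        ],
    )
    def test_known_codon_changes(self, anc, der, expected):
        assert classify_codon_change(anc, der) == expected

    def test_agrees_with_exhaustive_code_oracle(self):
        """All single-base codon changes vs the hardcoded vertebrate table."""
        bases = "ACGT"
        n = 0
        for codon in VERT_MITO_CODE:
            for i in range(3):
                for b in bases:
                    if b == codon[i]:
                        continue
                    der = codon[:i] + b + codon[i + 1:]
                    want = (
                        "synonymous"
                        if VERT_MITO_CODE[codon] == VERT_MITO_CODE[der]
                        else "nonsynonymous"
                    )
                    assert classify_codon_change(codon, der) == want, (codon, der)
                    n += 1
        assert n == 64 * 9

    def test_counts_on_constructed_tree(self):
        # gene 1..12 on +: codons AAA AAA AAA AAA (Lys); A->G at codon pos 3
        # is synonymous (AAA->AAG Lys), at pos 1 nonsynonymous (AAA->GAA Glu)
        ref = "A" * 12
        aln = lt.MitoAlignment(ids=["reference"], seqs=[ref], ref_id="reference")
        tree = lt.HaplogroupTree.from_rows(
            [
                ("R", None, []),
                ("H1", "R", [lt.Mutation(3, "A", "G")]),   # syn
                ("H2", "R", [lt.Mutation(4, "A", "G")]),   # nonsyn
            ]
        )
        ann = [lt.GeneAnnotation("toy", 1, 12, "+")]
        (res,) = lt.ns_s_ratio(aln, ann, tree)
        assert (res.n_nonsyn, res.n_syn) == (1, 1)
        assert res.ratio == 1.0

    def test_minus_strand_uses_reverse_complement(self):
        # '-' strand gene over 1..6; reference read 3'->5' is revcomp
        ref = "TTTCAT"  # revcomp = ATGAAA -> Met Lys
        aln = lt.MitoAlignment(ids=["reference"], seqs=[ref], ref_id="reference")
        # T2C on the reference is G5->G? revcomp offset: pos 2 -> codon 2 pos 2
        tree = lt.HaplogroupTree.from_rows(
            [("R", None, []), ("H", "R", [lt.Mutation(1, "T", "C")])]
        )
        # pos 1 '+' is last base of the revcomp gene: AAA -> AAG, synonymous
        (res,) = lt.ns_s_ratio(aln, [lt.GeneAnnotation("toy", 1, 6, "-")], tree)
        assert (res.n_nonsyn, res.n_syn) == (0, 1)

    def test_ratio_zero_when_only_synonymous_sites_mutate(self):
        ref = "AAA" * 4
        aln = lt.MitoAlignment(ids=["reference"], seqs=[ref], ref_id="reference")
        muts = [lt.Mutation(p, "A", "G") for p in (3, 6, 9)]  # all 3rd positions
        tree = lt.HaplogroupTree.from_rows([("R", None, []), ("H", "R", muts)])
        (res,) = lt.ns_s_ratio(aln, [lt.GeneAnnotation("toy", 1, 12, "+")], tree)
        assert res.n_nonsyn == 0 and res.n_syn == 3
        assert res.ratio == 0.0


def transition(base):
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[base]


class TestNumtScan:
    def _panel(self, length=4000, seed=0):
        rng = np.random.default_rng(seed)
        root = "".join(rng.choice(list("ACGT"), length))
        near = list(root)
        for i in rng.choice(length, 20, replace=False):
            near[i] = transition(near[i])
        return lt.MitoAlignment(ids=["p1", "p2"], seqs=[root, "".join(near)]), root

    def _mutated(self, seq, frac, seed):
        rng = np.random.default_rng(seed)
        s = list(seq)
        for i in rng.choice(len(seq), int(frac * len(seq)), replace=False):
            s[i] = transition(s[i])
        return "".join(s)

    def test_panel_member_is_clean(self):
        panel, root = self._panel()
        scan = lt.numt_scan("q", root, panel)
        assert scan.verdict == "clean"
        assert max(scan.min_divergence) == 0.0
        assert scan.flagged_segments == []

    def test_half_genome_chimera_flagged(self):
        panel, root = self._panel()
        half = len(root) // 2
        chimera = root[:half] + self._mutated(root, 0.10, seed=1)[half:]
        scan = lt.numt_scan("q", chimera, panel)
        assert scan.verdict == "chimeric"
        assert len(scan.flagged_segments) == 1
        start, end, div = scan.flagged_segments[0]
        assert start >= half - 500 and end == len(root)
        assert div > 5

    def test_uniformly_divergent_species_not_chimeric(self):
        panel, root = self._panel()
        other = self._mutated(root, 0.05, seed=2)
        scan = lt.numt_scan("q", other, panel)
        assert scan.verdict == "clean"
        assert all(d > 2.0 for d in scan.min_divergence)


class TestSpeciesFlag:
    def test_cave_lion_value_is_within_species(self):
        assert lt.species_flag(1.74) == "within-species"

    @pytest.mark.parametrize(
        "pi,expected", [(0.0, "within-species"), (2.5, "distinct"), (2.0, "distinct")]
    )
    def test_threshold_rule(self, pi, expected):
        assert lt.species_flag(pi) == expected
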