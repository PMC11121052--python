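"""Polymorphism statistics on aligned mitogenome sequences.

Nucleotide diversity uses the Jukes–Cantor correction
``d = -(3/4) ln(1 - 4p/3)`` on per-pair proportions of differing sites,
with pairwise deletion of missing data (each pair is compared only over
columns callable in both members — partial cytb sequences dominate real
panels, so complete deletion would discard most of the locus).  Diversity
is reported in percent (substitutions per 100 sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io import GeneAnnotation, MitoAlignment, VALID_BASES
from .haplotree import HaplogroupTree

logger = logging.getLogger("liontree")

JC_SATURATION = 0.75
#: Below this percent divergence two mitochondrial lineages are conspecific.
SPECIES_THRESHOLD_PERCENT = 2.0

_ENCODE = {b: i for i, b in enumerate("ACGT")}


def jc_distance(p: float) -> float:
    """Jukes–Cantor corrected distance from a proportion of differing sites."""
    if not 0.0 <= p < JC_SATURATION:
        raise ValueError(f"p={p} outside [0, 0.75): Jukes–Cantor saturation")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def encode_alignment(aln: MitoAlignment, ids: list[str] | None = None) -> np.ndarray:
    """Integer matrix (n_seqs, n_cols): A,C,G,T -> 0..3, missing -> -1."""
    ids = ids if ids is not None else aln.ids
    mat = np.full((len(ids), aln.length), -1, dtype=np.int8)
    for r, seq_id in enumerate(ids):
        seq = aln.seq(seq_id)
        for c, b in enumerate(seq):
            if b in VALID_BASES:
                mat[r, c] = _ENCODE[b]
    return mat


def _pair_p(mat: np.ndarray, i: int, j: int, cols: np.ndarray | None = None):
    a = mat[i] if cols is None else mat[i, cols]
    b = mat[j] if cols is None else mat[j, cols]
    callable_ = (a >= 0) & (b >= 0)
    n = int(callable_.sum())
    if n == 0:
        return None, 0
    return float((a[callable_] != b[callable_]).sum()) / n, n


@dataclass
class DiversityResult:
    scope: str  # within-group | between-groups | window
    groups: tuple[str, ...]
    pi: float  # percent, substitutions per 100 sites, JC-corrected
    n_pairs: int
    callable_sites: float  # mean callable sites per pair
    mean_p: float = float("nan")  # uncorrected mean proportion of differences
    window: tuple[int, int] | None = None  # 1-based inclusive, for scope=window


def _mean_pairwise_jc(mat, pairs, cols=None) -> tuple[float, int, float, float]:
    dists, sites, raws = [], [], []
    for i, j in pairs:
        p, n = _pair_p(mat, i, j, cols)
        if p is None:
            continue
        dists.append(jc_distance(p))
        raws.append(p)
        sites.append(n)
    if not dists:
        raise ValueError("no callable pairs — all sequences missing at shared sites")
    return float(np.mean(dists)), len(dists), float(np.mean(sites)), float(np.mean(raws))


def nucleotide_diversity(
    aln: MitoAlignment, groups: dict[str, list[str]]
) -> list[DiversityResult]:
    """Within-group and between-group JC nucleotide diversity, in percent.

    Within a group: mean pairwise JC distance over all pairs inside it.
    Between two groups: mean pairwise JC distance across groups (no net
    correction, matching the plain between-haplogroup values).
    """
    results = []
    order = sorted(groups)
    mat = encode_alignment(aln)
    for g in order:
        ids = groups[g]
        if len(ids) >= 2:
            idx = [aln.ids.index(i) for i in ids]
            pi, n_pairs, ncall, p = _mean_pairwise_jc(mat, combinations(idx, 2))
            results.append(
                DiversityResult("within-group", (g,), 100 * pi, n_pairs, ncall, p)
            )
    for g1, g2 in combinations(order, 2):
        idx1 = [aln.ids.index(i) for i in groups[g1]]
        idx2 = [aln.ids.index(i) for i in groups[g2]]
        if not idx1 or not idx2:
            continue
        pi, n_pairs, ncall, p = _mean_pairwise_jc(mat, product(idx1, idx2))
        results.append(
            DiversityResult("between-groups", (g1, g2), 100 * pi, n_pairs, ncall, p)
        )
    return results


def sliding_windows(
    aln: MitoAlignment,
    ids: list[str] | None = None,
    window: int = 50,
    step: int = 25,
) -> list[DiversityResult]:
    """Mean pairwise JC diversity in sliding windows over alignment columns.

    Windows start at positions 1, 1+step, 1+2*step, ...; a trailing window
    shorter than ``window`` is dropped.  Windows with no callable pairs get
    pi = NaN rather than an error (fully missing segments are common).
    """
    ids = ids if ids is not None else aln.ids
    mat = encode_alignment(aln, ids)
    pairs = list(combinations(range(len(ids)), 2))
    results = []
    start = 1
    while start + window - 1 <= aln.length:
        cols = np.arange(start - 1, start - 1 + window)
        try:
            pi, n_pairs, ncall, p = _mean_pairwise_jc(mat, pairs, cols)
        except ValueError:
            pi, n_pairs, ncall, p = float("nan"), 0, 0.0, float("nan")
        results.append(
            DiversityResult("window", (), 100 * pi if pi == pi else pi,
                            n_pairs, ncall, p, window=(start, start + window - 1))
        )
        start += step
    return results


# --- non-synonymous / synonymous classification -------------------------

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial


def translate_codon(codon: str) -> str:
    """One-letter amino acid under genetic code 2; '*' for stop."""
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


@dataclass
class NsSResult:
    gene: str
    n_nonsyn: int
    n_syn: int
    n_uncalled: int = 0
    stop_involving: list[str] = field(default_factory=list)

    @property
    def ratio(self) -> float | None:
        if self.n_syn == 0:
            return float("inf") if self.n_nonsyn > 0 else None
        return self.n_nonsyn / self.n_syn


_COMP = str.maketrans("ACGT", "TGCA")


def classify_codon_change(anc_codon: str, der_codon: str) -> str:
    """'synonymous' or 'nonsynonymous' for a single-codon change (code 2)."""
    return "synonymous" if translate_codon(anc_codon) == translate_codon(der_codon) else "nonsynonymous"


def ns_s_ratio(
    aln: MitoAlignment,
    annotation: list[GeneAnnotation],
    tree: HaplogroupTree,
) -> list[NsSResult]:
    """Per-gene non-synonymous vs synonymous counts of tree branch mutations.

    Each branch mutation falling inside a gene is classified by translating
    the path-reconstructed ancestral codon against the mutated codon under
    the vertebrate mitochondrial code.  Minus-strand genes are read on the
    reverse complement.  Genes whose span is not a codon multiple are
    trimmed of the trailing partial codon (mutations there are 'uncalled').
    Changes where either codon is a stop are flagged.
    """
    ref = aln.ref_seq
    pos_to_col = {
        aln.positions[c]: c
        for c in range(aln.length)
        if aln.insertion_ordinal[c] == 0
    }
    results = []
    for gene in annotation:
        n_syn = n_nonsyn = n_uncalled = 0
        stop_involving: list[str] = []
        usable_len = gene.length - gene.length % 3
        if gene.length % 3:
            logger.warning("gene %s: trimming %d trailing bases", gene.gene, gene.length % 3)
        for name in tree.preorder():
            parent, muts = tree.nodes[name]
            if parent is None:
                continue
            # ancestral background at the parent node
            parent_states = tree.expected_states(parent)
            for mut in muts:
                if not gene.start <= mut.pos <= gene.end:
                    continue
                offset = mut.pos - gene.start  # 0-based within gene, + strand
                if gene.strand == "-":
                    offset = gene.length - 1 - offset
                if offset >= usable_len:
                    n_uncalled += 1
                    logger.info("mutation %s in trimmed codon of %s: uncalled",
                                mut.label(), gene.gene)
                    continue
                codon_idx = offset // 3
                within = offset % 3

                def gene_base(off: int, states: dict) -> str:
                    if gene.strand == "+":
                        pos = gene.start + off
                        base = states[pos][1] if pos in states else ref[pos_to_col[pos]]
                        return base
                    pos = gene.end - off
                    base = states[pos][1] if pos in states else ref[pos_to_col[pos]]
                    return base.translate(_COMP)

                anc_codon = "".join(
                    gene_base(codon_idx * 3 + k, parent_states) for k in range(3)
                )
                der_base = mut.alt if gene.strand == "+" else mut.alt.translate(_COMP)
                der_codon = anc_codon[:within] + der_base + anc_codon[within + 1:]
                if "N" in anc_codon or "N" in der_codon:
                    n_uncalled += 1
                    continue
                if classify_codon_change(anc_codon, der_codon) == "synonymous":
                    n_syn += 1
                else:
                    n_nonsyn += 1
                if translate_codon(anc_codon) == "*" or translate_codon(der_codon) == "*":
                    stop_involving.append(mut.label())
        results.append(NsSResult(gene.gene, n_nonsyn, n_syn, n_uncalled, stop_involving))
    return results


# --- NUMT flagging -------------------------------------------------------

@dataclass
class NumtScan:
    windows: list[tuple[int, int]]  # 1-based inclusive column spans
    min_divergence: list[float]  # percent JC to closest panel member
    flagged_segments: list[tuple[int, int, float]]  # (start, end, mean divergence %)
    verdict: str  # clean | chimeric


def numt_scan(
    query_id: str,
    query: str,
    panel: MitoAlignment,
    window: int = 500,
    step: int = 250,
    threshold: float = SPECIES_THRESHOLD_PERCENT,
) -> NumtScan:
    """Scan a putative mitogenome for NUMT-like chimerism.

    Per window, the minimum JC distance (%) from the query to any panel
    member; maximal runs of >=2 consecutive windows above ``threshold`` are
    merged into flagged segments.  The verdict is 'chimeric' when >=20% of
    windows are flagged while >=20% sit below threshold/2 — a uniformly
    divergent sequence (a different species) is not chimeric.
    """
    ids = [i for i in panel.ids if i != query_id]
    mat = encode_alignment(panel, ids)
    q = np.full(panel.length, -1, dtype=np.int8)
    for c, b in enumerate(query):
        if b in VALID_BASES:
            q[c] = _ENCODE[b]

    spans, mins = [], []
    start = 1
    while start + window - 1 <= panel.length:
        cols = slice(start - 1, start - 1 + window)
        best = np.inf
        for r in range(mat.shape[0]):
            a, b = q[cols], mat[r, cols]
            mask = (a >= 0) & (b >= 0)
            n = int(mask.sum())
            if n == 0:
                continue
            p = float((a[mask] != b[mask]).sum()) / n
            if p < JC_SATURATION:
                best = min(best, 100 * jc_distance(p))
        spans.append((start, start + window - 1))
        mins.append(best if np.isfinite(best) else float("nan"))
        start += step

    above = [d == d and d > threshold for d in mins]
    segments = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if j - i + 1 >= 2:
                seg_div = float(np.nanmean(mins[i: j + 1]))
                segments.append((spans[i][0], spans[j][1], seg_div))
            i = j + 1
        else:
            i += 1

    n_win = len(above)
    n_flagged = sum(
        1 for k, (s, e) in enumerate(spans)
        if any(s >= fs and e <= fe for fs, fe, _ in segments)
    )
    n_low = sum(1 for d in mins if d == d and d < threshold / 2)
    chimeric = n_win > 0 and n_flagged >= 0.2 * n_win and n_low >= 0.2 * n_win
    return NumtScan(spans, mins, segments, "chimeric" if chimeric else "clean")


def species_flag(pi_between_percent: float) -> str:
    """Two-percent rule: mitochondrial divergence below 2% is conspecific."""
    if pi_between_percent < 0:
        raise ValueError("diversity cannot be negative")
    return "within-species" if pi_between_percent < SPECIES_THRESHOLD_PERCENT else "distinct"
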