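"""Readers, writers and shared containers for mitogenome and genotype data.

External coordinates are 1-based inclusive throughout (GenBank/GFF
convention, matching the lion reference mitogenome annotation).  Alignment
columns where the reference carries a gap (insertions relative to the
reference) inherit the position of the left neighbour plus an insertion
ordinal and are excluded from mutation notation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("liontree")

VALID_BASES = frozenset("ACGT")
MISSING = frozenset("N-")
#: IUPAC ambiguity codes collapsed to N on input (N itself is kept).
AMBIGUITY = frozenset("RYSWKMBDHV")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_MUTATION_RE = re.compile(r"^([ACGT])(\d+)([ACGT])(!?)$")


def mutation_kind(ref: str, alt: str) -> str:
    """Transition (purine<->purine, pyrimidine<->pyrimidine) or transversion."""
    if (ref in PURINES) == (alt in PURINES):
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class Mutation:
    """A single substitution in ``<ref><1-based position><alt>`` notation.

    ``back`` flags a reversion toward the ancestral state on a tree path;
    it does not participate in equality so that a reversion and a forward
    change at the same site compare by state only.
    """

    pos: int
    ref: str
    alt: str
    back: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at position {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"bases must be in ACGT: {self.ref}{self.pos}{self.alt}")
        if self.pos < 1:
            raise ValueError("positions are 1-based")

    @property
    def kind(self) -> str:
        return mutation_kind(self.ref, self.alt)

    def label(self) -> str:
        return f"{self.ref}{self.pos}{self.alt}" + ("!" if self.back else "")

    def reverted(self) -> "Mutation":
        return Mutation(self.pos, self.alt, self.ref, back=True)


def parse_mutation(label: str) -> Mutation:
    """Parse a ``G1234A`` style label (optional trailing ``!`` = back-mutation)."""
    m = _MUTATION_RE.match(label.strip().upper())
    if not m:
        raise ValueError(f"malformed mutation label: {label!r}")
    ref, pos, alt, bang = m.groups()
    return Mutation(int(pos), ref, alt, back=bool(bang))


def format_mutation(mut: Mutation) -> str:
    return mut.label()


@dataclass
class MitoAlignment:
    """Reference-anchored nucleotide alignment.

    seqs are equal-length uppercase strings over ``{A,C,G,T,N,-}``;
    ``positions[c]`` is the 1-based reference coordinate of column ``c`` and
    ``insertion_ordinal[c]`` is 0 for reference columns, k>0 for the k-th
    inserted column after that reference position.
    """

    ids: list[str]
    seqs: list[str]
    ref_id: str | None = None
    positions: list[int] = field(default_factory=list)
    insertion_ordinal: list[int] = field(default_factory=list)
    region_mask: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ids:
            raise ValueError("alignment has no records")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError("unequal lengths among alignment records")
        (self.length,) = lengths
        if self.ref_id is not None and self.ref_id not in self.ids:
            raise ValueError(f"reference id {self.ref_id!r} absent from alignment")
        if not self.positions:
            self._assign_positions()
        if not self.region_mask:
            self.region_mask = ["coding"] * self.length
        ref_pos = [p for p, o in zip(self.positions, self.insertion_ordinal) if o == 0]
        if any(b > a for a, b in zip(ref_pos[1:], ref_pos)):
            raise ValueError("reference positions must be strictly increasing")

    def _assign_positions(self) -> None:
        ref = self.ref_seq if self.ref_id is not None else self.seqs[0]
        pos, ordinal = 0, 0
        self.positions, self.insertion_ordinal = [], []
        for base in ref:
            if base == "-":
                ordinal += 1
            else:
                pos += 1
                ordinal = 0
            self.positions.append(max(pos, 1))
            self.insertion_ordinal.append(ordinal)

    @property
    def ref_seq(self) -> str:
        if self.ref_id is None:
            raise ValueError("alignment has no designated reference")
        return self.seqs[self.ids.index(self.ref_id)]

    def seq(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def column_of(self, position: int) -> int:
        """0-based column index of a 1-based reference position."""
        for c, (p, o) in enumerate(zip(self.positions, self.insertion_ordinal)):
            if p == position and o == 0:
                return c
        raise KeyError(f"reference position {position} not in alignment")

    def position_of(self, column: int) -> int:
        """1-based reference position of a 0-based, non-inserted column."""
        if self.insertion_ordinal[column] != 0:
            raise KeyError(f"column {column} is an insertion column")
        return self.positions[column]

    def subset(self, ids: list[str]) -> "MitoAlignment":
        keep = [self.ids.index(i) for i in ids]
        return MitoAlignment(
            ids=list(ids),
            seqs=[self.seqs[k] for k in keep],
            ref_id=self.ref_id if self.ref_id in ids else None,
            positions=list(self.positions),
            insertion_ordinal=list(self.insertion_ordinal),
            region_mask=list(self.region_mask),
        )


def _normalise_seq(raw: str) -> tuple[str, int]:
    s = raw.upper().replace("U", "T")
    n_ambiguous = sum(1 for b in s if b in AMBIGUITY)
    if n_ambiguous:
        s = "".join("N" if b in AMBIGUITY else b for b in s)
    return s, n_ambiguous


def read_fasta(path, ref_id: str | None = None) -> MitoAlignment:
    """Read an aligned FASTA into a :class:`MitoAlignment`.

    Sequences are uppercased, U mapped to T, and IUPAC ambiguity codes other
    than N mapped to N (count logged).  Records of unequal length are
    rejected — inputs must be pre-aligned.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids, seqs, total_ambiguous = [], [], 0
    for rec in records:
        s, n_amb = _normalise_seq(str(rec.seq))
        ids.append(rec.id)
        seqs.append(s)
        total_ambiguous += n_amb
    if len({len(s) for s in seqs}) != 1:
        raise ValueError(f"unequal lengths among records in {path}")
    if total_ambiguous:
        logger.info("mapped %d ambiguity codes to N in %s", total_ambiguous, path)
    return MitoAlignment(ids=ids, seqs=seqs, ref_id=ref_id)


def write_fasta(aln: MitoAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval on the reference, 1-based inclusive."""

    gene: str
    start: int
    end: int
    strand: str
    code: str = "vertebrate_mitochondrial"

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates for {self.gene}: {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_annotation(path) -> list[GeneAnnotation]:
    """Read a GFF-like whitespace/tab table: gene, start, end, strand.

    Mitochondrial genes legitimately overlap (e.g. ATP8/ATP6); same-strand
    overlaps are warned about, never fatal.  Genes whose length is not a
    codon multiple are logged — trailing partial codons are trimmed later.
    """
    annotations = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{line_no}: expected gene start end strand")
            gene, start, end, strand = parts[0], int(parts[1]), int(parts[2]), parts[3]
            ann = GeneAnnotation(gene, start, end, strand)
            if ann.length % 3:
                logger.info("gene %s length %d is not a codon multiple", gene, ann.length)
            annotations.append(ann)
    for a in annotations:
        for b in annotations:
            if a is not b and a.strand == b.strand and a.start <= b.end and b.start <= a.end:
                logger.warning("overlapping genes on same strand: %s / %s", a.gene, b.gene)
    return annotations


def write_annotation(annotations: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.gene}\t{a.start}\t{a.end}\t{a.strand}\n")


def read_haplogroup_table(path):
    """Read the haplogroup-definition TSV into a rooted HaplogroupTree.

    Columns: haplogroup, parent (empty for the single root), comma-separated
    mutation labels in ``<ref><pos><alt>`` notation.
    """
    from .haplotree import HaplogroupTree  # local import: io <-> haplotree

    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or (
                line_no == 1 and line.lower().startswith("haplogroup")
            ):
                continue
            parts = line.split("\t")
            name = parts[0].strip()
            parent = parts[1].strip() if len(parts) > 1 else ""
            muts_field = parts[2].strip() if len(parts) > 2 else ""
            muts = [parse_mutation(m) for m in muts_field.split(",") if m.strip()]
            rows.append((name, parent or None, muts))
    return HaplogroupTree.from_rows(rows)


def write_haplogroup_table(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write("haplogroup\tparent\tmutations\n")
        for name in tree.preorder():
            parent, muts = tree.nodes[name]
            fh.write(
                "%s\t%s\t%s\n" % (name, parent or "", ",".join(m.label() for m in muts))
            )


def read_genotypes(path):
    """Read a genotype CSV: individual, population, then two columns per locus.

    Allele columns are named ``<locus>_1``/``<locus>_2`` (any paired suffix
    accepted); alleles are integer fragment sizes with 0 = missing.  A
    genotype with either allele missing is treated as missing at that locus.
    """
    from .popgen import GenotypeMatrix  # local import: io <-> popgen

    df = pd.read_csv(path)
    if df.shape[1] < 4:
        raise ValueError("genotype table needs individual, population and allele columns")
    ind_col, pop_col = df.columns[0], df.columns[1]
    allele_cols = list(df.columns[2:])
    if len(allele_cols) % 2:
        raise ValueError("odd number of allele columns — two per locus required")
    if df[pop_col].isna().any() or (df[pop_col].astype(str).str.strip() == "").any():
        raise ValueError("empty population label")
    loci = []
    for i in range(0, len(allele_cols), 2):
        a = allele_cols[i]
        locus = re.sub(r"[._-]?[12aAbB]$", "", a) or a
        loci.append(locus)
    alleles = df[allele_cols].to_numpy(dtype=int).reshape(len(df), len(loci), 2)
    return GenotypeMatrix(
        individuals=df[ind_col].astype(str).tolist(),
        populations=df[pop_col].astype(str).tolist(),
        loci=loci,
        alleles=alleles,
    )


def write_genotypes(G, path) -> None:
    cols = {"individual": G.individuals, "population": G.populations}
    for j, locus in enumerate(G.loci):
        cols[f"{locus}_1"] = G.alleles[:, j, 0]
        cols[f"{locus}_2"] = G.alleles[:, j, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_config(path) -> dict[str, str]:
    """Flat key=value config; '#' comments and blank lines ignored."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line without '=': {line!r}")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg
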