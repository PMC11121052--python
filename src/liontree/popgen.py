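"""Microsatellite (SSR) summary statistics, Weir–Cockerham FST and Evanno ΔK.

The FST estimator is the Weir & Cockerham (1984) theta: per-allele variance
components a (among populations), b (among individuals within populations)
and c (within individuals), combined across alleles and loci as a ratio of
sums.  Significance comes from permuting individuals among populations;
confidence intervals from a percentile bootstrap over loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenotypeMatrix:
    """Diploid genotypes: individuals x loci x 2 integer alleles (0 = missing).

    A genotype with either allele missing is dropped for that locus; allele
    pairs are unordered.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n_individuals, n_loci, 2), int

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=int)
        n = len(self.individuals)
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")
        if any(not str(p).strip() for p in self.populations):
            raise ValueError("empty population label")
        if self.alleles.shape != (n, len(self.loci), 2):
            raise ValueError(f"allele array must be ({n}, {len(self.loci)}, 2)")

    def complete(self, locus_idx: int) -> np.ndarray:
        """Boolean mask of individuals with both alleles present at a locus."""
        return (self.alleles[:, locus_idx, :] > 0).all(axis=1)

    @property
    def population_names(self) -> list[str]:
        seen = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen


@dataclass
class LocusStats:
    locus: str
    population: str
    n: int  # complete genotypes
    allele_freqs: dict[int, float]
    Ho: float
    He: float
    PIC: float
    FIS: float | None  # None (NA) when He == 0


def _freqs(alleles: np.ndarray) -> dict[int, float]:
    vals, counts = np.unique(alleles, return_counts=True)
    total = counts.sum()
    return {int(v): c / total for v, c in zip(vals, counts)}


def pic_from_freqs(p: np.ndarray) -> float:
    """Polymorphism information content: 1 - sum p^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(p, dtype=float)
    s2 = float(np.sum(p**2))
    cross = float(np.sum(np.outer(p**2, p**2))) - float(np.sum(p**4))
    return 1.0 - s2 - cross


def locus_stats(G: GenotypeMatrix) -> list[LocusStats]:
    """Per-locus, per-population Ho, Nei-unbiased He, PIC and FIS.

    He uses the small-sample correction (2n/(2n-1))(1 - sum p^2); FIS is
    1 - Ho/He, reported as None for monomorphic loci (He = 0).
    """
    out = []
    pops = np.asarray(G.populations)
    for j, locus in enumerate(G.loci):
        comp = G.complete(j)
        for pop in G.population_names:
            mask = comp & (pops == pop)
            n = int(mask.sum())
            if n == 0:
                out.append(LocusStats(locus, pop, 0, {}, float("nan"),
                                      float("nan"), float("nan"), None))
                continue
            gt = G.alleles[mask, j, :]
            freqs = _freqs(gt.ravel())
            p = np.array(list(freqs.values()))
            ho = float((gt[:, 0] != gt[:, 1]).mean())
            he = (2 * n / (2 * n - 1)) * (1 - float(np.sum(p**2))) if n > 0 else 0.0
            pic = pic_from_freqs(p)
            fis = None if he == 0 else 1 - ho / he
            out.append(LocusStats(locus, pop, n, freqs, ho, he, pic, fis))
    return out


# --- Weir & Cockerham theta ---------------------------------------------

def _wc_components(G: GenotypeMatrix, pops: np.ndarray) -> tuple[float, float, float]:
    """Summed variance components (a, b, c) over all loci and alleles."""
    pop_names = [p for p in dict.fromkeys(pops)]
    r = len(pop_names)
    if r < 2:
        raise ValueError("at least two populations required")
    A = B = C = 0.0
    for j in range(len(G.loci)):
        comp = G.complete(j)
        sizes, freqs_by_pop, het_by_pop = [], [], []
        alleles_present = set()
        for pop in pop_names:
            mask = comp & (pops == pop)
            n_i = int(mask.sum())
            if n_i == 0:
                continue
            gt = G.alleles[mask, j, :]
            sizes.append(n_i)
            f = _freqs(gt.ravel())
            freqs_by_pop.append(f)
            alleles_present.update(f)
            het_by_pop.append({
                a: float(((gt[:, 0] == a) ^ (gt[:, 1] == a)).mean())
                for a in f
            })
        if len(sizes) < 2 or len(alleles_present) < 2:
            continue
        n = np.array(sizes, dtype=float)
        ri = len(n)
        nbar = n.mean()
        nc = (ri * nbar - float(np.sum(n**2)) / (ri * nbar)) / (ri - 1)
        for allele in sorted(alleles_present):
            p_i = np.array([f.get(allele, 0.0) for f in freqs_by_pop])
            h_i = np.array([h.get(allele, 0.0) for h in het_by_pop])
            pbar = float(np.sum(n * p_i) / (ri * nbar))
            s2 = float(np.sum(n * (p_i - pbar) ** 2) / ((ri - 1) * nbar))
            hbar = float(np.sum(n * h_i) / (ri * nbar))
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (ri - 1) / ri * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (ri - 1) / ri * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            A += a
            B += b
            C += c
    if A + B + C == 0:
        raise ValueError("theta undefined: all loci monomorphic")
    return A, B, C


def _theta(G: GenotypeMatrix, pops: np.ndarray) -> float:
    a, b, c = _wc_components(G, pops)
    return a / (a + b + c)


@dataclass
class FstResult:
    scope: str  # "overall" or "pair:<p1>|<p2>"
    theta: float
    p_value: float | None = None
    ci: tuple[float, float] | None = None
    per_locus: dict[str, float] = field(default_factory=dict)


def weir_cockerham_fst(
    G: GenotypeMatrix,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
    pairwise: bool = False,
) -> list[FstResult]:
    """Multilocus Weir–Cockerham theta with permutation test and bootstrap CI.

    theta is the ratio of summed components over loci and alleles (the 1984
    convention).  The permutation test shuffles individuals among
    populations (preserving sizes); the CI is a percentile bootstrap over
    loci.  With ``pairwise=True``, per-population-pair results follow the
    overall one.
    """
    rng = np.random.default_rng(seed)
    pops = np.asarray(G.populations)
    pop_names = G.population_names
    for pop in pop_names:
        if sum(1 for j in range(len(G.loci))
               if (G.complete(j) & (pops == pop)).sum() >= 2) == 0:
            raise ValueError(f"population {pop!r} has <2 complete genotypes at every locus")

    def analyse(sub_mask: np.ndarray, scope: str) -> FstResult:
        sub = GenotypeMatrix(
            [G.individuals[i] for i in np.flatnonzero(sub_mask)],
            [G.populations[i] for i in np.flatnonzero(sub_mask)],
            G.loci,
            G.alleles[sub_mask],
        )
        sub_pops = np.asarray(sub.populations)
        theta = _theta(sub, sub_pops)
        p_value = None
        if n_perm:
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(sub_pops)
                try:
                    if _theta(sub, perm) >= theta:
                        hits += 1
                except ValueError:
                    hits += 1
            p_value = (hits + 1) / (n_perm + 1)
        ci = None
        per_locus: dict[str, float] = {}
        for j, locus in enumerate(sub.loci):
            try:
                one = GenotypeMatrix(sub.individuals, sub.populations, [locus],
                                     sub.alleles[:, [j], :])
                per_locus[locus] = _theta(one, sub_pops)
            except ValueError:
                per_locus[locus] = float("nan")
        if n_boot and len(sub.loci) > 1:
            vals = []
            for _ in range(n_boot):
                pick = rng.integers(0, len(sub.loci), size=len(sub.loci))
                boot = GenotypeMatrix(sub.individuals, sub.populations,
                                      [f"L{k}" for k in range(len(pick))],
                                      sub.alleles[:, pick, :])
                try:
                    vals.append(_theta(boot, sub_pops))
                except ValueError:
                    continue
            if vals:
                ci = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
        return FstResult(scope, theta, p_value, ci, per_locus)

    results = [analyse(np.ones(len(G.individuals), dtype=bool), "overall")]
    if pairwise:
        from itertools import combinations

        for p1, p2 in combinations(pop_names, 2):
            mask = (pops == p1) | (pops == p2)
            results.append(analyse(mask, f"pair:{p1}|{p2}"))
    return results


# --- Evanno delta-K ------------------------------------------------------

@dataclass
class EvannoResult:
    K: list[int]
    mean_lnP: dict[int, float]
    sd_lnP: dict[int, float]
    delta_K: dict[int, float]  # interior K only
    best_K: int


def evanno_delta_k(lnP: dict[int, list[float]]) -> EvannoResult:
    """Evanno's ΔK from a table of clustering log-likelihoods (runs per K).

    ΔK(K) = mean over runs of |lnP(K+1) - 2 lnP(K) + lnP(K-1)|, divided by
    the run-to-run sd of lnP(K); defined for interior K only.  Needs >=3
    consecutive K values with >=2 runs each and non-zero sd.
    """
    Ks = sorted(lnP)
    if len(Ks) < 3 or any(b - a != 1 for a, b in zip(Ks, Ks[1:])):
        raise ValueError("need >=3 consecutive K values")
    runs = {k: len(v) for k, v in lnP.items()}
    if min(runs.values()) < 2:
        raise ValueError("sd undefined: need >=2 runs per K")
    n_runs = min(runs.values())
    mean_lnP = {k: float(np.mean(lnP[k])) for k in Ks}
    sd_lnP = {k: float(np.std(lnP[k], ddof=1)) for k in Ks}
    delta = {}
    for k in Ks[1:-1]:
        if sd_lnP[k] == 0:
            raise ValueError(f"sd undefined (zero) at K={k}")
        second = [
            abs(lnP[k + 1][r] - 2 * lnP[k][r] + lnP[k - 1][r]) for r in range(n_runs)
        ]
        delta[k] = float(np.mean(second)) / sd_lnP[k]
    best = max(delta, key=delta.get)
    return EvannoResult(Ks, mean_lnP, sd_lnP, delta, best)
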