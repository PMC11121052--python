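"""Microsatellite statistics: He/Ho/PIC/FIS, Weir-Cockerham FST, Evanno dK.

Simulates four populations at a known differentiation level (Balding-
Nichols F = 0.20), computes per-locus summary statistics and the
multilocus Weir-Cockerham theta with a permutation test, then picks the
number of ancestral gene pools from a clustering likelihood table with
Evanno's delta-K.
"""

import numpy as np

import liontree as lt

G = lt.simulate_ssr(4, 0.20, 50, n_loci=7, seed=0)

print("locus   pop   n    Ho     He     PIC    FIS")
for s in lt.locus_stats(G)[:8]:
    fis = "NA" if s.FIS is None else f"{s.FIS:5.2f}"
    print(f"{s.locus:6s} {s.population:4s} {s.n:3d} {s.Ho:6.2f} {s.He:6.2f} "
          f"{s.PIC:6.2f}  {fis}")
print("  ... He is Nei's unbiased gene diversity; FIS < 0 means "
      "heterozygote excess.\n")

(fst,) = lt.weir_cockerham_fst(G, n_perm=199, n_boot=199, seed=0)
lo, hi = fst.ci
print(f"multilocus Weir-Cockerham theta = {fst.theta:.3f} "
      f"(95% bootstrap CI {lo:.3f}-{hi:.3f}), permutation p = {fst.p_value:.3f}")
print(f"simulated truth F = 0.20: the estimator recovers the "
      f"differentiation level.\n")

rng = np.random.default_rng(0)
lnp = {k: list(-500 + 50 * min(k, 5) - 5 * max(0, k - 5) + rng.normal(0, 0.1, 10))
       for k in range(1, 13)}
res = lt.evanno_delta_k(lnp)
print("K :", "  ".join(f"{k}={res.delta_K[k]:.0f}" for k in sorted(res.delta_K)))
print(f"Evanno delta-K peaks at K = {res.best_K}: the likelihood curve's "
      f"slope change marks the number of ancestral gene pools.")
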