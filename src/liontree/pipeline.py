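"""End-to-end orchestration with config, logging and a run manifest.

A run executes stages in dependency order (simulate -> classify ->
diversity -> date -> network, and/or ssr-stats -> fst -> deltak), writes
TSV outputs, and records a JSON manifest with the config snapshot, input
hashes, seed, tool version and output list.  Identical config + seed
reproduces outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import time

import pandas as pd

from . import __version__
from .io import read_config, read_genotypes, write_fasta, write_haplogroup_table
from .haplotree import classify
from .seqstats import nucleotide_diversity
from .clock import CalibratedClock, CountTree, rho_date
from .hapnet import build_network, collapse_haplotypes, write_dot, write_graphml
from .popgen import evanno_delta_k, locus_stats, weir_cockerham_fst
from .simulate import SimScenario, simulate_mitogenomes, simulate_ssr

logger = logging.getLogger("liontree")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_RUNTIME = 3

REQUIRED_KEYS = ("out_dir", "seed")


class ConfigError(ValueError):
    pass


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(cfg: dict[str, str]) -> dict[str, str]:
    for key in REQUIRED_KEYS:
        if key not in cfg:
            raise ConfigError(f"missing required config key: {key}")
    if "stages" not in cfg:
        cfg["stages"] = "simulate,classify,diversity,date,network"
    known = {"simulate", "classify", "diversity", "date", "network",
             "ssr-stats", "fst", "deltak"}
    stages = [s.strip() for s in cfg["stages"].split(",") if s.strip()]
    unknown = set(stages) - known
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    ssr_stages = {"ssr-stats", "fst", "deltak"} & set(stages)
    if ssr_stages and "genotypes" not in cfg and "ssr_simulate" not in cfg:
        raise ConfigError("ssr stages need config key 'genotypes' or 'ssr_simulate'")
    return cfg


def run_pipeline(config: dict[str, str] | str | os.PathLike) -> dict:
    """Run configured stages; returns the manifest (also written to disk).

    Partial failure leaves the outputs of completed stages in place and an
    ``errors`` entry in the manifest.
    """
    if not isinstance(config, dict):
        cfg_path = str(config)
        cfg = read_config(cfg_path)
        input_hashes = {cfg_path: _sha256(cfg_path)}
    else:
        cfg = dict(config)
        input_hashes = {}
    cfg = validate_config(cfg)
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg["seed"])
    stages = [s.strip() for s in cfg["stages"].split(",") if s.strip()]
    for key in ("genotypes", "lnp_table", "alignment"):
        if key in cfg and os.path.exists(cfg[key]):
            input_hashes[cfg[key]] = _sha256(cfg[key])

    manifest: dict = {
        "command": "run_pipeline",
        "config": cfg,
        "inputs": input_hashes,
        "seed": seed,
        "version": __version__,
        "outputs": [],
        "errors": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def out(name: str) -> str:
        path = os.path.join(out_dir, name)
        manifest["outputs"].append(name)
        return path

    truth = tree = aln = None
    try:
        if "simulate" in stages:
            from .simulate import FIXTURE_NEWICK

            scenario = SimScenario(
                newick=cfg.get("newick", FIXTURE_NEWICK),
                rate=float(cfg.get("rate", 0.01797 * 40)),
                samples_per_leaf=int(cfg.get("samples_per_leaf", 5)),
                private_mutations=int(cfg.get("private_mutations", 1)),
                locus_length=int(cfg.get("locus_length", 1040)),
                seed=seed,
            )
            truth = simulate_mitogenomes(scenario)
            aln, tree = truth.alignment, truth.tree
            write_fasta(aln, out("simulated.fasta"))
            write_haplogroup_table(tree, out("haplogroups.tsv"))

        results = None
        if "classify" in stages and aln is not None:
            rows = []
            results = {}
            for sid in aln.ids:
                if sid == aln.ref_id:
                    continue
                res = classify(sid, aln.seq(sid), tree, aln)
                results[sid] = res
                rows.append({
                    "query": sid, "haplogroup": res.haplogroup,
                    "score": round(res.score, 4),
                    "matched": len(res.matched), "missing": len(res.missing),
                    "private": len(res.private),
                    "ties": ";".join(res.ties),
                })
            pd.DataFrame(rows).to_csv(out("classification.tsv"), sep="\t", index=False)

        if "diversity" in stages and aln is not None:
            groups: dict[str, list[str]] = {}
            for sid, hg in truth.true_haplogroup.items():
                groups.setdefault(hg, []).append(sid)
            rows = [
                {
                    "scope": r.scope, "groups": "|".join(r.groups),
                    "pi_percent": round(r.pi, 4), "n_pairs": r.n_pairs,
                }
                for r in nucleotide_diversity(aln, groups)
            ]
            pd.DataFrame(rows).to_csv(out("diversity.tsv"), sep="\t", index=False)

        if "date" in stages and truth is not None:
            clock = CalibratedClock(
                rate=float(cfg.get("rate", 0.01797 * 40)),
                locus_length=truth.alignment.length,
            )
            tips = {
                sid: (hg, len(truth.sample_substitutions[sid]))
                for sid, hg in truth.true_haplogroup.items()
            }
            ctree = CountTree.from_haplogroup_tree(tree, tips)
            rows = []
            for node in tree.preorder():
                if not tree.children(node):
                    continue
                d = rho_date(ctree, node, clock)
                rows.append({
                    "node": node, "rho": round(d.rho, 4),
                    "sigma_rho": round(d.sigma_rho, 4),
                    "age_years": round(d.age_years, 1),
                    "sd_years": round(d.sd_years, 1),
                    "n_tips": d.n_tips,
                })
            pd.DataFrame(rows).to_csv(out("dated_nodes.tsv"), sep="\t", index=False)

        if "network" in stages and aln is not None:
            haps = collapse_haplotypes(
                aln.subset([i for i in aln.ids if i != aln.ref_id]),
                {sid: hg for sid, hg in truth.true_haplogroup.items()},
            )
            G = build_network(haps, tree, aln)
            write_graphml(G, out("network.graphml"))
            write_dot(G, out("network.dot"))

        if {"ssr-stats", "fst"} & set(stages):
            if "genotypes" in cfg:
                G = read_genotypes(cfg["genotypes"])
            else:
                k, f, n = (cfg.get("ssr_simulate") or "4,0.2,20").split(",")
                G = simulate_ssr(int(k), float(f), int(n), seed=seed)
            if "ssr-stats" in stages:
                rows = [
                    {
                        "locus": s.locus, "population": s.population, "n": s.n,
                        "Ho": round(s.Ho, 4), "He": round(s.He, 4),
                        "PIC": round(s.PIC, 4),
                        "FIS": "NA" if s.FIS is None else round(s.FIS, 4),
                    }
                    for s in locus_stats(G)
                ]
                pd.DataFrame(rows).to_csv(out("ssr_stats.tsv"), sep="\t", index=False)
            if "fst" in stages:
                res = weir_cockerham_fst(
                    G,
                    n_perm=int(cfg.get("n_perm", 199)),
                    n_boot=int(cfg.get("n_boot", 199)),
                    seed=seed,
                    pairwise=cfg.get("pairwise", "false").lower() == "true",
                )
                rows = [
                    {
                        "scope": r.scope, "theta": round(r.theta, 4),
                        "p_value": r.p_value,
                        "ci_low": None if r.ci is None else round(r.ci[0], 4),
                        "ci_high": None if r.ci is None else round(r.ci[1], 4),
                    }
                    for r in res
                ]
                pd.DataFrame(rows).to_csv(out("fst.tsv"), sep="\t", index=False)

        if "deltak" in stages and "lnp_table" in cfg:
            lnp_df = pd.read_csv(cfg["lnp_table"])
            lnp = {int(k): g["lnP"].tolist() for k, g in lnp_df.groupby("K")}
            res = evanno_delta_k(lnp)
            rows = [
                {"K": k, "mean_lnP": res.mean_lnP[k], "sd_lnP": res.sd_lnP[k],
                 "delta_K": res.delta_K.get(k)}
                for k in res.K
            ]
            pd.DataFrame(rows).to_csv(out("deltak.tsv"), sep="\t", index=False)
    except Exception as exc:  # partial failure: keep prior outputs + record
        logger.error("pipeline stage failed: %s", exc)
        manifest["errors"].append(str(exc))

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def main(argv: list[str] | None = None) -> int:
    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 1:
        print("usage: python -m liontree.pipeline <config>", file=sys.stderr)
        return EXIT_VALIDATION
    try:
        manifest = run_pipeline(argv[0])
    except ConfigError as exc:
        print(f"config error: {exc}", file=sys.stderr)
        return EXIT_VALIDATION
    except Exception as exc:
        print(f"error: {exc}", file=sys.stderr)
        return EXIT_RUNTIME
    return EXIT_OK if not manifest["errors"] else EXIT_RUNTIME


if __name__ == "__main__":
    raise SystemExit(main())
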