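"""End-to-end orchestration: collapse -> distances/gap -> network -> popgen
-> (optionally) ABC, from a single YAML/JSON config, with per-stage
artifacts and a combined JSON + Markdown report.

Config layout (all blocks optional except ``input`` or ``synthetic``)::

    input:     {fasta: path, metadata: path}
    synthetic: {seed: 1}          # generate a study-like dataset instead
    seed: 42                      # master seed
    trim:      {min_keep: 456}
    distances: {n_boot: 1000, deletion: pairwise, bin_width: 0.005}
    network:   {epsilon: 0}
    popgen:    {n_sims: 1000, n_boot: 100, mismatch_model: spatial,
                mu_site_year: 1.77e-8, generations_per_year: 1.0}
    abc:       {enabled: false, n_sims: 2000, k: 100, species: <label>, ...}
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc_inference as abc
from . import distances as dist
from . import mjnetwork, popgen, sequence_io, synthetic_data

log = logging.getLogger("barcodepop.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


STAGE_EXIT_CODES = {
    "load": 10,
    "trim": 11,
    "collapse": 12,
    "distances": 13,
    "network": 14,
    "popgen": 15,
    "abc": 16,
    "report": 17,
}


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    return yaml.safe_load(text)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config, "stages": {}}
    seed = int(config.get("seed", 0))

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s: start", name)
                fn()
                log.info("stage %s: done", name)
            except Exception as exc:  # halt with stage-specific context
                raise PipelineError(name, exc) from exc

        return deco

    state: dict = {}

    @stage("load")
    def _load():
        if "input" in config:
            aln = sequence_io.read_alignment(
                config["input"]["fasta"], config["input"]["metadata"]
            )
            report["stages"]["load"] = {"source": "files", "n": aln.n, "length": aln.length}
        elif "synthetic" in config:
            syn_seed = int(config["synthetic"].get("seed", seed))
            aln, truth = synthetic_data.generate_study_like(seed=syn_seed)
            synthetic_data.write_study_dataset(aln, truth, out / "synthetic")
            report["stages"]["load"] = {
                "source": "synthetic",
                "seed": syn_seed,
                "n": aln.n,
                "length": aln.length,
            }
        else:
            raise ValueError("config needs an 'input' or 'synthetic' block")
        state["aln"] = aln

    @stage("trim")
    def _trim():
        blk = config.get("trim")
        if not blk:
            report["stages"]["trim"] = {"skipped": True}
            return
        aln, dropped = sequence_io.trim_to_common_length(
            state["aln"], int(blk["min_keep"])
        )
        state["aln"] = aln
        report["stages"]["trim"] = {
            "dropped": dropped,
            "n": aln.n,
            "length": aln.length,
        }

    @stage("collapse")
    def _collapse():
        haps = sequence_io.collapse_haplotypes(state["aln"])
        sequence_io.write_haplotype_table(haps, out / "haplotypes.tsv")
        sequence_io.haplotype_fasta(haps, out / "haplotypes.fasta")
        state["haps"] = haps
        report["stages"]["collapse"] = {
            "n_haplotypes": len(haps.haplotypes),
            "n_sequences": haps.total,
        }

    @stage("distances")
    def _distances():
        blk = config.get("distances", {})
        aln = state["aln"]
        dm = dist.p_distance_matrix(aln, deletion=blk.get("deletion", "pairwise"))
        dm.write_csv(out / "distance_matrix.csv")
        gap = dist.barcoding_gap(
            dm, aln.species_of(), bin_width=float(blk.get("bin_width", 0.005))
        )
        gap.to_json(out / "gap_report.json")
        gap.histogram.to_csv(out / "gap_histogram.tsv", sep="\t", index=False)
        div = dist.group_divergence(
            aln,
            aln.species_of(),
            n_boot=int(blk.get("n_boot", 1000)),
            seed=seed,
        )
        div.to_csv(out / "species_divergence.csv", index=False)
        state["gap"] = gap
        report["stages"]["distances"] = {
            "max_intra": gap.max_intra,
            "min_inter": gap.min_inter,
            "gap_exists": gap.gap_exists,
            "threshold": gap.threshold,
        }

    @stage("network")
    def _network():
        blk = config.get("network", {})
        aln = state["aln"]
        net = mjnetwork.build_mj(
            state["haps"],
            eps=int(blk.get("epsilon", 0)),
            populations=aln.population_of(),
        )
        net.write_gml(out / "network.gml")
        net.edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        net.node_table().to_csv(out / "network_nodes.tsv", sep="\t", index=False)
        hap_species = {
            h.hap_id: aln.species_of()[h.member_ids[0]]
            for h in state["haps"].haplotypes
        }
        sep = mjnetwork.group_separation(net, hap_species)
        sep.to_csv(out / "species_separation.tsv", sep="\t", index=False)
        report["stages"]["network"] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_medians": len(net.median_nodes),
            "separations": sep.to_dict("records"),
        }

    @stage("popgen")
    def _popgen():
        blk = config.get("popgen", {})
        aln = state["aln"]
        mu = float(blk.get("mu_site_year", 1.77e-8))
        gpy = float(blk.get("generations_per_year", 1.0))
        rows = []
        for (sp, pop_aln) in _population_samples(aln):
            pop = pop_aln.records[0].population
            if pop_aln.n < 4:
                continue
            summ = popgen.population_summary(
                pop_aln,
                n_sims=int(blk.get("n_sims", 1000)),
                seed=seed,
                mismatch_model=blk.get("mismatch_model", "spatial"),
                n_boot=int(blk.get("n_boot", 100)),
            )
            et = popgen.expansion_time(summ["tau"], mu, pop_aln.length, gpy)
            summ.update(
                {
                    "species": sp,
                    "population": pop,
                    "t_expansion_years": et.t_years,
                }
            )
            obs = popgen.mismatch_observed(pop_aln)
            pd.DataFrame(
                {"differences": np.arange(len(obs)), "pairs": obs}
            ).to_csv(out / f"mismatch_{sp}_{pop}.tsv", sep="\t", index=False)
            rows.append(summ)
        df = pd.DataFrame(rows)
        df.to_csv(out / "population_summary.csv", index=False)
        report["stages"]["popgen"] = df.to_dict("records")

    @stage("abc")
    def _abc():
        blk = config.get("abc", {})
        if not blk.get("enabled", False):
            report["stages"]["abc"] = {"skipped": True}
            return
        aln = state["aln"]
        species = blk.get("species")
        sub = aln.by_species()[species] if species else aln
        pops = sorted({r.population for r in sub.records})
        if len(pops) != 3:
            raise ValueError("ABC stage needs a species with exactly 3 populations")
        # population roles: pop1 = source, pop2/pop3 = daughters; explicit
        # in the config, else alphabetical order (document in the report)
        roles = blk.get("population_roles") or dict(
            zip(pops, ("pop1", "pop2", "pop3"))
        )
        obs, _ = abc.summarize_alignment(sub, roles=roles)
        priors = synthetic_data.study_priors()
        by_role = {v: k for k, v in roles.items()}
        sizes = tuple(
            len([r for r in sub.records if r.population == by_role[role]])
            for role in ("pop1", "pop2", "pop3")
        )
        ref = abc.build_reference(
            priors,
            n_sims=int(blk.get("n_sims", 2000)),
            sample_sizes=sizes,
            L=sub.length,
            seed=seed,
        )
        k = int(blk.get("k", max(50, len(ref.df) // 20)))
        direct = abc.scenario_posterior_direct(ref, obs, k=k)
        logistic = abc.scenario_posterior_logistic(
            ref, obs, closest_fraction=float(blk.get("closest_fraction", 0.05))
        )
        chosen = max(sorted(direct), key=lambda s: direct[s])
        est = abc.estimate_parameters(
            ref, obs, chosen, closest_fraction=float(blk.get("closest_fraction", 0.05))
        )
        est["summary"].to_csv(out / "abc_posterior_summary.csv")
        report["stages"]["abc"] = {
            "population_roles": roles,
            "direct": direct,
            "logistic": logistic,
            "chosen": chosen,
            "n_reference": len(ref.df),
            "posterior_summary": est["summary"].to_dict(),
        }

    @stage("report")
    def _report():
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        (out / "report.md").write_text(_markdown_report(report))

    return report


def _population_samples(aln):
    for sp, sp_aln in aln.by_species().items():
        for pop, pop_aln in sp_aln.by_population().items():
            yield sp, pop_aln


def _markdown_report(report: dict) -> str:
    lines = ["# barcodepop run report", ""]
    for stage, payload in report["stages"].items():
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(payload, indent=2, default=str))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
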