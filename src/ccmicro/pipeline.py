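"""Configuration and end-to-end orchestration of the analysis stages.

A single :class:`RunConfig` drives every stage; all randomness flows from
one seed through per-stage child seeds, and the seed is recorded in the JSON
summary, so identical inputs + config + seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import assembly, diversity, network, neutral, robustness, simulate
from .io import (LONG_TERM, SHORT_TERM, AbundanceTable, read_abundance_table,
                 read_metadata, read_tree, write_abundance_table,
                 write_metadata, write_tree)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("diversity", "network", "robustness", "ncm", "bnti")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    # input paths; all three None -> generate the synthetic fixture
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    rank: str = "genus"
    # thresholds
    r_min: float = 0.7
    alpha: float = 0.05
    abundance_floor: float = 0.001
    max_removed_frac: float = 0.8
    n_null: int = 199
    n_boot: int = 200
    n_dominant: int = 10
    use_relative: bool = True
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        for name, lo, hi in (("r_min", 0.0, 1.0), ("alpha", 0.0, 1.0),
                             ("abundance_floor", 0.0, 1.0),
                             ("max_removed_frac", 0.0, 1.0)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.n_null < 99:
            raise ValueError("n_null must be >= 99")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")
        given = [self.table_path, self.metadata_path]
        if any(p is not None for p in given) and not all(p is not None for p in given):
            raise ValueError("table_path and metadata_path must be given together")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _load_inputs(config: RunConfig, outdir: Path, sim_seed: int):
    if config.table_path is None:
        table, metadata, tree = simulate.simulate_ccy_dataset(sim_seed)
        write_abundance_table(table, outdir / "synthetic_table.tsv")
        write_metadata(metadata, outdir / "synthetic_metadata.tsv")
        write_tree(tree, outdir / "synthetic_tree.nwk")
        return table, metadata, tree
    table = read_abundance_table(config.table_path, rank=config.rank)
    metadata = read_metadata(config.metadata_path)
    tree = read_tree(config.tree_path) if config.tree_path else None
    missing = set(table.sample_ids) - set(metadata.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    return table, metadata, tree


def _duration_samples(metadata: pd.DataFrame, cls: str) -> list[str]:
    return list(metadata.index[metadata["duration_class"] == cls])


def _write_graphml(net: network.CorrelationNetwork, topo, seed: int, path) -> None:
    g = net.graph.copy()
    if g.number_of_edges() > 0:
        communities = nx.community.louvain_communities(
            g, weight="abs_r", seed=seed)
        module_of = {}
        for i, comm in enumerate(sorted(communities, key=lambda c: sorted(c)[0])):
            for v in comm:
                module_of[v] = i
    else:
        module_of = {v: 0 for v in g.nodes}
    for v in g.nodes:
        g.nodes[v]["degree"] = g.degree(v)
        g.nodes[v]["module"] = module_of.get(v, -1)
    nx.write_graphml(g, path)


def run_pipeline(config: RunConfig, stages=ALL_STAGES) -> dict:
    """Run the requested stages, write per-stage tables, return the summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(("simulate", "diversity", "network", "robustness",
                      "ncm", "bnti"), _child_seeds(config.seed, 6)))
    if "bnti" in stages and config.table_path is not None and config.tree_path is None:
        raise PipelineError("stage bnti: tree required")
    try:
        table, metadata, tree = _load_inputs(config, outdir, seeds["simulate"])
    except Exception as exc:
        raise PipelineError(f"stage input: {exc}") from exc
    metadata = metadata.loc[table.sample_ids]
    summary: dict = {"seed": config.seed, "stages": list(stages),
                     "n_samples": table.n_samples, "n_taxa": table.n_taxa,
                     "input": "synthetic" if config.table_path is None else "files"}

    nets: dict[str, network.CorrelationNetwork] = {}
    for stage in stages:
        try:
            if stage == "diversity":
                summary["diversity"] = _stage_diversity(
                    table, metadata, config, outdir)
            elif stage == "network":
                summary["network"] = _stage_network(
                    table, metadata, config, outdir, seeds["network"], nets)
            elif stage == "robustness":
                if not nets:
                    _stage_network(table, metadata, config, outdir,
                                   seeds["network"], nets)
                summary["robustness"] = _stage_robustness(
                    nets, config, outdir, seeds["robustness"])
            elif stage == "ncm":
                summary["ncm"] = _stage_ncm(
                    table, metadata, config, outdir, seeds["ncm"])
            elif stage == "bnti":
                if tree is None:
                    raise ValueError("tree required")
                summary["bnti"] = _stage_bnti(
                    table, metadata, tree, config, outdir, seeds["bnti"])
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return summary


def _stage_diversity(table: AbundanceTable, metadata: pd.DataFrame,
                     config: RunConfig, outdir: Path) -> dict:
    alpha_df = diversity.alpha_diversity(table)
    alpha_df.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    out: dict = {}
    ccy = metadata["ccy"].to_numpy(dtype=float)
    trend_rows = []
    for metric in ("chao1", "shannon"):
        rep = diversity.test_group_differences(alpha_df[metric], metadata)
        out[f"{metric}_anova_p"] = rep.anova_p
        out[f"{metric}_short_vs_long_p"] = rep.ttest_p
        fit = diversity.fit_ccy_trend(alpha_df[metric].loc[metadata.index], ccy)
        trend_rows.append({"metric": metric, "model": "linear",
                           "r2": fit.r2, "pearson_r": fit.pearson_r,
                           "p": fit.p_value})
        out[f"{metric}_ccy_r"] = fit.pearson_r
    bc = diversity.bray_curtis(table)
    bc.to_csv(outdir / "bray_curtis.tsv", sep="\t")
    ord_res = diversity.pcoa(bc)
    ord_res.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
    out["pcoa_explained"] = [float(e) for e in ord_res.explained[:2]]
    if ord_res.coordinates.shape[1] >= 2:
        fit = diversity.fit_ccy_trend(
            ord_res.coordinates["PCo2"].loc[metadata.index], ccy)
        trend_rows.append({"metric": "PCo2", "model": "linear", "r2": fit.r2,
                           "pearson_r": fit.pearson_r, "p": fit.p_value})
        out["pco2_ccy_r"] = fit.pearson_r
    # dominant-taxon abundance trends (top-N by grand mean relative abundance)
    rel = table.relative()
    order = np.argsort(rel.values.mean(axis=1))[::-1][:config.n_dominant]
    dom_sum = rel.values[order].sum(axis=0)
    for model in ("linear", "quadratic"):
        fit = diversity.fit_ccy_trend(dom_sum, ccy, model=model)
        trend_rows.append({"metric": "dominant_abundance", "model": model,
                           "r2": fit.r2, "pearson_r": fit.pearson_r,
                           "p": fit.p_value})
        out[f"dominant_{model}_r2"] = fit.r2
    pd.DataFrame(trend_rows).to_csv(outdir / "ccy_trends.tsv", sep="\t",
                                    index=False)
    return out


def _stage_network(table: AbundanceTable, metadata: pd.DataFrame,
                   config: RunConfig, outdir: Path, seed: int,
                   nets: dict) -> dict:
    out = {}
    topo_rows = []
    for label, cls in (("short_term", SHORT_TERM), ("long_term", LONG_TERM)):
        samples = _duration_samples(metadata, cls)
        if len(samples) < 4:
            raise ValueError(f"duration class {label} has fewer than 4 samples")
        sub = table.subset_samples(samples)
        net = network.cooccurrence_network(
            sub, r_min=config.r_min, alpha=config.alpha,
            floor=config.abundance_floor, use_relative=config.use_relative,
            group=label)
        nets[label] = net
        net.edges.to_csv(outdir / f"network_edges_{label}.tsv", sep="\t",
                         index=False)
        topo = network.topology(net, seed=seed)
        _write_graphml(net, topo, seed, outdir / f"network_{label}.graphml")
        topo_rows.append(topo.to_series(label))
        out[label] = {"n_nodes": topo.n_nodes, "n_edges": topo.n_edges,
                      "modularity": topo.modularity,
                      "pct_negative_edges": topo.pct_negative_edges}
    pd.DataFrame(topo_rows).to_csv(outdir / "network_topology.tsv", sep="\t",
                                   index_label="group")
    return out


def _stage_robustness(nets: dict, config: RunConfig, outdir: Path,
                      seed: int) -> dict:
    out = {}
    curves = {}
    for label, net in nets.items():
        if net.n_nodes < 2 or net.n_edges == 0:
            out[label] = {"degenerate": True}
            continue
        curve = robustness.attack_curve(
            net, strategy="highest_degree", max_frac=config.max_removed_frac,
            seed=seed)
        curves[label] = curve
        curve.steps.to_csv(outdir / f"robustness_{label}.tsv", sep="\t",
                           index=False)
        out[label] = {"initial_connectivity": curve.initial,
                      "n_steps": len(curve.steps) - 1}
    if len(curves) == 2:
        a, b = (curves[k] for k in ("short_term", "long_term"))
        cmp_res = robustness.compare_curves(a, b)
        pd.DataFrame([{
            "curve_a": "short_term", "curve_b": "long_term",
            "wilcoxon_w": cmp_res.statistic, "p": cmp_res.p_value,
            "median_difference": cmp_res.median_difference,
            "n_points": cmp_res.n_points, "note": cmp_res.note,
        }]).to_csv(outdir / "robustness_comparison.tsv", sep="\t", index=False)
        out["comparison"] = {"wilcoxon_p": cmp_res.p_value,
                             "median_difference": cmp_res.median_difference}
    return out


def _stage_ncm(table: AbundanceTable, metadata: pd.DataFrame,
               config: RunConfig, outdir: Path, seed: int) -> dict:
    out = {}
    summary_rows = []
    jobs = [("all", list(table.sample_ids))]
    for label, cls in (("short_term", SHORT_TERM), ("long_term", LONG_TERM)):
        jobs.append((label, _duration_samples(metadata, cls)))
    for label, samples in jobs:
        if len(samples) < 3:
            continue
        fit = neutral.fit_ncm(table.subset_samples(samples),
                              n_boot=config.n_boot, seed=seed)
        fit.per_taxon.to_csv(outdir / f"ncm_taxa_{label}.tsv", sep="\t")
        above, within, below = neutral.summarize_fractions(fit)
        summary_rows.append({
            "group": label, "m": fit.m, "Nm": fit.nm, "N": fit.N,
            "rsqr": fit.rsqr, "n_boot": fit.n_boot, "seed": seed,
            "pct_above": above, "pct_within": within, "pct_below": below,
        })
        out[label] = {"m": fit.m, "Nm": fit.nm, "rsqr": fit.rsqr,
                      "pct_within": within}
    pd.DataFrame(summary_rows).to_csv(outdir / "ncm_summary.tsv", sep="\t",
                                      index=False)
    return out


def _stage_bnti(table: AbundanceTable, metadata: pd.DataFrame, tree,
                config: RunConfig, outdir: Path, seed: int) -> dict:
    result = assembly.beta_nti(table, tree, n_null=config.n_null, seed=seed)
    result.pairs.to_csv(outdir / "bnti_pairs.tsv", sep="\t", index=False)
    out = {}
    rows = []
    for grouping in ("within_short", "within_long", "between"):
        try:
            summ = assembly.summarize_assembly(result, metadata, grouping)
        except ValueError:
            continue
        rows.append(summ.__dict__)
        out[grouping] = {"pct_heterogeneous": summ.pct_heterogeneous,
                         "pct_stochastic": summ.pct_stochastic}
    pd.DataFrame(rows).to_csv(outdir / "bnti_summary.tsv", sep="\t", index=False)
    return out
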