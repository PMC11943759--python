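"""End-to-end orchestration: diversity -> ordination -> network -> stability.

Every stage draws from a substream derived from the run seed and the stage
name, so repeated runs with the same :class:`RunConfig` are bit-identical
and adding randomness to one stage never shifts another. All outputs are
stamped with the config hash and seed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import network as nw
from . import ordination as od
from . import stability as st
from .containers import (
    CoNetwork, EnvTable, OtuTable, RunConfig, TaxonomyMap, ValidationError,
)
from .io import write_network, write_otu_table


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ResultBundle:
    """All stage outputs of one pipeline run plus provenance."""

    rarefied: OtuTable
    alpha: pd.DataFrame
    alpha_compare: dv.GroupCompareResult
    venn: pd.DataFrame
    phylum_abundance: pd.DataFrame
    distances: pd.DataFrame
    pcoa: od.OrdinationResult
    permanova: dict
    rda: od.OrdinationResult | None
    taxa_env: pd.DataFrame | None
    networks: dict[str, CoNetwork]
    topology: pd.DataFrame
    node_roles: dict[str, pd.DataFrame]
    stability: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write every tabular output (and networks) under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_otu_table(self.rarefied, outdir / "rarefied_counts.tsv")
        self.alpha.rename_axis("sample_id").to_csv(
            outdir / "alpha_diversity.tsv", sep="\t")
        self.alpha_compare.summary.to_csv(
            outdir / "alpha_group_compare.tsv", sep="\t")
        self.alpha_compare.letters.rename_axis("variable").to_csv(
            outdir / "alpha_letters.tsv", sep="\t")
        self.venn.to_csv(outdir / "otu_venn_regions.tsv", sep="\t", index=False)
        self.phylum_abundance.rename_axis("sample_id").to_csv(
            outdir / "phylum_relative_abundance.tsv", sep="\t")
        self.distances.rename_axis("sample_id").to_csv(
            outdir / "bray_curtis.tsv", sep="\t")
        self.pcoa.coordinates.rename_axis("sample_id").to_csv(
            outdir / "pcoa_coordinates.tsv", sep="\t")
        pd.DataFrame({
            "eigenvalue": self.pcoa.eigenvalues,
            "proportion": self.pcoa.proportion_explained,
        }).rename_axis("axis").to_csv(outdir / "pcoa_eigenvalues.tsv", sep="\t")
        pd.Series(self.permanova).to_csv(outdir / "permanova.tsv", sep="\t",
                                         header=False)
        if self.rda is not None:
            self.rda.coordinates.rename_axis("sample_id").to_csv(
                outdir / "rda_coordinates.tsv", sep="\t")
            pd.DataFrame({
                "eigenvalue": self.rda.eigenvalues,
                "proportion": self.rda.proportion_explained,
            }).rename_axis("axis").to_csv(outdir / "rda_eigenvalues.tsv", sep="\t")
            self.rda.biplot_scores.rename_axis("covariate").to_csv(
                outdir / "rda_biplot_scores.tsv", sep="\t")
        if self.taxa_env is not None:
            self.taxa_env.to_csv(outdir / "taxa_env_correlation.tsv",
                                 sep="\t", index=False)
        self.topology.to_csv(outdir / "network_topology.tsv", sep="\t",
                             index=False)
        self.stability.to_csv(outdir / "stability_report.tsv", sep="\t",
                              index=False)
        for group, net in self.networks.items():
            write_network(net, outdir / f"network_{group}.graphml")
            write_network(net, outdir / f"network_{group}.edgelist.tsv",
                          format="edgelist")
        for group, roles in self.node_roles.items():
            roles.rename_axis("node").to_csv(
                outdir / f"node_roles_{group}.tsv", sep="\t")
        # timings are wall-clock and would break byte-level reproducibility
        prov = pd.Series({k: v for k, v in self.provenance.items()
                          if k not in ("config", "timings")})
        prov.to_csv(outdir / "provenance.tsv", sep="\t", header=False)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise StageError(name, exc) from exc
            return out, time.perf_counter() - t0
        return wrapped
    return deco


def run_pipeline(config: RunConfig, otu: OtuTable, taxonomy: TaxonomyMap,
                 env: EnvTable, rda_covariates: list[str] | None = None
                 ) -> ResultBundle:
    """Run every analysis stage on one cohort.

    ``rda_covariates`` selects the environment columns entering the RDA;
    by default all numeric covariates are used (when any exist and the
    sample count allows).
    """
    otu.require_analysable()
    env.require_covering(otu)
    env.require_replication()
    env = env.aligned_to(otu.sample_ids)
    timings: dict[str, float] = {}

    @_stage("rarefaction")
    def _rarefy():
        return dv.rarefy(otu, config.rarefaction_fraction,
                         seed=config.stage_rng("rarefaction"))

    rarefied, timings["rarefaction"] = _rarefy()

    @_stage("diversity")
    def _diversity():
        alpha = dv.alpha_diversity(rarefied, config.simpson_convention)
        compare = dv.group_compare(alpha, env.group, alpha=config.alpha)
        venn = dv.otu_set_partition(rarefied, env)
        phylum = dv.aggregate_taxa(rarefied, taxonomy, "phylum")
        return alpha, compare, venn, phylum

    (alpha, compare, venn, phylum), timings["diversity"] = _diversity()

    @_stage("ordination")
    def _ordination():
        dist = od.bray_curtis(rarefied)
        pc = od.pcoa(dist)
        perm = od.permanova(dist, env.group, n_perm=config.n_permutations,
                            seed=config.stage_rng("permanova"))
        covs = env.covariates
        if rda_covariates is not None:
            covs = covs[list(rda_covariates)]
        rda_res, corr = None, None
        if covs.shape[1] and covs.shape[0] > covs.shape[1]:
            transform = "hellinger" if config.hellinger else "none"
            rda_res = od.rda(rarefied.counts, covs, transform=transform)
            corr = od.taxa_env_correlation(
                phylum, covs, method=config.correlation_method, adjust="none")
        return dist, pc, perm, rda_res, corr

    (dist, pc, perm, rda_res, corr), timings["ordination"] = _ordination()

    @_stage("network")
    def _network():
        networks, roles, topo_rows = {}, {}, []
        for group in env.groups:
            samples = env.samples_in(group)
            if len(samples) < config.min_group_n:
                raise ValidationError(
                    f"group {group!r} has {len(samples)} samples; "
                    f"correlation networks need at least {config.min_group_n}")
            sub = rarefied.select_samples(samples)
            dominant = nw.filter_dominant(sub, config.min_mean_rel_abund,
                                          config.min_prevalence)
            r, p = nw.correlation_matrix(dominant, config.correlation_method)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = nw.build_network(
                    r, p, r_min=config.r_min, p_max=config.p_max,
                    adjust=config.p_adjust, otu=dominant, tax=taxonomy,
                    group=group)
            if net.n_edges:
                _, q = nw.detect_modules(net)
                roles[group] = nw.zi_pi(net, zi_hub=config.zi_hub,
                                        pi_connector=config.pi_connector)
                for node, row in roles[group].iterrows():
                    net.graph.nodes[node]["zi"] = float(row["zi"])
                    net.graph.nodes[node]["pi"] = float(row["pi"])
                    net.graph.nodes[node]["role"] = row["role"]
                topo = nw.topology(net)
            else:
                roles[group] = pd.DataFrame(
                    columns=["module", "degree", "zi", "pi", "role",
                             "isolated"])
                topo = {"nodes": net.n_nodes, "edges": 0,
                        "path_length": np.nan, "clustering": np.nan,
                        "density": np.nan, "mean_degree": np.nan,
                        "modularity": np.nan}
            topo["group"] = group
            topo_rows.append(topo)
            networks[group] = net
        topo_table = pd.DataFrame(topo_rows)
        return networks, roles, topo_table[
            ["group"] + [c for c in topo_table.columns if c != "group"]]

    (networks, roles, topo_table), timings["network"] = _network()

    @_stage("stability")
    def _stability():
        rows = []
        for group, net in networks.items():
            if net.n_edges == 0 or net.n_nodes < 3:
                rows.append({"group": group, "nodes": net.n_nodes,
                             "edges": net.n_edges})
                continue
            q = topo_table.set_index("group").loc[group, "modularity"]
            rows.append(st.stability_report(
                net, roles=roles[group], modularity_q=q,
                fraction=config.removal_fraction,
                replicates=config.removal_replicates,
                seed=config.stage_rng(f"stability:{group}")))
        return pd.DataFrame(rows)

    stability_table, timings["stability"] = _stability()

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timings": {k: round(v, 4) for k, v in timings.items()},
    }
    return ResultBundle(
        rarefied=rarefied, alpha=alpha, alpha_compare=compare, venn=venn,
        phylum_abundance=phylum, distances=dist, pcoa=pc, permanova=perm,
        rda=rda_res, taxa_env=corr, networks=networks, topology=topo_table,
        node_roles=roles, stability=stability_table, provenance=provenance,
    )
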