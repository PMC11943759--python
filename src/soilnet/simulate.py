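"""Synthetic grouped OTU cohorts with known (planted) structure.

The generator follows a latent-Gaussian copula: per group, each sample's
log-abundance vector is drawn from a multivariate normal whose mean encodes
the group's rank-abundance profile (lognormal species-abundance curve) and
whose covariance contains planted correlation blocks among the dominant
taxa. The latent vector is pushed through a softmax to a composition and
counts are drawn multinomially at the sample's sequencing depth, so every
sample's depth is conserved exactly. Environmental covariates are standard
normal per sample and feed back linearly into the latent abundances of
their affected taxa.

Planted truths — block memberships, group richness, covariate effects —
are returned alongside the tables so every downstream stage can be scored
against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    CoNetwork, EnvTable, OtuTable, TAXONOMY_RANKS, TaxonomyMap,
    ValidationError,
)

# taxon pool used to fabricate plausible-looking lineages; phyla echo the
# dominant groups of temperate soil communities
_PHYLA = ("Actinobacteriota", "Proteobacteria", "Acidobacteriota",
          "Chloroflexi", "Firmicutes", "Bacteroidota", "Gemmatimonadota",
          "Myxococcota", "Verrucomicrobiota", "Planctomycetota")


@dataclass
class GroupSpec:
    """One sample group: size, richness and abundance-profile shape.

    ``evenness`` is the standard deviation of the lognormal rank-abundance
    profile: 0 gives a perfectly even community, larger values a steeper
    dominance curve. ``depth_mean`` / ``depth_sigma`` parameterise the
    lognormal sequencing-depth distribution.
    """

    name: str
    n_samples: int = 10
    richness: int = 400
    evenness: float = 1.0
    depth_mean: float = 20000.0
    depth_sigma: float = 0.2


@dataclass
class BlockSpec:
    """A planted correlation module among consecutive dominant taxa.

    ``rho`` is the within-block latent correlation; ``negative_fraction``
    of the members anti-correlate with the rest of the block.
    """

    size: int
    rho: float = 0.8
    negative_fraction: float = 0.0


@dataclass
class EnvEffectSpec:
    """A covariate with a linear effect on a set of taxa's latent abundance."""

    name: str
    n_taxa: int = 10
    effect: float = 1.0
    noise_sd: float = 0.5


@dataclass
class SimSpec:
    """Full description of a synthetic cohort."""

    groups: list[GroupSpec] = field(default_factory=lambda: [
        GroupSpec("forest", 10, 400, 1.2),
        GroupSpec("arable", 10, 700, 1.0),
        GroupSpec("wetland", 10, 500, 1.1),
    ])
    blocks: list[BlockSpec] = field(default_factory=lambda: [
        BlockSpec(12, 0.9), BlockSpec(12, 0.9), BlockSpec(10, 0.9),
        BlockSpec(10, 0.9, negative_fraction=0.2),
    ])
    env_effects: list[EnvEffectSpec] = field(default_factory=lambda: [
        EnvEffectSpec("pH", 12, 1.0), EnvEffectSpec("SOM", 12, 1.0),
        EnvEffectSpec("TN", 10, 0.8), EnvEffectSpec("AN", 10, 0.8),
    ])
    latent_sd: float = 1.0
    # global taxon pool size relative to the largest group richness;
    # the excess is what permits group-exclusive taxa
    pool_factor: float = 1.4
    # abundance rank at which planted blocks begin: co-occurrence guilds sit
    # among dominant-but-not-top specialists, and keeping the extreme head
    # unconstrained limits compositional-closure distortion of the planted
    # correlations
    block_rank_start: int = 10
    # per-group taxon-level shifts of the latent mean: land-use types host
    # distinct communities, so compositions must separate between groups
    group_effect_sd: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValidationError("need at least one group")
        for g in self.groups:
            if g.n_samples < 3:
                raise ValidationError(f"group {g.name!r}: need n >= 3 samples")
            if g.richness < 2:
                raise ValidationError(f"group {g.name!r}: need richness >= 2")
        total_block = self.block_rank_start + sum(b.size for b in self.blocks)
        min_s = min(g.richness for g in self.groups)
        if total_block > min_s:
            raise ValidationError(
                f"blocks end at rank {total_block} but the smallest group "
                f"richness is {min_s}")
        for b in self.blocks:
            if not -1 < b.rho < 1:
                raise ValidationError(f"block rho must be in (-1, 1), got {b.rho}")


def _block_correlation(block: BlockSpec, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Signed within-block correlation matrix and its Cholesky factor."""
    signs = np.ones(block.size)
    n_neg = int(round(block.negative_fraction * block.size))
    if n_neg:
        signs[rng.choice(block.size, size=n_neg, replace=False)] = -1.0
    corr = np.outer(signs, signs) * block.rho
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValidationError(
            f"planted block correlation (rho={block.rho}, size={block.size}) "
            f"is not positive definite; use a smaller rho") from None
    return corr, chol


def _make_taxonomy(otu_ids: list[str], rng: np.random.Generator) -> TaxonomyMap:
    phyla = rng.choice(_PHYLA, size=len(otu_ids))
    frame = pd.DataFrame(index=pd.Index(otu_ids, name="otu_id"))
    frame["domain"] = "Bacteria"
    frame["phylum"] = phyla
    for rank in TAXONOMY_RANKS[2:]:
        frame[rank] = [f"{p}_{rank[:3]}{i % 7}" for i, p in enumerate(phyla)]
    return TaxonomyMap(frame)


def simulate_counts(spec: SimSpec | None = None,
                    seed: int | np.random.Generator | None = None
                    ) -> tuple[OtuTable, TaxonomyMap, EnvTable, dict]:
    """Draw a grouped cohort: counts, taxonomy, environment and truth.

    Returns ``(otu, taxonomy, env, truth)`` where ``truth`` records the
    planted block memberships (over the shared dominant taxa), the per-group
    mean latent profile, and the covariate -> taxa effect map.
    """
    spec = spec or SimSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    # the taxon pool is larger than any single group's richness: groups
    # share the dominant core (head + planted blocks) but draw their tail
    # taxa independently, which yields group-exclusive OTUs as in real
    # land-use contrasts
    s_core = spec.block_rank_start + sum(b.size for b in spec.blocks)
    s_max = max(g.richness for g in spec.groups)
    s_pool = max(int(np.ceil(spec.pool_factor * s_max)), s_max)
    otu_ids = [f"OTU{i + 1:05d}" for i in range(s_pool)]

    # planted blocks occupy consecutive ranks just below the extreme head,
    # i.e. dominant taxa that still pass any sensible dominance filter
    block_members: list[list[int]] = []
    chols = []
    cursor = spec.block_rank_start
    for block in spec.blocks:
        members = list(range(cursor, cursor + block.size))
        block_members.append(members)
        _, chol = _block_correlation(block, rng)
        chols.append(chol)
        cursor += block.size

    # covariate effects target taxa cycling over the blocks so that env
    # structure and module structure overlap, as they do in real soils
    env_targets: dict[str, list[int]] = {}
    pool = [i for members in block_members for i in members] or list(range(s_max))
    for k, eff in enumerate(spec.env_effects):
        start = (k * 7) % max(len(pool) - eff.n_taxa, 1)
        env_targets[eff.name] = pool[start:start + eff.n_taxa]

    counts_rows, env_rows, sample_ids, group_labels = [], [], [], []
    group_profiles = {}
    for g in spec.groups:
        s = g.richness
        # lognormal rank-abundance profile, sorted so the shared core
        # (head + planted blocks) holds the dominant taxa; the tail is a
        # group-specific draw from the remaining pool
        base = np.sort(rng.normal(0.0, g.evenness, size=s))[::-1]
        tail = rng.choice(np.arange(s_core, s_pool), size=s - s_core,
                          replace=False)
        present = np.concatenate([np.arange(s_core), tail])
        profile = np.full(s_pool, -np.inf)
        profile[present] = base
        if spec.group_effect_sd > 0:
            profile[present] += rng.normal(0.0, spec.group_effect_sd, size=s)
        group_profiles[g.name] = profile.copy()
        if g.depth_mean <= 0:
            depths = np.zeros(g.n_samples, dtype=np.int64)
        else:
            depths = rng.lognormal(np.log(g.depth_mean), g.depth_sigma,
                                   size=g.n_samples).astype(np.int64)
        cov_values = {eff.name: rng.normal(0.0, 1.0, size=g.n_samples)
                      for eff in spec.env_effects}
        for j in range(g.n_samples):
            z = np.where(np.isfinite(profile), profile, -np.inf).copy()
            noise = rng.normal(0.0, spec.latent_sd, size=s_pool)
            for members, chol in zip(block_members, chols):
                m = np.array(members)
                noise[m] = spec.latent_sd * (chol @ rng.normal(size=len(m)))
            z = z + np.where(np.isfinite(z), noise, 0.0)
            for eff in spec.env_effects:
                idx = np.array(env_targets[eff.name])
                z[idx] += eff.effect * cov_values[eff.name][j] \
                    + rng.normal(0.0, eff.noise_sd, size=len(idx))
            finite = np.isfinite(z)
            p = np.zeros(s_pool)
            zmax = z[finite].max()
            p[finite] = np.exp(z[finite] - zmax)
            p /= p.sum()
            depth = int(depths[j])
            if depth == 0:
                warnings.warn(f"sample with zero depth in group {g.name!r}",
                              stacklevel=2)
                counts_rows.append(np.zeros(s_pool, dtype=np.int64))
            else:
                counts_rows.append(rng.multinomial(depth, p))
            sid = f"{g.name}_{j + 1:02d}"
            sample_ids.append(sid)
            group_labels.append(g.name)
            env_rows.append({"sample_id": sid, "group": g.name,
                             **{name: cov_values[name][j]
                                for name in cov_values}})

    counts = pd.DataFrame(np.array(counts_rows, dtype=np.int64),
                          index=pd.Index(sample_ids, name="sample_id"),
                          columns=otu_ids)
    otu = OtuTable(counts)
    tax = _make_taxonomy(otu_ids, rng)
    env = EnvTable(pd.DataFrame(env_rows).set_index("sample_id"))
    truth = {
        "block_members": [[otu_ids[i] for i in members]
                          for members in block_members],
        "block_rho": [b.rho for b in spec.blocks],
        "env_targets": {name: [otu_ids[i] for i in idx]
                        for name, idx in env_targets.items()},
        "env_effects": {e.name: e.effect for e in spec.env_effects},
        "group_richness": {g.name: g.richness for g in spec.groups},
        "group_evenness": {g.name: g.evenness for g in spec.groups},
        "seed": spec.seed if seed is None else None,
    }
    return otu, tax, env, truth


def planted_partition_graph(k_blocks: int, block_size: int, p_in: float,
                            p_out: float,
                            seed: int | np.random.Generator = 0) -> CoNetwork:
    """Benchmark graph with known communities for module-detection tests.

    Edges appear independently with probability ``p_in`` within a block and
    ``p_out`` between blocks; the true block label is stored on each node
    as ``true_block``.
    """
    if not 0 <= p_out <= p_in <= 1:
        raise ValidationError("need 0 <= p_out <= p_in <= 1")
    if k_blocks < 1 or block_size < 1:
        raise ValidationError("k_blocks and block_size must be >= 1")
    rng = np.random.default_rng(seed)
    n = k_blocks * block_size
    labels = np.repeat(np.arange(k_blocks), block_size)
    graph = nx.Graph()
    for i in range(n):
        graph.add_node(i, true_block=int(labels[i]))
    iu, ju = np.triu_indices(n, k=1)
    prob = np.where(labels[iu] == labels[ju], p_in, p_out)
    draw = rng.random(len(iu)) < prob
    graph.add_edges_from(zip(iu[draw].tolist(), ju[draw].tolist()))
    return CoNetwork(graph, params={"p_in": p_in, "p_out": p_out,
                                    "k_blocks": k_blocks,
                                    "block_size": block_size})
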