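"""Rarefaction, alpha diversity, OTU set partitions, taxonomic aggregation
and per-variable group comparisons.

Alpha-diversity estimators follow the mothur-style conventions common in
amplicon studies: Shannon in nats over nonzero proportions, Simpson either
as the dominance form (sum p_i^2) or its complement, bias-corrected Chao1
``S + F1(F1-1) / (2(F2+1))``, ACE with the rare-species cutoff at 10, and
Good's coverage ``1 - F1/N``.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import alpha as skb_alpha
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .containers import (
    EnvTable, OtuTable, TaxonomyMap, UNCLASSIFIED, ValidationError,
)

ALPHA_INDICES = ("sobs", "shannon", "simpson", "ace", "chao1", "coverage")


def rarefy(otu: OtuTable, fraction: float = 0.90,
           seed: int | np.random.Generator = 0) -> OtuTable:
    """Subsample every sample, without replacement, to a common depth.

    The target depth is ``floor(fraction * min sample depth)``. OTUs whose
    column becomes all-zero are retained and listed under
    ``flags['zero_otus']``.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    depths = otu.depths
    if (depths == 0).any():
        empty = list(depths.index[depths == 0])
        raise ValidationError(f"samples with zero depth cannot be rarefied: {empty}")
    target = int(np.floor(fraction * depths.min()))
    if target == 0:
        raise ValidationError(
            f"target depth is 0 at fraction={fraction} "
            f"(min depth {int(depths.min())}); increase the fraction")
    rng = np.random.default_rng(seed)
    out = np.empty_like(otu.counts.to_numpy())
    for i, row in enumerate(otu.counts.to_numpy()):
        # multivariate hypergeometric == exact subsampling without replacement
        out[i] = rng.multivariate_hypergeometric(row, target)
    rarefied = pd.DataFrame(out, index=otu.counts.index, columns=otu.counts.columns)
    zero = list(rarefied.columns[(rarefied == 0).all(axis=0)])
    flags = dict(otu.flags)
    flags["zero_otus"] = zero
    flags["rarefaction_depth"] = target
    return OtuTable(rarefied, flags=flags)


def _alpha_row(counts: np.ndarray, simpson_convention: str) -> dict:
    if counts.sum() == 0:
        return {k: np.nan for k in ALPHA_INDICES}
    dominance = skb_alpha.dominance(counts)
    try:
        ace = float(skb_alpha.ace(counts, rare_threshold=10))
    except ValueError:
        # ACE is undefined when every rare taxon is a singleton
        ace = np.nan
    return {
        "sobs": float(skb_alpha.sobs(counts)),
        "shannon": float(skb_alpha.shannon(counts, base=np.e)),
        "simpson": float(dominance if simpson_convention == "dominance"
                         else 1.0 - dominance),
        "ace": ace,
        "chao1": float(skb_alpha.chao1(counts, bias_corrected=True)),
        "coverage": float(skb_alpha.goods_coverage(counts)),
    }


def alpha_diversity(otu: OtuTable,
                    simpson_convention: str = "dominance") -> pd.DataFrame:
    """Per-sample alpha diversity table (samples x indices).

    All-zero samples yield NaN for every index rather than a misleading 0.
    The returned frame carries ``attrs['simpson_convention']``.
    """
    if simpson_convention not in ("dominance", "complement"):
        raise ValidationError(f"unknown Simpson convention {simpson_convention!r}")
    rows = [_alpha_row(r, simpson_convention) for r in otu.counts.to_numpy()]
    result = pd.DataFrame(rows, index=otu.counts.index)[list(ALPHA_INDICES)]
    result.attrs["simpson_convention"] = simpson_convention
    return result


def _presence_sets(otu: OtuTable, env: EnvTable) -> dict[str, set]:
    env.require_covering(otu)
    sets = {}
    for g in env.groups:
        samples = [s for s in env.samples_in(g) if s in otu.counts.index]
        if not samples:
            sets[g] = set()
            continue
        present = (otu.counts.loc[samples] > 0).any(axis=0)
        sets[g] = set(present.index[present])
    return sets


def otu_set_partition(otu: OtuTable, env: EnvTable) -> pd.DataFrame:
    """Shared/unique OTU counts per group (Venn regions for <= 3 groups).

    An OTU is present in a group iff it is nonzero in at least one of that
    group's samples. Returns one row per region with its member count; the
    OTU identifiers themselves are kept in ``attrs['members']``.
    """
    sets = _presence_sets(otu, env)
    groups = list(sets)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups for a set partition")
    rows, members = [], {}
    if len(groups) <= 3:
        for k in range(1, len(groups) + 1):
            for combo in itertools.combinations(groups, k):
                inside = set.intersection(*(sets[g] for g in combo))
                outside = set.union(set(), *(sets[g] for g in groups if g not in combo))
                region = inside - outside
                name = "&".join(combo)
                rows.append({"region": name, "n_groups": k, "count": len(region)})
                members[name] = sorted(region)
    else:
        union_others = {g: set.union(*(sets[h] for h in groups if h != g))
                        for g in groups}
        for g in groups:
            unique = sets[g] - union_others[g]
            rows.append({"region": g, "n_groups": 1, "count": len(unique)})
            members[g] = sorted(unique)
        core = set.intersection(*sets.values())
        rows.append({"region": "&".join(groups), "n_groups": len(groups),
                     "count": len(core)})
        members["&".join(groups)] = sorted(core)
    for g in groups:
        rows.append({"region": f"total:{g}", "n_groups": 1, "count": len(sets[g])})
    result = pd.DataFrame(rows)
    result.attrs["members"] = members
    return result


def aggregate_taxa(otu: OtuTable, tax: TaxonomyMap, rank: str = "phylum",
                   top_k: int | None = None) -> pd.DataFrame:
    """Relative abundance per sample aggregated at a taxonomic rank.

    OTUs without a mapping are pooled under 'unclassified'. With ``top_k``,
    all but the k most abundant taxa (by mean) collapse into 'others'.
    Rows sum to 1 except for all-zero samples, which are NaN.
    """
    lineage = tax.rank(rank)
    labels = pd.Series(
        [lineage.get(o, UNCLASSIFIED) for o in otu.otu_ids], index=otu.otu_ids)
    rel = otu.relative_abundance()
    agg = rel.T.groupby(labels).sum(min_count=1).T
    agg = agg[agg.mean(axis=0).sort_values(ascending=False).index]
    if top_k is not None and agg.shape[1] > top_k:
        keep = agg.columns[:top_k]
        others = agg.drop(columns=keep).sum(axis=1)
        agg = agg[list(keep)].copy()
        agg["others"] = others
    return agg


@dataclass
class GroupCompareResult:
    """ANOVA + Tukey HSD + compact letter display for a set of variables."""

    summary: pd.DataFrame           # variable x (per-group mean/sd, F, p)
    pairwise: pd.DataFrame          # long: variable, group1, group2, p_adj
    letters: pd.DataFrame           # variable x group -> letter string


def _letters_from_significance(groups: list[str], sig: dict[frozenset, bool],
                               means: pd.Series) -> dict[str, str]:
    """Compact letter display via maximal cliques of the non-significant graph.

    Two groups share a letter iff their difference is not significant; each
    letter labels one maximal clique. Letters are ordered by descending
    group mean so 'a' always marks the top group.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    for a, b in itertools.combinations(groups, 2):
        if not sig[frozenset((a, b))]:
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: (-max(means[m] for m in c), sorted(c)))
    letters = {grp: "" for grp in groups}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for grp in clique:
            letters[grp] += letter
    return letters


def group_compare(values: pd.DataFrame, group: pd.Series,
                  alpha: float = 0.05) -> GroupCompareResult:
    """One-way ANOVA per variable with Tukey HSD and letter display.

    ``values`` holds one column per variable, indexed like ``group``.
    Degenerate variables (zero variance within every group) are flagged in
    the summary and lettered from exact equality of group means.
    """
    group = group.loc[values.index].astype(str)
    groups = sorted(group.unique())
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if group.value_counts().min() < 2:
        raise ValidationError("every group needs at least 2 samples")

    sum_rows, pair_rows, letter_rows = [], [], {}
    for var in values.columns:
        x = values[var].astype(float)
        ok = x.notna()
        xs = [x[ok & (group == g)].to_numpy() for g in groups]
        means = pd.Series([v.mean() for v in xs], index=groups)
        sds = pd.Series([v.std(ddof=1) for v in xs], index=groups)
        degenerate = all(np.allclose(v, v[0]) for v in xs if len(v))
        if degenerate:
            f_stat, p_val = np.nan, np.nan
            sig = {frozenset((a, b)): not np.isclose(means[a], means[b])
                   for a, b in itertools.combinations(groups, 2)}
            for a, b in itertools.combinations(groups, 2):
                pair_rows.append({"variable": var, "group1": a, "group2": b,
                                  "p_adj": 0.0 if sig[frozenset((a, b))] else 1.0})
        else:
            f_stat, p_val = stats.f_oneway(*xs)
            tukey = pairwise_tukeyhsd(x[ok].to_numpy(), group[ok].to_numpy(),
                                      alpha=alpha)
            frame = pd.DataFrame(tukey.summary().data[1:],
                                 columns=tukey.summary().data[0])
            sig = {}
            for _, row in frame.iterrows():
                a, b = str(row["group1"]), str(row["group2"])
                p_adj = float(row["p-adj"])
                sig[frozenset((a, b))] = p_adj < alpha
                pair_rows.append({"variable": var, "group1": a, "group2": b,
                                  "p_adj": p_adj})
        letter_rows[var] = _letters_from_significance(groups, sig, means)
        row = {"variable": var, "F": f_stat, "p": p_val, "degenerate": degenerate}
        for g in groups:
            row[f"mean:{g}"] = means[g]
            row[f"sd:{g}"] = sds[g]
        sum_rows.append(row)

    return GroupCompareResult(
        summary=pd.DataFrame(sum_rows).set_index("variable"),
        pairwise=pd.DataFrame(pair_rows),
        letters=pd.DataFrame(letter_rows).T.reindex(columns=groups),
    )
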