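"""Core data containers for the pipeline.

The central object is :class:`OtuTable`, a validated samples x taxa count
matrix. :class:`EnvTable` carries the per-sample group label and numeric
environmental covariates (pH, SOM, TN, TP, TK, AN, AP, AK, ...).
:class:`CoNetwork` wraps an undirected signed correlation graph over OTUs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"

NODE_ROLES = ("peripheral", "connector", "module hub", "network hub")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    dups = {i for i in ids if i in seen or seen.add(i)}
    if dups:
        raise ValidationError(f"duplicate {what} identifier(s): {sorted(dups)}")
    return ids


class OtuTable:
    """Samples x OTUs table of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with sample identifiers as the index and OTU identifiers
        as the columns. Values must be non-negative integers.
    flags
        Free-form per-table annotations (e.g. all-zero OTUs after
        rarefaction). Carried along, never interpreted here.
    """

    def __init__(self, counts: pd.DataFrame, flags: dict | None = None):
        if not isinstance(counts, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame")
        _check_unique(counts.index.astype(str), "sample")
        _check_unique(counts.columns.astype(str), "OTU")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            rounded = np.rint(values)
            bad = ~np.isclose(values, rounded) | ~np.isfinite(values)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-integer count at sample {counts.index[i]!r}, "
                    f"OTU {counts.columns[j]!r}: {values[i, j]!r}"
                )
            values = rounded.astype(np.int64)
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {counts.index[i]!r}, "
                f"OTU {counts.columns[j]!r}: {values[i, j]}"
            )
        self.counts = pd.DataFrame(
            values.astype(np.int64), index=counts.index.astype(str),
            columns=counts.columns.astype(str),
        )
        self.flags = dict(flags or {})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    @property
    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised composition; all-zero samples become all-NaN rows."""
        depths = self.depths.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts.to_numpy(dtype=float) / depths[:, None]
        return pd.DataFrame(rel, index=self.counts.index, columns=self.counts.columns)

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)], flags=self.flags)

    def select_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[:, list(otu_ids)], flags=self.flags)

    def require_analysable(self) -> None:
        if self.n_samples < 2 or self.n_otus < 2:
            raise ValidationError(
                f"need at least 2 samples and 2 OTUs, got "
                f"{self.n_samples} x {self.n_otus}"
            )

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs)"


class TaxonomyMap:
    """OTU -> ranked lineage (domain..genus); missing ranks are 'unclassified'."""

    def __init__(self, lineages: pd.DataFrame):
        _check_unique(lineages.index.astype(str), "OTU")
        table = pd.DataFrame(index=lineages.index.astype(str))
        for rank in TAXONOMY_RANKS:
            if rank in lineages.columns:
                col = lineages[rank].astype("string").fillna(UNCLASSIFIED)
                col = col.replace("", UNCLASSIFIED)
            else:
                col = UNCLASSIFIED
            table[rank] = col
        self.lineages = table.astype(str)

    def rank(self, rank: str) -> pd.Series:
        if rank not in TAXONOMY_RANKS:
            raise ValidationError(f"unknown rank {rank!r}; valid: {TAXONOMY_RANKS}")
        return self.lineages[rank]

    def lineage_of(self, otu_id: str, rank: str = "genus") -> str:
        if otu_id not in self.lineages.index:
            return UNCLASSIFIED
        return self.lineages.loc[otu_id, rank]

    def __repr__(self) -> str:
        return f"TaxonomyMap({len(self.lineages)} OTUs)"


class EnvTable:
    """Per-sample group label plus named numeric environmental covariates."""

    GROUP_COL = "group"

    def __init__(self, data: pd.DataFrame):
        if self.GROUP_COL not in data.columns:
            raise ValidationError(f"missing required column {self.GROUP_COL!r}")
        _check_unique(data.index.astype(str), "sample")
        data = data.copy()
        data.index = data.index.astype(str)
        data[self.GROUP_COL] = pd.Categorical(data[self.GROUP_COL].astype(str))
        for col in data.columns:
            if col == self.GROUP_COL:
                continue
            coerced = pd.to_numeric(data[col], errors="coerce")
            bad = coerced.isna() & data[col].notna()
            if bad.any():
                sample = bad.idxmax()
                raise ValidationError(
                    f"non-numeric value in covariate {col!r}, "
                    f"sample {sample!r}: {data.loc[sample, col]!r}"
                )
            data[col] = coerced
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def group(self) -> pd.Series:
        return self.data[self.GROUP_COL]

    @property
    def groups(self) -> list[str]:
        return list(self.group.cat.categories)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=[self.GROUP_COL])

    def samples_in(self, group: str) -> list[str]:
        return list(self.data.index[self.group == group])

    def require_covering(self, otu: OtuTable) -> None:
        missing = sorted(set(otu.sample_ids) - set(self.sample_ids))
        if missing:
            raise ValidationError(
                f"samples present in the OTU table but absent from the "
                f"environment table: {missing}"
            )

    def require_replication(self, min_per_group: int = 2) -> None:
        sizes = self.group.value_counts()
        small = sizes[sizes < min_per_group]
        if len(self.groups) < 2:
            raise ValidationError("need at least 2 group levels")
        if len(small):
            raise ValidationError(
                f"groups with fewer than {min_per_group} samples: "
                f"{dict(small)}"
            )

    def aligned_to(self, sample_ids: Iterable[str]) -> "EnvTable":
        return EnvTable(self.data.loc[list(sample_ids)])

    def __repr__(self) -> str:
        return (f"EnvTable({len(self.data)} samples, groups={self.groups}, "
                f"{self.covariates.shape[1]} covariates)")


class CoNetwork:
    """Undirected signed co-occurrence graph over OTU nodes.

    Edges carry ``r`` (correlation), ``p`` (its significance) and ``sign``.
    Nodes may carry ``module`` (community id), ``taxonomy`` and
    ``mean_rel_abund``. ``params`` snapshots the construction settings and
    ``group`` the sample group the network was built from.
    """

    def __init__(self, graph: nx.Graph | None = None, group: str | None = None,
                 params: Mapping | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError("self-loops are not allowed")
        self.group = group
        self.params = dict(params or {})

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def modules(self) -> dict:
        return nx.get_node_attributes(self.graph, "module")

    def set_modules(self, assignment: Mapping) -> None:
        missing = set(self.graph.nodes) - set(assignment)
        if missing:
            raise ValidationError(f"module assignment misses nodes: {sorted(missing)}")
        nx.set_node_attributes(
            self.graph, {n: int(assignment[n]) for n in self.graph.nodes}, "module")

    def adjacency(self, nodes: list | None = None) -> np.ndarray:
        """Dense unweighted 0/1 adjacency in the given node order."""
        nodes = list(self.graph.nodes) if nodes is None else nodes
        return nx.to_numpy_array(self.graph, nodelist=nodes, weight=None)

    def largest_component(self) -> "CoNetwork":
        if self.n_nodes == 0:
            return self
        comp = max(nx.connected_components(self.graph), key=lambda c: (len(c), sorted(c)))
        return CoNetwork(self.graph.subgraph(comp).copy(), self.group, self.params)

    def __repr__(self) -> str:
        tag = f", group={self.group!r}" if self.group else ""
        return f"CoNetwork({self.n_nodes} nodes, {self.n_edges} edges{tag})"


@dataclass
class RunConfig:
    """All tunable analysis settings, stamped into every output.

    Fractions live in (0, 1]; thresholds are validated on construction.
    ``simpson_convention`` selects between the dominance form (sum p_i^2)
    and its complement (1 - sum p_i^2); both are common in the literature
    and reported tables tag which one was used.
    """

    rarefaction_fraction: float = 0.90
    correlation_method: str = "spearman"     # spearman | pearson
    r_min: float = 0.7
    p_max: float = 0.05
    p_adjust: str = "BH"                     # none | BH
    min_mean_rel_abund: float = 1e-4         # dominance filter: 0.01 %
    min_prevalence: float = 1.0 / 3.0
    zi_hub: float = 2.5
    pi_connector: float = 0.62
    removal_fraction: float = 0.10
    removal_replicates: int = 100
    simpson_convention: str = "dominance"    # dominance | complement
    min_group_n: int = 5                     # minimum samples per group for networks
    alpha: float = 0.05
    n_permutations: int = 999
    hellinger: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("rarefaction_fraction", "removal_fraction", "min_prevalence"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.min_mean_rel_abund <= 1:
            raise ValidationError("min_mean_rel_abund must be in [0, 1]")
        if not 0 <= self.r_min:
            raise ValidationError("r_min must be non-negative")
        if not 0 < self.p_max <= 1:
            raise ValidationError("p_max must be in (0, 1]")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValidationError(f"unknown correlation method {self.correlation_method!r}")
        if self.p_adjust not in ("none", "BH"):
            raise ValidationError(f"unknown p adjustment {self.p_adjust!r}")
        if self.simpson_convention not in ("dominance", "complement"):
            raise ValidationError(f"unknown Simpson convention {self.simpson_convention!r}")
        if self.removal_replicates < 1:
            raise ValidationError("removal_replicates must be >= 1")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Stage-local generator derived from the run seed and stage name.

        Stages draw from independent substreams so adding randomness to one
        stage never perturbs another.
        """
        digest = hashlib.sha256(stage.encode()).digest()
        stage_key = int.from_bytes(digest[:4], "big")
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage_key]))
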