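"""Readers and writers for the tabular and graph formats the pipeline uses.

Tables travel as UTF-8 TSV with a header row; OTU tables additionally read
BIOM v1 (JSON) files. Networks persist as GraphML (attributes included) or
a 3-column edge list. Internally samples are always rows; the TSV reader
auto-detects a taxa-as-rows table by a simple shape heuristic (taxa usually
outnumber samples) which can be overridden explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .containers import (
    CoNetwork, EnvTable, OtuTable, RunConfig, TAXONOMY_RANKS, TaxonomyMap,
    ValidationError,
)


def read_otu_table(path: str | Path, format: str = "tsv",
                   orientation: str = "auto",
                   sample_ids: list[str] | None = None) -> OtuTable:
    """Read an OTU count table from TSV or BIOM-JSON.

    ``orientation`` is 'samples' (samples as rows), 'taxa', or 'auto'.
    In auto mode, a known sample-id list wins; otherwise the smaller axis
    is taken to be samples when the axes differ, matching the common case
    of taxa vastly outnumbering samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("auto", "samples", "taxa"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "biom-json":
        frame = _read_biom_json(path)
    else:
        raise ValidationError(f"unknown OTU table format {format!r}")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if orientation == "taxa":
        frame = frame.T
    elif orientation == "auto":
        if sample_ids is not None:
            known = set(sample_ids)
            rows = len(known & set(frame.index))
            cols = len(known & set(frame.columns))
            if cols > rows:
                frame = frame.T
        elif frame.shape[0] > frame.shape[1]:
            frame = frame.T
    return OtuTable(frame)


def _read_biom_json(path: Path) -> pd.DataFrame:
    """Minimal BIOM v1 (JSON) reader: rows are observations (OTUs)."""
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    data = np.zeros(shape)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            data[i, j] = v
    else:
        data = np.asarray(doc["data"], dtype=float)
    # BIOM rows are OTUs; transpose to samples-as-rows
    return pd.DataFrame(data.T, index=sample_ids, columns=otu_ids)


def write_otu_table(otu: OtuTable, path: str | Path) -> None:
    otu.counts.rename_axis("sample_id").to_csv(path, sep="\t")


def read_env_table(path: str | Path) -> EnvTable:
    """Read the sample metadata table (group label + numeric covariates)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return EnvTable(frame)


def write_env_table(env: EnvTable, path: str | Path) -> None:
    env.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyMap(frame)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    tax.lineages.rename_axis("otu_id").to_csv(path, sep="\t")


def write_network(network: CoNetwork, path: str | Path,
                  format: str = "graphml") -> None:
    """Persist a co-occurrence network with node and edge attributes."""
    path = Path(path)
    if format == "graphml":
        graph = network.graph.copy()
        graph.graph.update({f"param_{k}": str(v)
                            for k, v in network.params.items()})
        if network.group is not None:
            graph.graph["group"] = network.group
        for _, data in graph.nodes(data=True):
            for key, value in list(data.items()):
                if isinstance(value, (np.floating, np.integer)):
                    data[key] = value.item()
                elif value is None or (isinstance(value, float) and np.isnan(value)):
                    data[key] = ""
        nx.write_graphml(graph, path)
    elif format == "edgelist":
        rows = [{"source": u, "target": v, "r": d.get("r", 1.0)}
                for u, v, d in network.graph.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "r"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> CoNetwork:
    path = Path(path)
    if format == "graphml":
        graph = nx.read_graphml(path)
        params = {k[6:]: v for k, v in graph.graph.items()
                  if k.startswith("param_")}
        group = graph.graph.get("group")
        for key in list(graph.graph):
            del graph.graph[key]
        return CoNetwork(nx.Graph(graph), group=group, params=params)
    if format == "edgelist":
        frame = pd.read_csv(path, sep="\t")
        graph = nx.Graph()
        for _, row in frame.iterrows():
            graph.add_edge(str(row["source"]), str(row["target"]),
                           r=float(row["r"]))
        return CoNetwork(graph)
    raise ValidationError(f"unknown network format {format!r}")


def read_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON, a YAML subset) mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(RunConfig().to_dict())
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
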