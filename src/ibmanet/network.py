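"""Regulatory-network container, thresholding, cycle removal, and file I/O."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["regulator_id", "target_id", "posterior_probability"]


@dataclass
class RegulatoryNetwork:
    """Directed weighted network of inferred regulatory relationships.

    ``edges`` has columns regulator_id, target_id, posterior_probability.
    ``mode`` records whether the network came from time-lag or static
    regression; static networks may not contain self-edges.
    """

    edges: pd.DataFrame
    gene_universe: set
    mode: str = "lag"
    results: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if list(self.edges.columns) != EDGE_COLUMNS:
            self.edges = self.edges[EDGE_COLUMNS]
        probs = self.edges["posterior_probability"].to_numpy(dtype=float)
        if probs.size and (probs.min() < 0 or probs.max() > 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        pairs = self.edges[["regulator_id", "target_id"]]
        if pairs.duplicated().any():
            raise ValueError("duplicate (regulator, target) pairs")
        if self.mode == "static":
            if (self.edges["regulator_id"] == self.edges["target_id"]).any():
                raise ValueError("static-mode networks cannot contain self-edges")
        self.gene_universe = set(self.gene_universe)

    @classmethod
    def from_edges(cls, rows, gene_universe, mode: str = "lag") -> "RegulatoryNetwork":
        df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        return cls(edges=df, gene_universe=gene_universe, mode=mode)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return set(
            zip(self.edges["regulator_id"], self.edges["target_id"])
        )

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_universe)
        for reg, tgt, p in self.edges.itertuples(index=False):
            g.add_edge(reg, tgt, probability=float(p))
        return g


def threshold_network(net: RegulatoryNetwork, threshold: float) -> RegulatoryNetwork:
    """Keep edges with posterior probability >= threshold (inclusive)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    kept = net.edges[net.edges["posterior_probability"] >= threshold]
    return RegulatoryNetwork(
        edges=kept.reset_index(drop=True),
        gene_universe=net.gene_universe,
        mode=net.mode,
    )


def remove_feedback_loops(net: RegulatoryNetwork) -> RegulatoryNetwork:
    """Break all feedback loops in a static network.

    Repeatedly finds nontrivial strongly connected components (including
    self-loops) and deletes the lowest-probability edge inside each, with
    ties broken by (regulator, target) id, until the graph is acyclic.  Each
    deletion strictly reduces the edge count inside some component, so the
    procedure terminates; deleted edges are logged.
    """
    if net.mode != "static":
        raise ValueError("feedback-loop removal applies to static networks")
    g = net.to_graph()
    removed = []
    while True:
        broke = False
        for comp in list(nx.strongly_connected_components(g)):
            # edges strictly inside the component; for a singleton component
            # only a self-loop qualifies
            sub_edges = [
                (u, v, g[u][v]["probability"])
                for u, v in g.edges(comp)
                if u in comp and v in comp and (len(comp) > 1 or u == v)
            ]
            if not sub_edges:
                continue
            victim = min(sub_edges, key=lambda e: (e[2], e[0], e[1]))
            g.remove_edge(victim[0], victim[1])
            removed.append(victim)
            broke = True
        if not broke:
            break
    if removed:
        logger.info("removed %d feedback edges: %s", len(removed), removed[:10])
    kept_pairs = set(g.edges())
    kept = net.edges[
        [
            (r, t) in kept_pairs
            for r, t in zip(net.edges["regulator_id"], net.edges["target_id"])
        ]
    ]
    return RegulatoryNetwork(
        edges=kept.reset_index(drop=True),
        gene_universe=net.gene_universe,
        mode=net.mode,
    )


# ---------------------------------------------------------------------------
# File formats (all plain TSV)
# ---------------------------------------------------------------------------


def write_network(net: RegulatoryNetwork, path) -> None:
    """Edge TSV: regulator_id, target_id, posterior_probability (6 d.p.),
    sorted by target then descending probability."""
    out = net.edges.sort_values(
        ["target_id", "posterior_probability", "regulator_id"],
        ascending=[True, False, True],
    ).copy()
    out["posterior_probability"] = out["posterior_probability"].map(
        lambda p: f"{p:.6f}"
    )
    out.to_csv(path, sep="\t", index=False)


def read_network(path, gene_universe=None, mode: str = "lag") -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = EDGE_COLUMNS
    df["posterior_probability"] = df["posterior_probability"].astype(float)
    if gene_universe is None:
        gene_universe = set(df["regulator_id"]) | set(df["target_id"])
    return RegulatoryNetwork(edges=df, gene_universe=gene_universe, mode=mode)


def write_expression(expr, path) -> None:
    """Long-format expression TSV: gene_id, sample_id, time, value."""
    g, t, s = expr.values.shape
    gene = np.repeat(expr.gene_ids, t * s)
    time = np.tile(np.repeat(expr.time_ids, s), g)
    sample = np.tile(expr.sample_ids, g * t)
    pd.DataFrame(
        {
            "gene_id": gene,
            "sample_id": sample,
            "time": time,
            "value": expr.values.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression(path):
    """Read long-format expression TSV into an :class:`ExpressionSeries`."""
    from ibmanet.ibma import ExpressionSeries

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    genes = list(pd.unique(df["gene_id"]))
    times = sorted(pd.unique(df["time"]))
    samples = list(pd.unique(df["sample_id"]))
    pivot = df.set_index(["gene_id", "time", "sample_id"])["value"]
    values = (
        pivot.reindex(pd.MultiIndex.from_product([genes, times, samples]))
        .to_numpy()
        .reshape(len(genes), len(times), len(samples))
    )
    if np.isnan(values).any():
        raise ValueError("expression table has missing (gene, time, sample) cells")
    return ExpressionSeries(
        values=values, gene_ids=genes, time_ids=times, sample_ids=samples
    )


def write_prior_matrix(priors, path) -> None:
    """Prior TSV: gene_id, regulator_id, pi."""
    priors.to_long().to_csv(path, sep="\t", index=False)


def read_prior_matrix(path, tau: float):
    from ibmanet.priors import RegulatoryPriorMatrix

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "regulator_id": str})
    return RegulatoryPriorMatrix.from_long(df, tau=tau)


def load_config(path):
    """Read an IbmaConfig from a YAML key-value file."""
    from ibmanet.ibma import IbmaConfig

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return IbmaConfig(**data)


def save_config(config, path) -> None:
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
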