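"""Gene co-expression networks with an FDR edge criterion.

For one condition (a treatment x cell type subset) every gene pair gets a
Pearson correlation over pairwise-complete samples, a two-sided p from the
t transform (df = n - 2), and a Benjamini-Hochberg q over all tested pairs
within the condition.  Pairs with q below the threshold (default 0.001)
become undirected edges carrying r, |r| as weight, and sign; nodes carry
the gene's median expression in the condition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class CorrelationNetwork:
    condition: str
    graph: nx.Graph
    tested: pd.DataFrame  # gene1, gene2, n, r, p, q
    q_threshold: float
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene1": u, "gene2": v, **d}
            for u, v, d in self.graph.edges(data=True)
        ]
        cols = ["gene1", "gene2", "r", "p", "q", "sign", "weight", "n"]
        return pd.DataFrame(rows, columns=cols)


def _pearson_p(r: np.ndarray, n) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with df = n - 2."""
    n = np.asarray(n, dtype=float)
    df = n - 2
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return p


def build_network(
    expr,
    condition: str = "",
    q_threshold: float = 1e-3,
    min_pairs: int = 5,
) -> CorrelationNetwork:
    """All-pairs Pearson network with BH-thresholded edges for one condition."""
    values = expr.values if hasattr(expr, "analysis_genes") else expr
    if hasattr(expr, "analysis_genes"):
        values = values[expr.analysis_genes()]
    if values.shape[1] < 2:
        raise ValueError("network construction needs >= 2 genes")
    sd = values.std(axis=0, ddof=1, skipna=True)
    degenerate = [g for g in values.columns if not np.isfinite(sd[g]) or sd[g] == 0.0]
    if degenerate:
        logger.info("condition %s: excluding zero-variance genes %s", condition, degenerate)
    genes = [g for g in values.columns if g not in degenerate]
    vals = values[genes]

    X = vals.to_numpy(dtype=float)
    complete = not np.isnan(X).any()
    pairs, ns, rs = [], [], []
    skipped = 0
    if complete:
        R = np.corrcoef(X, rowvar=False)
        n = X.shape[0]
        if n < min_pairs:
            raise ValueError(f"only {n} samples; min_pairs={min_pairs}")
        iu = np.triu_indices(len(genes), k=1)
        pairs = [(genes[i], genes[j]) for i, j in zip(*iu)]
        rs = R[iu]
        ns = np.full(len(pairs), n)
    else:
        for g1, g2 in itertools.combinations(genes, 2):
            sub = vals[[g1, g2]].dropna()
            if len(sub) < min_pairs:
                skipped += 1
                continue
            r = float(np.corrcoef(sub[g1], sub[g2])[0, 1])
            pairs.append((g1, g2))
            rs.append(r)
            ns.append(len(sub))
        rs = np.asarray(rs)
        ns = np.asarray(ns)
        if skipped:
            logger.info("condition %s: %d pairs below min_pairs=%d untested",
                        condition, skipped, min_pairs)
    if not len(pairs):
        raise ValueError("no testable gene pairs")
    ps = _pearson_p(rs, ns)
    qs = bh_adjust(ps)
    tested = pd.DataFrame(
        {
            "gene1": [a for a, _ in pairs],
            "gene2": [b for _, b in pairs],
            "n": ns,
            "r": rs,
            "p": ps,
            "q": qs,
        }
    )
    graph = nx.Graph(condition=condition)
    medians = values.median(axis=0, skipna=True)
    for g in values.columns:
        graph.add_node(g, median_expression=float(medians[g]))
    for row in tested.itertuples(index=False):
        if row.q < q_threshold:
            graph.add_edge(
                row.gene1, row.gene2,
                r=float(row.r), p=float(row.p), q=float(row.q),
                sign=int(np.sign(row.r)), weight=float(abs(row.r)), n=int(row.n),
            )
    return CorrelationNetwork(
        condition=condition, graph=graph, tested=tested,
        q_threshold=q_threshold, excluded_genes=degenerate,
    )


def edge_summary(networks: list[CorrelationNetwork]) -> dict[str, pd.DataFrame | pd.Series]:
    """Edge counts and per-gene degrees across conditions, with deltas.

    All networks must share a gene universe; degree deltas are reported for
    every ordered condition pair (Fig-style Withdrawal - Morphine /
    Withdrawal - Placebo differences are columns named "A-B").
    """
    if not networks:
        raise ValueError("no networks given")
    universes = [set(n.graph.nodes) for n in networks]
    base = universes[0]
    for net, uni in zip(networks[1:], universes[1:]):
        if uni != base:
            diff = sorted(base ^ uni)
            raise ValueError(f"gene universes differ (condition {net.condition}): {diff}")
    genes = sorted(base)
    counts = pd.Series({n.condition: n.n_edges for n in networks}, name="n_edges")
    degree = pd.DataFrame(
        {n.condition: [n.graph.degree(g) for g in genes] for n in networks},
        index=genes,
    )
    deltas = {}
    for a in degree.columns:
        for b in degree.columns:
            if a != b:
                deltas[f"{a}-{b}"] = degree[a] - degree[b]
    return {"edge_counts": counts, "degree": degree, "degree_deltas": pd.DataFrame(deltas)}


def write_network(net: CorrelationNetwork, edge_tsv, graphml=None) -> None:
    net.edge_table().to_csv(edge_tsv, sep="\t", index=False)
    if graphml is not None:
        nx.write_graphml(net.graph, graphml)
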